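"""Seeded generators for synthetic toxicokinetic datasets.

Every generator is a pure function of its parameters and an explicit seed,
so datasets are reproducible and fitting code can be validated by
round-trip: generate at known parameters, fit, compare.  The default
multiplicative lognormal noise with CV 0.06 mirrors the ~5-6% coefficients
of variation of pooled-larvae LC-MS/MS measurements; the default sampling
grids mirror a typical 8-h uptake / 48-h depuration design (uptake samples
at 0.25-8 h, depuration samples 1-48 h after transfer to clean water, all
on one absolute time axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import DoseResponseData, DoseResponseFit, evaluate_4pl
from .timecourse import COLUMNS, TimeCourseDataset
from .tissue_stats import TissuePanel
from .tk_multicomp import (
    BodyComposition,
    MultiCompartmentParams,
    combine_whole_body,
    simulate_multi_compartment,
)
from .tk_onecomp import ExposureScenario, OneCompartmentParams, simulate_one_compartment

__all__ = [
    "NoiseModel",
    "default_times",
    "gen_timecourse",
    "gen_tissue_panel",
    "gen_zfet_outcomes",
    "gen_biphasic_depuration",
    "DEFAULT_UPTAKE_TIMES",
    "DEFAULT_DEPURATION_OFFSETS",
]

#: hours since exposure start at which uptake-phase samples are taken
DEFAULT_UPTAKE_TIMES = (0.25, 1.0, 3.0, 6.0, 8.0)
#: hours since depuration start at which depuration samples are taken
DEFAULT_DEPURATION_OFFSETS = (1.0, 3.0, 6.0, 18.0, 24.0, 27.0, 48.0)

NOISE_KINDS = ("multiplicative-lognormal", "additive-normal")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise specification with an explicit seed.

    ``multiplicative-lognormal`` draws unit-mean lognormal factors with the
    requested coefficient of variation; ``additive-normal`` adds zero-mean
    Gaussian noise with sd = cv * model value, truncated at zero.
    """

    kind: str = "multiplicative-lognormal"
    cv: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"kind must be one of {NOISE_KINDS}, got {self.kind!r}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.cv == 0:
            return values.copy()
        if self.kind == "multiplicative-lognormal":
            sigma2 = math.log1p(self.cv**2)
            factors = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=values.shape)
            return values * factors
        noisy = values + rng.normal(0.0, self.cv * values, size=values.shape)
        return np.maximum(noisy, 0.0)


def default_times(scenario: ExposureScenario) -> np.ndarray:
    """Default absolute sampling grid for a scenario (uptake + depuration)."""
    up = [t for t in DEFAULT_UPTAKE_TIMES if t <= scenario.t_uptake]
    dep = [
        scenario.t_uptake + o
        for o in DEFAULT_DEPURATION_OFFSETS
        if o <= scenario.t_depuration
    ]
    return np.asarray(up + dep, dtype=float)


def _phases(times: np.ndarray, scenario: ExposureScenario) -> np.ndarray:
    return np.where(times <= scenario.t_uptake, "uptake", "depuration")


def gen_timecourse(
    params: OneCompartmentParams | MultiCompartmentParams,
    scenario: ExposureScenario,
    times=None,
    n_replicates: int = 16,
    noise: NoiseModel = NoiseModel(),
    body: BodyComposition | None = None,
    pigmentation: str = "WT",
) -> TimeCourseDataset:
    """Simulate a time course and overlay per-replicate measurement noise.

    One-compartment parameters yield whole-body rows; multi-compartment
    parameters additionally require a :class:`BodyComposition` and yield
    eye rows plus weight-combined whole-body rows.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    times = default_times(scenario) if times is None else np.asarray(times, float)
    rng = np.random.default_rng(noise.seed)
    phases = _phases(times, scenario)

    series: dict[str, np.ndarray] = {}
    if isinstance(params, MultiCompartmentParams):
        if body is None:
            raise ValueError("multi-compartment generation requires a BodyComposition")
        c_eyes, c_rest = simulate_multi_compartment(params, scenario, times)
        series["eyes"] = c_eyes
        series["whole"] = np.asarray(combine_whole_body(c_eyes, c_rest, body))
    else:
        series["whole"] = simulate_one_compartment(params, scenario, times)

    rows = []
    for tissue, curve in series.items():
        for rep in range(n_replicates):
            noisy = noise.apply(curve, rng)
            for t, ph, c in zip(times, phases, noisy):
                rows.append(
                    {
                        "replicate_id": f"r{rep + 1}",
                        "phase": ph,
                        "time_h": float(t),
                        "tissue": tissue,
                        "pigmentation": pigmentation,
                        "conc_mg_per_kg": float(c),
                    }
                )
    return TimeCourseDataset(pd.DataFrame(rows, columns=COLUMNS))


def gen_tissue_panel(
    tissue_means: dict[str, float],
    pigmentation_factors: dict[str, float],
    n_pools: int = 3,
    noise: NoiseModel = NoiseModel(),
) -> TissuePanel:
    """Tissue x pigmentation panel with group means = tissue mean / factor.

    ``pigmentation_factors`` maps each line to its fold reduction relative
    to the tissue means (factor 1 = unreduced reference line).
    """
    if n_pools < 1:
        raise ValueError(f"n_pools must be >= 1, got {n_pools}")
    for tissue, mean in tissue_means.items():
        if mean < 0:
            raise ValueError(f"tissue {tissue!r}: mean must be >= 0")
    for line, factor in pigmentation_factors.items():
        if factor <= 0:
            raise ValueError(f"line {line!r}: factor must be > 0")
    rng = np.random.default_rng(noise.seed)
    groups = {}
    for tissue, mean in tissue_means.items():
        for line, factor in pigmentation_factors.items():
            level = np.full(n_pools, mean / factor)
            groups[(tissue, line)] = noise.apply(level, rng)
    return TissuePanel(groups=groups)


def gen_zfet_outcomes(
    curve: DoseResponseFit,
    concentrations,
    n_per_conc: int = 10,
    seed: int = 0,
) -> DoseResponseData:
    """Binomial embryo outcomes at curve-evaluated response probabilities."""
    conc = np.asarray(concentrations, dtype=float)
    if n_per_conc < 1:
        raise ValueError(f"n_per_conc must be >= 1, got {n_per_conc}")
    p = np.asarray(evaluate_4pl(curve, conc), dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("curve yields invalid response probabilities in [0, 1]")
    rng = np.random.default_rng(seed)
    responding = rng.binomial(n_per_conc, p)
    return DoseResponseData(
        conc_um=conc,
        n_exposed=np.full(len(conc), n_per_conc),
        n_responding=responding,
        endpoint="lethal",
    )


def gen_biphasic_depuration(
    c_start: float,
    initial_half_life: float,
    terminal_half_life: float,
    breakpoint_h: float,
    offsets=DEFAULT_DEPURATION_OFFSETS,
    t_uptake: float = 8.0,
    n_replicates: int = 1,
    noise: NoiseModel = NoiseModel(cv=0.0),
    tissue: str = "whole",
) -> TimeCourseDataset:
    """Model-free piecewise-exponential depuration series.

    Decays from ``c_start`` with the initial half-life until
    ``breakpoint_h`` after depuration start, then with the terminal
    half-life.  Times are absolute (offset + t_uptake) with phase
    'depuration'.
    """
    if c_start <= 0:
        raise ValueError("c_start must be > 0")
    for name, hl in (("initial", initial_half_life), ("terminal", terminal_half_life)):
        if hl <= 0:
            raise ValueError(f"{name} half-life must be > 0")
    k1 = math.log(2.0) / initial_half_life
    k2 = math.log(2.0) / terminal_half_life
    t = np.asarray(offsets, dtype=float)
    c_bp = c_start * math.exp(-k1 * breakpoint_h)
    curve = np.where(
        t <= breakpoint_h,
        c_start * np.exp(-k1 * t),
        c_bp * np.exp(-k2 * (t - breakpoint_h)),
    )
    rng = np.random.default_rng(noise.seed)
    rows = []
    for rep in range(n_replicates):
        noisy = noise.apply(curve, rng)
        for off, c in zip(t, noisy):
            rows.append(
                {
                    "replicate_id": f"r{rep + 1}",
                    "phase": "depuration",
                    "time_h": float(t_uptake + off),
                    "tissue": tissue,
                    "pigmentation": "WT",
                    "conc_mg_per_kg": float(c),
                }
            )
    return TimeCourseDataset(pd.DataFrame(rows, columns=COLUMNS))
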