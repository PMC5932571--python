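"""Passive-partitioning baseline for uptake/elimination rate constants.

Predicts first-order uptake and elimination rates of a waterborne organic
chemical from its octanol-water partition coefficient and the organism's
lipid content and body weight, following the gill-uptake kinetic
bioaccumulation framework of Arnot & Gobas:

* gill chemical uptake efficiency   E_W = 1 / (a + b / Kow)
* gill ventilation rate (L/day)     G_V = 1400 * W^0.65 / C_OX
* uptake rate constant              k_in = E_W * G_V / W      (L kg^-1 d^-1)
* elimination rate constant         k_out = k_in / (L_B * Kow)  (d^-1)

so the implied steady-state bioconcentration factor is exactly
``L_B * Kow`` (lipid fraction times the partition coefficient).  Rates are
returned per hour.  All coefficients live in a versioned JSON config
(``data/passive_coefficients.json``) and can be overridden.

The baseline deliberately contains no facilitated-transport or
melanin-binding terms: the gap between its predictions and measured levels
is the quantitative argument for active uptake of basic psychoactive drugs
in zebrafish larvae.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .core_units import BcfResult, Compound, compute_bcf, log_d
from .tk_onecomp import ExposureScenario, OneCompartmentParams, simulate_one_compartment

__all__ = [
    "PassiveModelParams",
    "load_coefficients",
    "predict_passive_rates",
    "predicted_bcf",
    "predict_passive_timecourse",
]

HOURS_PER_DAY = 24.0


def load_coefficients(path=None) -> dict:
    """Framework coefficients from the packaged (or a user) JSON config."""
    if path is None:
        text = (
            resources.files("zebratk").joinpath("data/passive_coefficients.json")
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    coeffs = json.loads(text)
    if "framework_version" not in coeffs:
        raise ValueError("coefficient config must carry a framework_version")
    return coeffs


@dataclass(frozen=True)
class PassiveModelParams:
    """Organism and environment inputs to the passive baseline.

    Defaults describe a 5 dpf zebrafish larva: 360 ug wet weight, 5% lipid,
    28 degC rearing water.  ``dissolved_oxygen_mg_per_l`` overrides the
    temperature-derived oxygen level when given.  ``ph`` switches the
    partition input from logP to the pH-corrected logD.
    """

    lipid_fraction: float = 0.05
    body_weight_kg: float = 3.6e-7
    water_temperature_c: float = 28.0
    dissolved_oxygen_mg_per_l: float | None = None
    ph: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.lipid_fraction < 1.0):
            raise ValueError(
                f"lipid_fraction must be in (0, 1), got {self.lipid_fraction}"
            )
        if self.body_weight_kg <= 0:
            raise ValueError(f"body_weight_kg must be > 0, got {self.body_weight_kg}")
        if (
            self.dissolved_oxygen_mg_per_l is not None
            and self.dissolved_oxygen_mg_per_l <= 0
        ):
            raise ValueError("dissolved_oxygen_mg_per_l must be > 0")


def _partition_coefficient(compound: Compound, params: PassiveModelParams) -> float:
    if params.ph is not None:
        return 10.0 ** log_d(compound, params.ph)
    return 10.0 ** compound.log_p


def predict_passive_rates(
    compound: Compound,
    params: PassiveModelParams | None = None,
    coefficients: dict | None = None,
) -> OneCompartmentParams:
    """(k_in, k_out) predicted from physico-chemical properties alone."""
    params = params or PassiveModelParams()
    c = coefficients or load_coefficients()
    kow = _partition_coefficient(compound, params)
    e_w = 1.0 / (c["gill_uptake_a"] + c["gill_uptake_b"] / kow)
    if params.dissolved_oxygen_mg_per_l is not None:
        c_ox = params.dissolved_oxygen_mg_per_l
    else:
        c_ox = (
            c["oxygen_temp_slope"] * params.water_temperature_c
            + c["oxygen_temp_intercept"]
        ) * c["oxygen_saturation"]
    g_v = (
        c["ventilation_coeff_l_per_day"]
        * params.body_weight_kg ** c["ventilation_weight_exponent"]
        / c_ox
    )
    k_in_per_day = e_w * g_v / params.body_weight_kg
    k_in = k_in_per_day / HOURS_PER_DAY
    k_out = k_in / (params.lipid_fraction * kow)
    return OneCompartmentParams(k_in=k_in, k_out=k_out)


def predicted_bcf(
    compound: Compound, params: PassiveModelParams | None = None
) -> BcfResult:
    """Steady-state BCF implied by the baseline: lipid_fraction * Kow."""
    params = params or PassiveModelParams()
    rates = predict_passive_rates(compound, params)
    return compute_bcf(rates.k_in, rates.k_out)


def predict_passive_timecourse(
    compound: Compound,
    params: PassiveModelParams,
    scenario: ExposureScenario,
    times,
) -> np.ndarray:
    """Predicted whole-body time course (mg/kg) under the passive baseline."""
    rates = predict_passive_rates(compound, params)
    return simulate_one_compartment(rates, scenario, times)
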