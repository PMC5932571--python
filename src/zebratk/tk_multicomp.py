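"""Eye/rest-of-body multi-compartment toxicokinetic model.

Melanin-rich eyes act as a high-affinity, slowly releasing reservoir for
basic drugs, so they are modelled as a compartment with its own first-order
uptake/elimination rates, in parallel with a "rest of body" compartment:

    dC_eyes/dt = k_in_eyes * C_w(t) - k_out_eyes * C_eyes(t)
    dC_rest/dt = k_in_rest * C_w(t) - k_out_rest * C_rest(t)

Both compartments exchange only with the water (no eye<->body flux).  The
whole-larva concentration is the wet-weight-weighted mean of the two, which
conserves total chemical mass.  A slow eye compartment next to a fast rest
compartment produces the biphasic whole-body depuration the single
compartment cannot reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .exceptions import FitError
from .timecourse import TimeCourseDataset
from .tk_onecomp import (
    ExposureScenario,
    FitReport,
    OneCompartmentParams,
    _closed_form,
    _check_times,
    _ode_solution,
    fit_one_compartment,
)

__all__ = [
    "MultiCompartmentParams",
    "BodyComposition",
    "simulate_multi_compartment",
    "combine_whole_body",
    "fit_multi_compartment",
    "compartment_half_lives",
]


@dataclass
class MultiCompartmentParams:
    """Per-compartment rate constants (eyes vs rest of body)."""

    k_in_eyes: float
    k_out_eyes: float
    k_in_rest: float
    k_out_rest: float
    k_in_eyes_se: float = math.nan
    k_out_eyes_se: float = math.nan
    k_in_rest_se: float = math.nan
    k_out_rest_se: float = math.nan
    fit: FitReport | None = None

    def __post_init__(self) -> None:
        for name in ("k_in_eyes", "k_out_eyes", "k_in_rest", "k_out_rest"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class BodyComposition:
    """Wet weights of the eye and rest-of-body compartments (kg)."""

    w_eyes: float
    w_rest: float

    def __post_init__(self) -> None:
        if self.w_eyes <= 0:
            raise ValueError(f"w_eyes must be > 0, got {self.w_eyes}")
        if self.w_rest <= 0:
            raise ValueError(f"w_rest must be > 0, got {self.w_rest}")

    @property
    def total_weight(self) -> float:
        return self.w_eyes + self.w_rest

    @property
    def eye_mass_fraction(self) -> float:
        return self.w_eyes / self.total_weight

    @classmethod
    def from_fraction(
        cls, total_weight_kg: float, eye_mass_fraction: float
    ) -> "BodyComposition":
        if not (0.0 < eye_mass_fraction < 1.0):
            raise ValueError(
                f"eye_mass_fraction must be in (0, 1), got {eye_mass_fraction}"
            )
        if total_weight_kg <= 0:
            raise ValueError(f"total weight must be > 0, got {total_weight_kg}")
        return cls(
            w_eyes=total_weight_kg * eye_mass_fraction,
            w_rest=total_weight_kg * (1.0 - eye_mass_fraction),
        )


def simulate_multi_compartment(
    params: MultiCompartmentParams,
    scenario: ExposureScenario,
    times,
    method: str = "analytic",
) -> tuple[np.ndarray, np.ndarray]:
    """(eye, rest) concentrations (mg/kg) at the requested times.

    The compartments are independent under the shared water forcing, so
    each is the one-compartment solution with its own rates.
    """
    times = _check_times(times)
    if method == "analytic":
        c_eyes = _closed_form(params.k_in_eyes, params.k_out_eyes, scenario, times)
        c_rest = _closed_form(params.k_in_rest, params.k_out_rest, scenario, times)
    elif method == "ode":
        c_eyes = _ode_solution(params.k_in_eyes, params.k_out_eyes, scenario, times)
        c_rest = _ode_solution(params.k_in_rest, params.k_out_rest, scenario, times)
    else:
        raise ValueError(f"unknown method {method!r}")
    return c_eyes, c_rest


def combine_whole_body(c_eyes, c_rest, body: BodyComposition):
    """Whole-larva concentration as the wet-weight-weighted compartment mean.

    ``C_whole = (C_eyes * W_eyes + C_rest * W_rest) / (W_eyes + W_rest)``;
    equivalently the whole-body chemical amount is the sum of compartment
    amounts, so mass is conserved exactly.
    """
    total = body.total_weight
    if total <= 0:  # defensive; BodyComposition already guarantees this
        raise ValueError("total body weight must be > 0")
    return (np.asarray(c_eyes) * body.w_eyes + np.asarray(c_rest) * body.w_rest) / total


def _validate_against_scenario(
    df, scenario: ExposureScenario, what: str, tol: float = 1e-9
) -> None:
    t = df["time_h"].to_numpy(float)
    phase = df["phase"].to_numpy()
    up = phase == "uptake"
    if np.any(t[up] > scenario.t_uptake + tol):
        raise ValueError(
            f"{what}: uptake-phase samples after t_uptake={scenario.t_uptake} h"
        )
    dep = ~up
    if np.any(t[dep] <= scenario.t_uptake + tol) or np.any(
        t[dep] > scenario.t_end + tol
    ):
        raise ValueError(
            f"{what}: depuration-phase samples outside "
            f"({scenario.t_uptake}, {scenario.t_end}] h"
        )


def fit_multi_compartment(
    whole_body: TimeCourseDataset,
    eyes: TimeCourseDataset,
    body: BodyComposition,
    scenario: ExposureScenario,
) -> MultiCompartmentParams:
    """Joint least-squares fit of the four compartment rate constants.

    Residuals stack the eye-concentration misfit and the misfit of the
    weight-combined whole-body curve against the whole-body observations,
    equally weighted on the concentration scale.  Standard errors come
    from the Jacobian at the optimum.

    Raises
    ------
    FitError
        If eye data are missing (use the one-compartment model on
        whole-body data instead) or too sparse, or on non-convergence.
    ValueError
        If either series is inconsistent with the exposure scenario.
    """
    eye_df = eyes.subset(tissue="eyes")
    whole_df = whole_body.subset(tissue="whole")
    if len(eye_df) == 0:
        raise FitError(
            "no eye-compartment observations: the multi-compartment model "
            "requires eye data; fit the one-compartment model instead"
        )
    if eye_df["time_h"].nunique() < 2:
        raise FitError("need eye data at >= 2 distinct time points")
    if len(whole_df) == 0:
        raise FitError("no whole-body observations")
    _validate_against_scenario(eye_df, scenario, "eye series")
    _validate_against_scenario(whole_df, scenario, "whole-body series")

    t_eye = eye_df["time_h"].to_numpy(float)
    y_eye = eye_df["conc_mg_per_kg"].to_numpy(float)
    t_whole = whole_df["time_h"].to_numpy(float)
    y_whole = whole_df["conc_mg_per_kg"].to_numpy(float)
    oe = np.argsort(t_eye, kind="stable")
    ow = np.argsort(t_whole, kind="stable")
    t_eye, y_eye = t_eye[oe], y_eye[oe]
    t_whole, y_whole = t_whole[ow], y_whole[ow]

    # starting values: one-compartment fit of the eye series; rest-of-body
    # starts from the whole-body fit corrected for the eye contribution
    try:
        eye0 = fit_one_compartment(eyes, scenario, tissue="eyes")
        k_in_eyes0, k_out_eyes0 = eye0.k_in, eye0.k_out
    except FitError:
        k_in_eyes0, k_out_eyes0 = 100.0, 0.1
    try:
        whole0 = fit_one_compartment(whole_body, scenario, tissue="whole")
        f = body.eye_mass_fraction
        k_in_rest0 = max((whole0.k_in - f * k_in_eyes0) / (1.0 - f), 1e-3)
        k_out_rest0 = max(whole0.k_out, 1e-3)
    except FitError:
        k_in_rest0, k_out_rest0 = 100.0, 0.5

    pars = lmfit.Parameters()
    pars.add("k_in_eyes", value=k_in_eyes0, min=1e-9)
    pars.add("k_out_eyes", value=k_out_eyes0, min=1e-9)
    pars.add("k_in_rest", value=k_in_rest0, min=1e-9)
    pars.add("k_out_rest", value=k_out_rest0, min=1e-9)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        m_eye = _closed_form(p["k_in_eyes"].value, p["k_out_eyes"].value, scenario, t_eye)
        m_eye_w = _closed_form(
            p["k_in_eyes"].value, p["k_out_eyes"].value, scenario, t_whole
        )
        m_rest_w = _closed_form(
            p["k_in_rest"].value, p["k_out_rest"].value, scenario, t_whole
        )
        m_whole = combine_whole_body(m_eye_w, m_rest_w, body)
        return np.concatenate([m_eye - y_eye, m_whole - y_whole])

    result = lmfit.minimize(residual, pars, method="leastsq")
    if not result.success:
        raise FitError(f"multi-compartment fit did not converge: {result.message}")
    resid = np.asarray(result.residual, dtype=float)
    report = FitReport(
        success=True,
        message=str(result.message),
        n_obs=len(t_eye) + len(t_whole),
        residuals=resid,
        rss=float(np.sum(resid**2)),
        nfev=int(result.nfev),
    )

    def val(name: str) -> float:
        return float(result.params[name].value)

    def se(name: str) -> float:
        s = result.params[name].stderr
        return float(s) if s is not None else math.nan

    return MultiCompartmentParams(
        k_in_eyes=val("k_in_eyes"),
        k_out_eyes=val("k_out_eyes"),
        k_in_rest=val("k_in_rest"),
        k_out_rest=val("k_out_rest"),
        k_in_eyes_se=se("k_in_eyes"),
        k_out_eyes_se=se("k_out_eyes"),
        k_in_rest_se=se("k_in_rest"),
        k_out_rest_se=se("k_out_rest"),
        fit=report,
    )


def compartment_half_lives(params: MultiCompartmentParams) -> dict[str, float]:
    """Elimination half-lives t1/2 = ln2 / k_out per compartment (hours)."""
    return {
        "eyes": math.log(2.0) / params.k_out_eyes,
        "rest": math.log(2.0) / params.k_out_rest,
    }


def as_one_compartment(params: MultiCompartmentParams) -> OneCompartmentParams | None:
    """Collapse to a single compartment when both share identical rates."""
    if (
        params.k_in_eyes == params.k_in_rest
        and params.k_out_eyes == params.k_out_rest
    ):
        return OneCompartmentParams(k_in=params.k_in_eyes, k_out=params.k_out_eyes)
    return None
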