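"""Four-parameter logistic (4PL) dose-response fitting and internal doses.

The embryo toxicity test records, per exposure concentration, how many of
the exposed embryos show a lethal or sub-lethal endpoint.  Response
fractions are fitted with the variable-slope sigmoid

    f(c) = bottom + (top - bottom) / (1 + 10^((logEC50 - log10 c) * hill))

by unweighted least squares on proportions (common 4PL practice); a
binomial-likelihood option is available.  External effect concentrations
are converted to internal body-burden metrics (ILC50 / IEC50 / INTC
analogues, mmol/kg) with the kinetic bioconcentration factor:

    internal dose (mmol/kg) = external concentration (mmol/L) * BCF (L/kg)

This conversion is an approximation — the exact convention behind
published internal-dose metrics varies — and outputs should be labelled
approximate wherever reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DoseResponseData",
    "DoseResponseFit",
    "fit_4pl",
    "evaluate_4pl",
    "internal_dose_metric",
]


@dataclass
class DoseResponseData:
    """Binary-outcome counts per exposure concentration (uM)."""

    conc_um: np.ndarray
    n_exposed: np.ndarray
    n_responding: np.ndarray
    endpoint: str = "lethal"

    def __post_init__(self) -> None:
        c = np.asarray(self.conc_um, dtype=float)
        ne = np.asarray(self.n_exposed, dtype=int)
        nr = np.asarray(self.n_responding, dtype=int)
        if not (len(c) == len(ne) == len(nr)):
            raise ValueError("conc_um, n_exposed, n_responding must align")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if len(np.unique(c)) != len(c):
            raise ValueError("concentrations must be distinct")
        if np.any(ne <= 0):
            raise ValueError("n_exposed must be > 0")
        if np.any((nr < 0) | (nr > ne)):
            raise ValueError("need 0 <= n_responding <= n_exposed")
        self.conc_um, self.n_exposed, self.n_responding = c, ne, nr

    @property
    def response(self) -> np.ndarray:
        return self.n_responding / self.n_exposed


@dataclass
class DoseResponseFit:
    """Fitted 4PL curve; ``ec50_ci`` is a Wald 95% interval (uM)."""

    bottom: float
    top: float
    log_ec50: float
    hill_slope: float
    ec50: float = math.nan
    ec50_ci: tuple[float, float] = (math.nan, math.nan)
    non_estimable: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if math.isnan(self.ec50) and math.isfinite(self.log_ec50):
            self.ec50 = 10.0**self.log_ec50


def evaluate_4pl(fit: DoseResponseFit, conc_um) -> np.ndarray:
    """Response fraction predicted by a 4PL curve at given concentrations."""
    c = np.asarray(conc_um, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log10(c)
    return fit.bottom + (fit.top - fit.bottom) / (
        1.0 + 10.0 ** ((fit.log_ec50 - logc) * fit.hill_slope)
    )


def _4pl_model(logc, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


def fit_4pl(data: DoseResponseData, likelihood: str = "ls") -> DoseResponseFit:
    """Fit the variable-slope 4PL to observed response fractions.

    ``likelihood="ls"`` (default) minimizes squared residuals of the
    proportions; ``likelihood="binomial"`` maximizes the binomial
    log-likelihood.  Requires >= 4 distinct positive concentrations.  A
    response that never varies (all 0% or all 100%) is flagged
    ``non_estimable`` rather than fitted; a poorly determined EC50 (wide
    Wald interval) triggers a warning.
    """
    pos = data.conc_um > 0
    c = data.conc_um[pos]
    y = data.response[pos]
    n = data.n_exposed[pos]
    r = data.n_responding[pos]
    if len(c) < 4:
        raise ValueError(f"need >= 4 positive concentrations, got {len(c)}")
    if np.all(y == y[0]):
        return DoseResponseFit(
            bottom=float(y[0]),
            top=float(y[0]),
            log_ec50=math.nan,
            hill_slope=math.nan,
            non_estimable=True,
            message="constant response; EC50 not estimable",
        )
    logc = np.log10(c)

    # initial values: span of the data, EC50 near the half-response dose
    b0, t0 = float(y.min()), float(y.max())
    half = (b0 + t0) / 2.0
    log_ec50_0 = float(np.interp(half, np.sort(y), logc[np.argsort(y)]))
    pars = lmfit.Parameters()
    pars.add("bottom", value=b0)
    pars.add("top", value=t0)
    pars.add("log_ec50", value=log_ec50_0)
    pars.add("hill", value=1.0)

    if likelihood == "ls":

        def residual(p):
            return (
                _4pl_model(
                    logc,
                    p["bottom"].value,
                    p["top"].value,
                    p["log_ec50"].value,
                    p["hill"].value,
                )
                - y
            )

        result = lmfit.minimize(residual, pars, method="leastsq")
        vals = {k: float(result.params[k].value) for k in pars}
        se = result.params["log_ec50"].stderr
        se = float(se) if se is not None else math.nan
        message = str(result.message)
    elif likelihood == "binomial":

        def nll(x):
            p = np.clip(_4pl_model(logc, *x), 1e-9, 1.0 - 1e-9)
            return -float(np.sum(r * np.log(p) + (n - r) * np.log1p(-p)))

        x0 = [b0, t0, log_ec50_0, 1.0]
        res = minimize(nll, x0, method="Nelder-Mead", options={"maxiter": 5000})
        vals = dict(zip(("bottom", "top", "log_ec50", "hill"), map(float, res.x)))
        se = math.nan
        message = str(res.message)
    else:
        raise ValueError(f"unknown likelihood {likelihood!r}")

    log_ec50 = vals["log_ec50"]
    if math.isfinite(se):
        ci = (10.0 ** (log_ec50 - 1.96 * se), 10.0 ** (log_ec50 + 1.96 * se))
    else:
        ci = (math.nan, math.nan)
    fit = DoseResponseFit(
        bottom=vals["bottom"],
        top=vals["top"],
        log_ec50=log_ec50,
        hill_slope=vals["hill"],
        ec50_ci=ci,
        message=message,
    )
    if likelihood == "ls" and (not math.isfinite(se) or se > 0.5):
        warnings.warn(
            "EC50 poorly determined (wide or undefined confidence interval); "
            "inspect the dose-response data",
            stacklevel=2,
        )
    return fit


def internal_dose_metric(
    external_conc_um: float, bcf: float, compound=None
) -> float:
    """Internal molar body burden (mmol/kg) from an external concentration.

    ``uM / 1000`` gives mmol/L; multiplying by BCF (L/kg) gives mmol/kg.
    Approximate stand-in for published internal-dose conventions; molar
    inputs need no molecular weight, so ``compound`` is accepted only for
    interface symmetry with the mass-based converters.
    """
    if external_conc_um <= 0:
        raise ValueError(f"external concentration must be > 0, got {external_conc_um}")
    if bcf <= 0:
        raise ValueError(f"bcf must be > 0, got {bcf}")
    return external_conc_um / 1000.0 * bcf
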