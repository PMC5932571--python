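"""Model-free elimination analyses.

Depuration of a chemical that is stored partly in a slowly releasing
reservoir (here, melanin-rich eyes) is biphasic: a fast initial decline
driven by the bulk of the body followed by a slow terminal phase as the
reservoir empties.  ``biphasic_half_lives`` quantifies this with a
two-segment log-linear regression, scanning every interior observed time
point as a candidate breakpoint and keeping the split with the smallest
total residual sum of squares on ln(concentration) — an exhaustive scan,
so the chosen breakpoint is optimal by construction.

The remaining operations are simple printed-table arithmetic used in
tissue-retention reporting: percent remaining after depuration, fold
differences between groups, and linear scaling of a tissue concentration
across external doses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .timecourse import TimeCourseDataset

__all__ = [
    "HalfLifeEstimate",
    "biphasic_half_lives",
    "percent_remaining",
    "fold_difference",
    "linear_dose_scaling",
]

#: two segment slopes closer than this (relative) are flagged degenerate,
#: i.e. the data look single-exponential
DEGENERACY_RTOL = 0.05


@dataclass
class HalfLifeEstimate:
    """Two-phase elimination summary.

    Half-lives in hours; ``breakpoint`` in hours since depuration start;
    slopes are d ln(C)/dt per segment with standard errors from the
    segment regressions.  ``degenerate`` is set when the two slopes are
    indistinguishable (single-exponential data).
    """

    initial_half_life: float
    terminal_half_life: float
    breakpoint: float
    initial_slope: float
    initial_slope_se: float
    terminal_slope: float
    terminal_slope_se: float
    n_initial: int
    n_terminal: int
    degenerate: bool
    sse: float


def _segment_fit(t: np.ndarray, logy: np.ndarray):
    res = stats.linregress(t, logy)
    pred = res.intercept + res.slope * t
    sse = float(np.sum((logy - pred) ** 2))
    return res.slope, res.stderr if math.isfinite(res.stderr) else 0.0, sse


def biphasic_half_lives(
    data: TimeCourseDataset,
    tissue: str = "whole",
    depuration_start: float | None = None,
    per_replicate: bool = False,
):
    """Two-segment log-linear half-life analysis of a depuration series.

    Replicates are pooled to per-time means by default
    (``per_replicate=True`` returns a dict of per-replicate estimates).
    Non-positive concentrations cannot enter a log regression and are
    dropped with a warning.  Candidate breakpoints are the interior
    observed times leaving >= 2 points in each segment (the breakpoint
    sample belongs to both); SSE ties resolve to the earlier breakpoint,
    which is conservative for the initial phase.

    Parameters
    ----------
    depuration_start
        Hours-since-exposure-start at which depuration began.  When None
        it is inferred from the latest uptake-phase sample in ``data``,
        or 0 if none (times already relative to depuration start).
    """
    dep = data.subset(tissue=tissue, phase="depuration")
    if depuration_start is None:
        up = data.subset(tissue=tissue, phase="uptake")
        depuration_start = float(up["time_h"].max()) if len(up) else 0.0

    if per_replicate:
        return {
            rep: _biphasic_from_points(
                g["time_h"].to_numpy(float) - depuration_start,
                g["conc_mg_per_kg"].to_numpy(float),
            )
            for rep, g in dep.groupby("replicate_id")
        }

    g = dep.groupby("time_h")["conc_mg_per_kg"].mean().sort_index()
    t = g.index.to_numpy(float) - depuration_start
    y = g.to_numpy(float)
    return _biphasic_from_points(t, y)


def _biphasic_from_points(t: np.ndarray, y: np.ndarray) -> HalfLifeEstimate:
    keep = y > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} non-positive concentration(s) "
            "from log-linear regression",
            stacklevel=2,
        )
    t, y = t[keep], y[keep]
    order = np.argsort(t)
    t, y = t[order], y[order]
    if len(t) < 4:
        raise ValueError(
            f"need >= 4 positive depuration points for a biphasic fit, got {len(t)}"
        )
    logy = np.log(y)

    best = None
    for bp in t[1:-1]:
        left = t <= bp
        right = t >= bp
        if left.sum() < 2 or right.sum() < 2:
            continue
        s1, se1, sse1 = _segment_fit(t[left], logy[left])
        s2, se2, sse2 = _segment_fit(t[right], logy[right])
        sse = sse1 + sse2
        # strict < keeps the earliest breakpoint on ties
        if best is None or sse < best[0] - 1e-15:
            best = (sse, bp, s1, se1, s2, se2, int(left.sum()), int(right.sum()))
    if best is None:
        raise ValueError("no admissible breakpoint with >= 2 points per segment")
    sse, bp, s1, se1, s2, se2, n1, n2 = best
    if s1 >= 0 or s2 >= 0:
        warnings.warn("non-decreasing segment in depuration data", stacklevel=2)
    hl1 = math.log(2.0) / abs(s1) if s1 != 0 else math.inf
    hl2 = math.log(2.0) / abs(s2) if s2 != 0 else math.inf
    degenerate = abs(s1 - s2) <= DEGENERACY_RTOL * max(abs(s1), abs(s2), 1e-300)
    return HalfLifeEstimate(
        initial_half_life=hl1,
        terminal_half_life=hl2,
        breakpoint=float(bp),
        initial_slope=float(s1),
        initial_slope_se=float(se1),
        terminal_slope=float(s2),
        terminal_slope_se=float(se2),
        n_initial=n1,
        n_terminal=n2,
        degenerate=degenerate,
        sse=float(sse),
    )


def percent_remaining(c_final: float, c_initial: float) -> float:
    """Percent of the initial concentration remaining: 100 * final/initial."""
    if c_initial <= 0:
        raise ValueError(f"c_initial must be > 0, got {c_initial}")
    if c_final < 0:
        raise ValueError(f"c_final must be >= 0, got {c_final}")
    return 100.0 * c_final / c_initial


def fold_difference(reference: float, other: float) -> float:
    """How many times lower ``other`` is than ``reference``: reference/other."""
    if other <= 0:
        raise ValueError(f"other must be > 0, got {other}")
    if reference < 0:
        raise ValueError(f"reference must be >= 0, got {reference}")
    return reference / other


def linear_dose_scaling(
    c_tissue_at_ref: float, dose_ref: float, dose_query: float
) -> float:
    """Tissue concentration at another external dose, assuming linear uptake.

    ``c(dose_query) = c(dose_ref) * dose_query / dose_ref`` — used e.g. to
    project a measured brain level down to the lowest behaviourally
    effective exposure concentration.
    """
    if dose_ref <= 0:
        raise ValueError(f"dose_ref must be > 0, got {dose_ref}")
    if dose_query < 0:
        raise ValueError(f"dose_query must be >= 0, got {dose_query}")
    return c_tissue_at_ref * dose_query / dose_ref
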