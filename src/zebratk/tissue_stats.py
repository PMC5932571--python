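"""Tissue-panel comparisons: ANOVA with Tukey HSD and fold-reduction tables.

The statistical unit is a pool of larvae (one measured value per pooled
sample), matching how dissected-tissue panels are replicated; replicate
counts per group are carried through rather than assumed balanced.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .depuration_analysis import fold_difference
from .timecourse import TimeCourseDataset

__all__ = ["TissuePanel", "AnovaResult", "tissue_anova", "pigmentation_report"]

GroupKey = tuple[str, str]  # (tissue, pigmentation)


@dataclass
class TissuePanel:
    """Replicate concentrations (mg/kg) per (tissue, pigmentation) group."""

    groups: dict[GroupKey, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[GroupKey, np.ndarray] = {}
        for key, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float)
            if arr.ndim != 1 or len(arr) == 0:
                raise ValueError(f"group {key}: need a non-empty 1-d array")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"group {key}: concentrations must be finite >= 0")
            clean[key] = arr
        self.groups = clean

    @classmethod
    def from_timecourse(cls, data: TimeCourseDataset, time_h: float | None = None):
        """Panel from a time course, optionally restricted to one time point."""
        df = data.frame
        if time_h is not None:
            df = df[np.isclose(df["time_h"], time_h)]
        if len(df) == 0:
            raise ValueError("no rows at the requested time point")
        groups = {
            (tis, pig): g["conc_mg_per_kg"].to_numpy(float)
            for (tis, pig), g in df.groupby(["tissue", "pigmentation"])
        }
        return cls(groups=groups)

    def tissues(self) -> list[str]:
        return sorted({t for t, _ in self.groups})

    def pigmentations(self) -> list[str]:
        return sorted({p for _, p in self.groups})


@dataclass
class AnovaResult:
    """One-way ANOVA with all-pairs Tukey HSD.

    ``pairwise`` columns: group1, group2, diff (mean1 - mean2),
    p_unadj (pooled-variance Fisher-LSD t test), p_adj (Tukey HSD).
    """

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame = field(repr=False)


def _select(panel: TissuePanel, keys) -> list[tuple[GroupKey, np.ndarray]]:
    if keys is None:
        keys = sorted(panel.groups)
    return [(k, panel.groups[k]) for k in keys]


def tissue_anova(
    panel: TissuePanel, keys=None, log_scale: bool = False
) -> AnovaResult:
    """One-way ANOVA across groups plus Tukey-adjusted pairwise contrasts.

    ``log_scale=True`` analyses ln(concentration) (requires positive
    values).  Unadjusted pairwise p-values use the pooled within-group
    mean square, so the Tukey-adjusted p is never smaller.
    """
    selected = _select(panel, keys)
    if len(selected) < 2:
        raise ValueError(f"need >= 2 groups for ANOVA, got {len(selected)}")
    for key, vals in selected:
        if len(vals) < 2:
            raise ValueError(f"group {key}: need >= 2 replicates, got {len(vals)}")
    samples = []
    for key, vals in selected:
        if log_scale:
            if np.any(vals <= 0):
                raise ValueError(f"group {key}: log scale requires positive values")
            vals = np.log(vals)
        samples.append(vals)

    f_stat, p_val = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)

    n_total = sum(len(s) for s in samples)
    k = len(samples)
    mse = sum(np.sum((s - s.mean()) ** 2) for s in samples) / (n_total - k)
    df_err = n_total - k

    rows = []
    for (i, (key_i, _)), (j, (key_j, _)) in itertools.combinations(
        enumerate(selected), 2
    ):
        diff = samples[i].mean() - samples[j].mean()
        se = math.sqrt(mse * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
        if se > 0:
            t = diff / se
            p_unadj = 2.0 * stats.t.sf(abs(t), df_err)
        else:
            p_unadj = 1.0
        rows.append(
            {
                "group1": "/".join(key_i),
                "group2": "/".join(key_j),
                "diff": diff,
                "p_unadj": p_unadj,
                "p_adj": float(tukey.pvalue[i, j]),
            }
        )
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pd.DataFrame(rows),
    )


def pigmentation_report(
    panel: TissuePanel, reference: str = "WT", log_scale: bool = False
) -> pd.DataFrame:
    """Per-tissue fold reductions of each pigmentation line vs a reference.

    For every tissue with the reference line present, reports mean, sd, n
    per line, the fold reduction ``reference mean / line mean``, and the
    Tukey-adjusted p-value of the line-vs-reference contrast (NaN for the
    reference itself or when a line has a single pool).

    Raises
    ------
    ValueError
        If the reference line is absent from every tissue.
    """
    if not any(pig == reference for _, pig in panel.groups):
        raise ValueError(f"reference pigmentation {reference!r} not in panel")
    rows = []
    for tissue in panel.tissues():
        lines = {
            pig: vals for (tis, pig), vals in panel.groups.items() if tis == tissue
        }
        if reference not in lines:
            continue
        ref_mean = float(np.mean(lines[reference]))
        keys = [(tissue, pig) for pig in sorted(lines)]
        testable = [k for k in keys if len(panel.groups[k]) >= 2]
        p_adj: dict[str, float] = {}
        if len(testable) >= 2 and (tissue, reference) in testable:
            res = tissue_anova(panel, keys=testable, log_scale=log_scale)
            ref_label = f"{tissue}/{reference}"
            for _, r in res.pairwise.iterrows():
                if ref_label in (r["group1"], r["group2"]):
                    other = r["group2"] if r["group1"] == ref_label else r["group1"]
                    p_adj[other.split("/", 1)[1]] = r["p_adj"]
        for pig in sorted(lines):
            vals = lines[pig]
            mean = float(np.mean(vals))
            rows.append(
                {
                    "tissue": tissue,
                    "pigmentation": pig,
                    "mean": mean,
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan,
                    "n": len(vals),
                    "fold_vs_reference": (
                        fold_difference(ref_mean, mean) if mean > 0 else math.inf
                    ),
                    "p_adj": math.nan if pig == reference else p_adj.get(pig, math.nan),
                }
            )
    return pd.DataFrame(rows)
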