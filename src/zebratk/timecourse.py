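"""Tabular time-course container for internal-concentration measurements.

A :class:`TimeCourseDataset` wraps a pandas DataFrame with one row per
(replicate, time, tissue) observation.  Times are hours since the start of
exposure on a single absolute axis; depuration samples carry a phase label
rather than a second clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

PHASES = ("uptake", "depuration")
TISSUES = ("whole", "brain", "eyes", "trunk")
PIGMENTATIONS = ("WT", "albino", "PTU")

#: canonical CSV column order
COLUMNS = [
    "replicate_id",
    "phase",
    "time_h",
    "tissue",
    "pigmentation",
    "conc_mg_per_kg",
]


@dataclass
class TimeCourseDataset:
    """Validated table of internal concentrations over time.

    Columns: ``replicate_id`` (str), ``phase`` (uptake|depuration),
    ``time_h`` (hours since exposure start), ``tissue``
    (whole|brain|eyes|trunk), ``pigmentation`` (WT|albino|PTU),
    ``conc_mg_per_kg`` (mg/kg wet weight, >= 0).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"missing columns: {missing}")
        if len(df) == 0:
            raise DataError("empty dataset")
        df = df[COLUMNS].copy()
        df["replicate_id"] = df["replicate_id"].astype(str)

        bad_phase = ~df["phase"].isin(PHASES)
        if bad_phase.any():
            raise DataError(
                f"invalid phase in rows {list(df.index[bad_phase])}: "
                f"allowed {PHASES}"
            )
        bad_tissue = ~df["tissue"].isin(TISSUES)
        if bad_tissue.any():
            raise DataError(
                f"invalid tissue in rows {list(df.index[bad_tissue])}: "
                f"allowed {TISSUES}"
            )
        bad_pig = ~df["pigmentation"].isin(PIGMENTATIONS)
        if bad_pig.any():
            raise DataError(
                f"invalid pigmentation in rows {list(df.index[bad_pig])}: "
                f"allowed {PIGMENTATIONS}"
            )
        for col in ("time_h", "conc_mg_per_kg"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = ~np.isfinite(vals)
            if bad.any():
                raise DataError(f"non-numeric {col} in rows {list(df.index[bad])}")
            df[col] = vals.astype(float)
        neg_t = df["time_h"] < 0
        if neg_t.any():
            raise DataError(f"negative time_h in rows {list(df.index[neg_t])}")
        neg_c = df["conc_mg_per_kg"] < 0
        if neg_c.any():
            raise DataError(
                f"negative conc_mg_per_kg in rows {list(df.index[neg_c])}"
            )
        dup = df.duplicated(
            subset=["replicate_id", "time_h", "tissue", "pigmentation"], keep=False
        )
        if dup.any():
            raise DataError(
                "duplicate (replicate_id, time_h, tissue, pigmentation) keys "
                f"in rows {list(df.index[dup])}"
            )
        df = df.sort_values(["tissue", "pigmentation", "replicate_id", "time_h"])
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    # -- convenience views -------------------------------------------------

    def subset(
        self,
        tissue: str | None = None,
        phase: str | None = None,
        pigmentation: str | None = None,
    ) -> pd.DataFrame:
        """Filtered view of the underlying frame (may be empty)."""
        df = self.frame
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        if phase is not None:
            df = df[df["phase"] == phase]
        if pigmentation is not None:
            df = df[df["pigmentation"] == pigmentation]
        return df

    def pooled_means(
        self, tissue: str = "whole", phase: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(times, mean concentration) pooled over replicates for a tissue."""
        df = self.subset(tissue=tissue, phase=phase)
        g = df.groupby("time_h")["conc_mg_per_kg"].mean().sort_index()
        return g.index.to_numpy(float), g.to_numpy(float)

    def n_time_points(self, tissue: str = "whole") -> int:
        return self.subset(tissue=tissue)["time_h"].nunique()
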