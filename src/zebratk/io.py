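"""CSV/JSON readers and writers for the package's tabular artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DoseResponseData
from .exceptions import DataError
from .timecourse import COLUMNS, TimeCourseDataset

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_zfet",
    "write_zfet",
    "write_json",
]

ZFET_COLUMNS = ["conc_um", "n_exposed", "n_responding", "endpoint"]


def read_timecourse(path) -> TimeCourseDataset:
    """Read and validate a time-course CSV.

    Expected header: replicate_id, phase, time_h, tissue, pigmentation,
    conc_mg_per_kg.  Malformed rows are reported by number (0-based data
    rows, header excluded).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty file") from None
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    try:
        return TimeCourseDataset(df)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from None


def write_timecourse(data: TimeCourseDataset, path) -> None:
    data.frame.to_csv(path, index=False)


def read_zfet(path) -> DoseResponseData:
    """Read a dose-response outcome CSV (conc_um, n_exposed, n_responding, endpoint)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty file") from None
    missing = [c for c in ZFET_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    endpoint = "lethal"
    if "endpoint" in df.columns:
        labels = df["endpoint"].unique()
        if len(labels) != 1:
            raise DataError(f"{path}: mixed endpoint labels {list(labels)}")
        endpoint = str(labels[0])
    try:
        return DoseResponseData(
            conc_um=df["conc_um"].to_numpy(float),
            n_exposed=df["n_exposed"].to_numpy(int),
            n_responding=df["n_responding"].to_numpy(int),
            endpoint=endpoint,
        )
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from None


def write_zfet(data: DoseResponseData, path) -> None:
    pd.DataFrame(
        {
            "conc_um": data.conc_um,
            "n_exposed": data.n_exposed,
            "n_responding": data.n_responding,
            "endpoint": data.endpoint,
        }
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):  # NaN/inf -> null
        return None
    return obj


def write_json(obj, path) -> None:
    """Serialize with sorted keys and full float precision (deterministic)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
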