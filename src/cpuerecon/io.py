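"""Schema-validated CSV readers/writers for the pipeline's tabular formats.

All files are UTF-8 CSV with a header row; timestamps are ISO-8601.
Readers collect rows violating the schema into a rejects report (with the
original line numbers) instead of failing, but missing required columns are
fatal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table", "read_config", "write_config"]


def _positive(col):
    return lambda df: df[col] > 0


def _nonnegative(col):
    return lambda df: df[col].isna() | (df[col] >= 0)


SCHEMAS = {
    "landings": {
        "required": ["vessel_id", "date", "port", "weight_kg", "fish_count"],
        "numeric": ["weight_kg", "fish_count"],
        "datetime": ["date"],
        "row_checks": [("weight_kg > 0", _positive("weight_kg")),
                       ("fish_count >= 0", _nonnegative("fish_count"))],
    },
    "tracks": {
        "required": ["vessel_id", "timestamp", "lat", "lon", "speed_kn"],
        "numeric": ["lat", "lon", "speed_kn"],
        "datetime": ["timestamp"],
        "row_checks": [
            ("|lat| <= 90", lambda df: df["lat"].abs() <= 90),
            ("|lon| <= 180", lambda df: df["lon"].abs() <= 180),
            ("speed_kn >= 0", lambda df: df["speed_kn"] >= 0),
        ],
    },
    "trips": {
        "required": ["trip_id", "vessel_id", "port", "vessel_class", "depart", "return_"],
        "numeric": [],
        "datetime": ["depart", "return_"],
        "row_checks": [],
    },
    "cpue": {
        "required": ["trip_id", "year", "month", "area", "vessel_class",
                     "fishing_days", "catch_n"],
        "numeric": ["year", "month", "fishing_days", "catch_n"],
        "datetime": [],
        "row_checks": [("fishing_days > 0", _positive("fishing_days")),
                       ("catch_n >= 0", _nonnegative("catch_n"))],
    },
    "labels": {
        "required": ["vessel_id", "date", "is_fishing"],
        "numeric": [],
        "datetime": ["date"],
        "row_checks": [],
    },
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Returns the valid rows; rejected rows (with ``line`` numbers and a
    ``reject_reason``) are attached as ``df.attrs["rejects"]`` (a list of
    row dicts).  Missing required columns raise immediately, naming them.
    """
    spec = SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df["line"] = np.arange(2, len(df) + 2)  # header is line 1
    rejects = []
    for col in spec["numeric"]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rejects.append(df[bad].assign(reject_reason=f"non-numeric {col}"))
            df = df[~bad]
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in spec["datetime"]:
        parsed = pd.to_datetime(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            rejects.append(df[bad].assign(reject_reason=f"unparseable {col}"))
            df = df[~bad]
        df[col] = pd.to_datetime(df[col], errors="coerce")
    for label, check in spec["row_checks"]:
        ok = check(df)
        if (~ok).any():
            rejects.append(df[~ok].assign(reject_reason=f"violates {label}"))
            df = df[ok]
    out = df.drop(columns=["line"]).reset_index(drop=True)
    out.attrs["rejects"] = (
        pd.concat(rejects, ignore_index=True).to_dict("records") if rejects else []
    )
    return out


def write_table(df: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_config(cfg: dict, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
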