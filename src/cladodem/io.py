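"""CSV schemas and low-level table readers/writers.

All six tables are plain UTF-8 CSV with a header row; missing loss causes
are written as ``NA``.  Floats round-trip losslessly (shortest-repr
serialization of IEEE doubles).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMAS: dict[str, list[str]] = {
    "survival": [
        "plant_id",
        "gender",
        "cladode_id",
        "last_log_size",
        "alive",
        "loss_cause",
    ],
    "growth": ["plant_id", "gender", "cladode_id", "day", "log_size"],
    "shrink_attached": [
        "plant_id",
        "gender",
        "cladode_id",
        "max_log_size",
        "min_log_size",
        "interval_days",
    ],
    "shrink_detached": ["cladode_id", "gender", "weight0_g", "weight1_g", "interval_days"],
    "flowering": ["plant_id", "gender", "terminal_total", "terminal_flowering"],
    "clonality": ["cladode_id", "gender", "rooted", "budded"],
}

FILENAMES = {name: f"{name}.csv" for name in SCHEMAS}


class TableSchemaError(ValueError):
    """A table does not match its declared schema."""


def write_table(df: pd.DataFrame, name: str, directory: str | Path) -> Path:
    if name not in SCHEMAS:
        raise KeyError(f"unknown table {name!r}")
    path = Path(directory) / FILENAMES[name]
    df.to_csv(path, index=False, na_rep="NA")
    return path


def read_table(name: str, directory: str | Path) -> pd.DataFrame:
    if name not in SCHEMAS:
        raise KeyError(f"unknown table {name!r}")
    path = Path(directory) / FILENAMES[name]
    df = pd.read_csv(path, na_values=["NA"])
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{path}: missing columns {missing}")
    return df[SCHEMAS[name]]
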