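"""The feature-table dialect shared across the pipeline.

A feature table is a pandas DataFrame with metadata columns ``sample_id``
and ``group`` followed by named numeric descriptor columns — the common
currency between texture extraction, the synthetic generators, feature
selection and clustering.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["META_COLUMNS", "feature_columns", "feature_matrix", "read_table", "write_table"]

META_COLUMNS = ("sample_id", "group")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Descriptor column names: everything except the metadata columns."""
    return [c for c in table.columns if c not in META_COLUMNS]


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Descriptor values as a float matrix, one row per sample."""
    X = table[feature_columns(table)].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    return X


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV, validating the dialect."""
    df = pd.read_csv(path)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"feature table {path} lacks required column {col!r}")
    return df


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
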