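"""Reading, writing and validation of expression and clinical tables.

The canonical on-disk dialect is TSV: first column holds gene (or sample)
identifiers, the header row holds sample (or feature) identifiers.  CSV is
auto-detected on read.  Writers round-trip losslessly with the readers
(``read(write(x)) == x``), which the test suite asserts for every table type.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "validate_expression",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "write_table",
    "read_table",
    "write_json",
]


class ValidationError(ValueError):
    """Raised when a table violates the structural contract of the pipeline."""


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def validate_expression(
    X: pd.DataFrame,
    *,
    impute_missing: bool = False,
    min_genes: int = 2,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Validate (and optionally repair) a genes × samples expression matrix.

    Requirements: unique gene and sample labels, at least ``min_genes`` rows
    and ``min_samples`` columns, numeric values, and no missing entries.
    Missing values are rejected unless ``impute_missing`` is set, in which
    case each gene's missing entries are replaced by that gene's mean.
    """
    if X.index.duplicated().any():
        dups = X.index[X.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    if X.columns.duplicated().any():
        dups = X.columns[X.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    if X.shape[0] < min_genes or X.shape[1] < min_samples:
        raise ValidationError(
            f"matrix too small: {X.shape[0]} genes × {X.shape[1]} samples "
            f"(need ≥ {min_genes} × {min_samples})"
        )
    X = X.astype(float)
    values = X.to_numpy()
    if not np.isfinite(values).all():
        if not impute_missing:
            n_bad = int((~np.isfinite(values)).sum())
            raise ValidationError(
                f"{n_bad} non-finite entries; pass impute_missing=True to "
                "replace them with per-gene means"
            )
        values = np.where(np.isfinite(values), values, np.nan)
        row_means = np.nanmean(values, axis=1, keepdims=True)
        if not np.isfinite(row_means).all():
            bad = X.index[~np.isfinite(row_means).ravel()].tolist()
            raise ValidationError(f"genes with no finite values: {bad[:5]}")
        values = np.where(np.isnan(values), np.broadcast_to(row_means, values.shape), values)
        X = pd.DataFrame(values, index=X.index, columns=X.columns)
    return X


def read_expression(path: str | Path, *, impute_missing: bool = False) -> pd.DataFrame:
    """Read a genes × samples matrix from delimited text (TSV/CSV)."""
    path = Path(path)
    X = pd.read_csv(path, sep=_detect_sep(path), index_col=0, float_precision="round_trip")
    X.index = X.index.astype(str)
    X.columns = X.columns.astype(str)
    X.index.name = None
    return validate_expression(X, impute_missing=impute_missing)


def write_expression(X: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    X.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a samples × features clinical table (numeric; NaN permitted)."""
    path = Path(path)
    C = pd.read_csv(path, sep=_detect_sep(path), index_col=0, float_precision="round_trip")
    C.index = C.index.astype(str)
    C.columns = C.columns.astype(str)
    non_numeric = [c for c in C.columns if not np.issubdtype(C[c].dtype, np.number)]
    if non_numeric:
        raise ValidationError(
            f"clinical features must be numerically encoded; offending columns: "
            f"{non_numeric} (categorical features are not silently coerced)"
        )
    if C.index.duplicated().any():
        raise ValidationError("duplicate sample ids in clinical table")
    C.index.name = None
    return C.astype(float)


def write_clinical(C: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    C.to_csv(path, sep="\t", index_label="sample_id")


def write_table(df: pd.DataFrame, path: str | Path, *, index_label: str = "id") -> None:
    """Generic labeled-table writer (TSV)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
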