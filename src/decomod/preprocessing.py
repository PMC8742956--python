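"""Pre-processing: outlier-sample removal and gene-wise standardization.

Both steps run before any decomposition.  Outliers are flagged by their
standardized network connectivity — the z-scored row sum of the off-diagonal
sample–sample Pearson correlation matrix — a common QC convention for
expression data.  Normalization centers and standardizes every gene across
samples so that downstream decompositions see unit-variance rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "remove_outlier_samples",
    "normalize_expression",
    "sample_connectivity_z",
    "drop_constant_genes",
]


def sample_connectivity_z(X: pd.DataFrame) -> pd.Series:
    """Standardized connectivity of each sample.

    Connectivity of sample *i* is the sum of its Pearson correlations with
    every other sample (computed over genes); the vector of connectivities is
    then z-scored across samples.  A mutually identical set of samples has
    zero spread, in which case all z-scores are defined as 0.
    """
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    np.fill_diagonal(corr, 0.0)
    k = corr.sum(axis=1)
    sd = k.std(ddof=0)
    z = np.zeros_like(k) if sd == 0 else (k - k.mean()) / sd
    return pd.Series(z, index=X.columns, name="connectivity_z")


def remove_outlier_samples(
    X: pd.DataFrame, z_cut: float = -2.5
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples whose standardized connectivity falls below ``z_cut``.

    Parameters
    ----------
    X : genes × samples expression matrix.
    z_cut : negative cutoff on the connectivity z-score (default −2.5).

    Returns the filtered matrix (sample order preserved) and the list of
    removed sample ids.  Raises if ``z_cut`` is non-negative or if fewer than
    3 samples would remain.
    """
    if z_cut >= 0:
        raise ValueError(f"z_cut must be negative, got {z_cut}")
    z = sample_connectivity_z(X)
    removed = [s for s in X.columns if z[s] < z_cut]
    kept = [s for s in X.columns if s not in removed]
    if len(kept) < 3:
        raise ValueError(
            f"outlier removal would leave {len(kept)} samples (< 3); "
            "relax z_cut or inspect the data"
        )
    return X[kept], removed


def normalize_expression(X: pd.DataFrame) -> pd.DataFrame:
    """Center and standardize each gene across samples (population sd).

    Every row of the result has mean 0 and standard deviation 1 (dividing by
    n, not n−1).  Idempotent to numerical precision.  A zero-variance gene is
    a hard error naming the gene; drop constant genes first if needed.
    """
    values = X.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    zero = sd.ravel() == 0
    if zero.any():
        bad = X.index[zero].tolist()
        raise ValueError(f"zero variance gene(s): {bad[:10]}")
    return pd.DataFrame((values - mu) / sd, index=X.index, columns=X.columns)


def drop_constant_genes(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove zero-variance genes; returns (filtered matrix, dropped ids)."""
    sd = X.to_numpy(dtype=float).std(axis=1, ddof=0)
    dropped = X.index[sd == 0].tolist()
    return X.loc[sd != 0], dropped
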