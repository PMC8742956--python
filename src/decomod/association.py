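"""Module–trait association and pattern-vs-eigengene comparison.

A module's *pattern* (its sample-space component) summarizes the module as
one profile per sample; correlating each pattern with each clinical feature
(Pearson r, pairwise-complete, two-sided t-test p-value with n−2 degrees of
freedom) yields the module–trait table.  Benjamini–Hochberg adjusted
p-values are reported alongside the raw ones.

For comparison with hard-clustering tools the *module eigengene* — the first
principal component of a gene set's normalized expression submatrix — plays
the role of the pattern; ``compare_patterns_to_eigengenes`` cross-correlates
the two panels and flags patterns no eigengene reaches (|r| < r_cut) as
"missed" and eigengenes some pattern reaches as "captured".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assign import ModuleSet
from .decomposition import DecompositionResult
from .preprocessing import normalize_expression

__all__ = [
    "AssociationTable",
    "module_trait_correlation",
    "compute_eigengene",
    "compare_patterns_to_eigengenes",
]

logger = logging.getLogger(__name__)


@dataclass
class AssociationTable:
    r: pd.DataFrame  # modules × features
    p: pd.DataFrame
    p_adjusted: pd.DataFrame  # Benjamini–Hochberg over the whole table
    n_used: pd.DataFrame  # pairwise-complete sample counts

    def to_frame(self) -> pd.DataFrame:
        """Long form: module, feature, r, p, p_bh, n."""
        rows = []
        for m in self.r.index:
            for f in self.r.columns:
                rows.append(
                    (m, f, self.r.at[m, f], self.p.at[m, f], self.p_adjusted.at[m, f],
                     self.n_used.at[m, f])
                )
        return pd.DataFrame(rows, columns=["module", "feature", "r", "p", "p_bh", "n"])


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with two-sided t-test p (df = n−2)."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xv, yv = x[ok], y[ok]
    if xv.std(ddof=0) == 0 or yv.std(ddof=0) == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, np.finfo(float).tiny, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, max(p, np.finfo(float).tiny), n


def module_trait_correlation(
    R: DecompositionResult, M: ModuleSet, C: pd.DataFrame
) -> AssociationTable:
    """Correlate each module's pattern with each clinical feature.

    ``C`` is a samples × features table aligned to the expression samples by
    id (order-free); missing values are allowed and handled pairwise.  A
    module–feature pair with fewer than 3 complete samples gets a missing
    cell and a warning rather than a hard error.
    """
    shared = [s for s in R.patterns.columns if s in C.index]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} samples shared between patterns and clinical "
            "table (need ≥ 3); check sample ids"
        )
    comps = M.source_components or list(R.patterns.index[: len(M.module_ids)])
    features = list(C.columns)
    shape = (len(M.module_ids), len(features))
    r_mat = np.full(shape, np.nan)
    p_mat = np.full(shape, np.nan)
    n_mat = np.zeros(shape, dtype=int)
    for i, comp in enumerate(comps):
        pattern = R.patterns.loc[comp, shared].to_numpy(dtype=float)
        for j, f in enumerate(features):
            feat = C.loc[shared, f].to_numpy(dtype=float)
            r, p, n = _pearson_with_p(pattern, feat)
            if np.isnan(r):
                warnings.warn(
                    f"module {M.module_ids[i]} × feature {f!r}: fewer than 3 "
                    "complete pairs (or constant values); cell set to missing",
                    stacklevel=2,
                )
            r_mat[i, j], p_mat[i, j], n_mat[i, j] = r, p, n
    flat = p_mat.ravel()
    adj = np.full_like(flat, np.nan)
    ok = np.isfinite(flat)
    if ok.any():
        adj[ok] = stats.false_discovery_control(flat[ok], method="bh")
    idx, cols = M.module_ids, features
    return AssociationTable(
        r=pd.DataFrame(r_mat, index=idx, columns=cols),
        p=pd.DataFrame(p_mat, index=idx, columns=cols),
        p_adjusted=pd.DataFrame(adj.reshape(shape), index=idx, columns=cols),
        n_used=pd.DataFrame(n_mat, index=idx, columns=cols),
    )


def compute_eigengene(X: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """First principal component of the gene set's normalized submatrix.

    Returned over samples with unit (population) variance and sign oriented
    to correlate positively with the set's mean standardized profile.  A
    singleton set returns that gene's standardized profile directly.
    """
    missing = [g for g in gene_set if g not in X.index]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing[:5]}")
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    sub = normalize_expression(X.loc[list(gene_set)])
    values = sub.to_numpy()
    if len(gene_set) == 1:
        return pd.Series(values[0], index=X.columns, name="eigengene")
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    pc = Vt[0]
    mean_profile = values.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    sd = pc.std(ddof=0)
    pc = (pc - pc.mean()) / sd if sd > 0 else pc
    return pd.Series(pc, index=X.columns, name="eigengene")


def compare_patterns_to_eigengenes(
    R: DecompositionResult, eigengenes: pd.DataFrame, r_cut: float = 0.8
) -> dict:
    """Cross-correlate decomposition patterns with external module eigengenes.

    ``eigengenes`` is samples × eigengene columns.  Returns the full |r|
    matrix, per-pattern "missed" flags (max |r| < r_cut), per-eigengene
    "captured" flags (max |r| ≥ r_cut), and summary percentages on both
    sides.
    """
    if not (0.0 < r_cut < 1.0):
        raise ValueError(f"r_cut must be in (0, 1), got {r_cut}")
    shared = [s for s in R.patterns.columns if s in eigengenes.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between patterns and eigengenes")
    P = R.patterns[shared].to_numpy(dtype=float)
    E = eigengenes.loc[shared].to_numpy(dtype=float)
    n_p, n_e = P.shape[0], E.shape[1]
    r_abs = np.empty((n_p, n_e))
    for i in range(n_p):
        for j in range(n_e):
            r, _, _ = _pearson_with_p(P[i], E[:, j])
            r_abs[i, j] = abs(r)
    r_df = pd.DataFrame(r_abs, index=R.patterns.index, columns=eigengenes.columns)
    missed = r_df.max(axis=1) < r_cut
    captured = r_df.max(axis=0) >= r_cut
    return {
        "abs_r": r_df,
        "pattern_missed": missed,
        "eigengene_captured": captured,
        "pct_patterns_matched": 100.0 * float((~missed).mean()),
        "pct_eigengenes_captured": 100.0 * float(captured.mean()),
        "r_cut": r_cut,
    }
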