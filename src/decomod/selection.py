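"""Choosing the number of components by permutation (parallel analysis).

The observed statistic for candidate j is the fraction of total variance
carried by the j-th singular value of the normalized matrix.  For each of B
permutations the entries of every gene row are independently shuffled across
samples — destroying gene–gene correlation while preserving each gene's
marginal distribution — and the statistic is recomputed.  The +1-corrected
empirical p-value for candidate j compares the observed statistic with its
permutation distribution; the chosen number of components is the length of
the initial run of candidates significant at level alpha.

A companion heuristic recommends ICA or IPCA at the chosen k: the method
retaining more heavy-tailed (kurtosis ≥ 3) signatures wins, with ties broken
toward IPCA, which is more robust to dense noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import DecompositionConfig, decompose
from .nongaussian import kurtosis

__all__ = ["ComponentSelectionReport", "permutation_select_k", "recommend_method"]


@dataclass
class ComponentSelectionReport:
    candidate_counts: list[int]
    observed_stat: np.ndarray
    perm_pvalues: np.ndarray
    chosen_k: int
    recommended_method: str | None
    n_permutations: int
    alpha: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate_k": self.candidate_counts,
                "variance_fraction": self.observed_stat,
                "perm_pvalue": self.perm_pvalues,
                "significant": self.perm_pvalues < self.alpha,
            }
        ).set_index("candidate_k")


def _variance_fractions(values: np.ndarray, k_max: int) -> np.ndarray:
    s = np.linalg.svd(values, compute_uv=False)
    frac = s**2 / np.sum(s**2)
    return frac[:k_max]


def permutation_select_k(
    X: pd.DataFrame,
    k_max: int,
    B: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> ComponentSelectionReport:
    """Permutation test for the number of non-random principal components.

    Parameters
    ----------
    X : normalized genes × samples matrix.
    k_max : largest candidate count (≤ min(dims)).
    B : number of within-row permutations (≥ 19 so the smallest attainable
        p-value 1/(B+1) resolves the default alpha).
    alpha : significance level for the run-length decision rule.
    seed : seed for the permutation generator.

    Returns a report with per-candidate observed variance fractions,
    permutation p-values, and ``chosen_k`` = the largest m such that all
    candidates j ≤ m have p < alpha (0 when the first candidate is null).
    """
    if B < 19:
        raise ValueError(f"B must be ≥ 19 for usable p-value resolution, got {B}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    values = np.asarray(X, dtype=float)
    if k_max < 1 or k_max > min(values.shape):
        raise ValueError(f"k_max must be in [1, min(dims)], got {k_max}")
    observed = _variance_fractions(values, k_max)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(k_max, dtype=int)
    for _ in range(B):
        perm = rng.permuted(values, axis=1)
        exceed += _variance_fractions(perm, k_max) >= observed
    pvals = (1.0 + exceed) / (B + 1.0)
    significant = pvals < alpha
    chosen_k = int(np.argmin(significant)) if not significant.all() else k_max
    return ComponentSelectionReport(
        candidate_counts=list(range(1, k_max + 1)),
        observed_stat=observed,
        perm_pvalues=pvals,
        chosen_k=chosen_k,
        recommended_method=None,
        n_permutations=B,
        alpha=alpha,
        seed=seed,
    )


def recommend_method(
    X: pd.DataFrame, chosen_k: int, seed: int = 0, kurtosis_threshold: float = 3.0
) -> str:
    """Recommend ICA or IPCA at the chosen component count.

    Both decompositions are run; the method whose signatures include more
    columns with kurtosis ≥ ``kurtosis_threshold`` is recommended.  Ties go
    to IPCA.
    """
    if chosen_k < 1:
        raise ValueError(
            "chosen_k is 0: no non-random structure was found, so there is "
            "no component count at which to compare methods"
        )
    counts = {}
    for method in ("ICA", "IPCA"):
        cfg = DecompositionConfig(method=method, n_components=chosen_k, seed=seed)
        result = decompose(X, cfg)
        sig = result.signatures.to_numpy()
        counts[method] = int(
            sum(kurtosis(sig[:, j]) >= kurtosis_threshold for j in range(sig.shape[1]))
        )
    return "ICA" if counts["ICA"] > counts["IPCA"] else "IPCA"
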