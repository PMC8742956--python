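"""Matching recovered components to planted truth up to permutation and sign.

Decompositions are identifiable only up to component order and sign, so any
comparison with a reference factorization must first solve an assignment
problem.  `match_by_correlation` builds the |Pearson r| matrix between two
sets of vectors and finds the optimal one-to-one pairing (Hungarian
algorithm), returning the pairing and the matched |r| values.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["match_by_correlation", "jaccard"]


def match_by_correlation(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Optimal pairing of columns of ``estimated`` with columns of ``reference``.

    Returns ``(pairs, matched_abs_r)`` where ``pairs[i] = (est_col, ref_col)``
    and ``matched_abs_r[i]`` is the absolute Pearson correlation of that pair.
    """
    E = np.asarray(estimated, dtype=float)
    R = np.asarray(reference, dtype=float)
    n_e, n_r = E.shape[1], R.shape[1]
    corr = np.zeros((n_e, n_r))
    for i in range(n_e):
        for j in range(n_r):
            corr[i, j] = abs(np.corrcoef(E[:, i], R[:, j])[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    return pairs, corr[rows, cols]


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two boolean membership vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
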