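"""Kurtosis-based retention of non-Gaussian signatures.

Decomposition is only informative for module detection when a signature's
weight distribution across genes is heavy-tailed: a handful of genes in the
tails drive the component while the bulk near the center is inert.  Tailedness
is measured by Pearson (non-excess) kurtosis, m4/m2², for which the Gaussian
reference value is 3; signatures below the threshold (default 3) are dropped
together with their paired patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DecompositionResult

__all__ = ["kurtosis", "filter_signatures", "SignatureFilterResult"]


def kurtosis(x: np.ndarray) -> float:
    """Pearson kurtosis m4/m2² (moments about the sample mean, no bias
    correction).  Gaussian → 3; ±1 two-point → 1; Laplace → 6.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if x.std(ddof=0) == 0:
        raise ValueError("zero-variance vector has undefined kurtosis")
    return float(stats.kurtosis(x, fisher=False, bias=True))


@dataclass
class SignatureFilterResult:
    """Per-signature kurtosis and the indices retained at the threshold."""

    kurtosis_values: np.ndarray
    kept_indices: list[int]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "signature": np.arange(1, len(self.kurtosis_values) + 1),
                "kurtosis": self.kurtosis_values,
                "kept": [i in set(self.kept_indices) for i in range(len(self.kurtosis_values))],
            }
        ).set_index("signature")


def filter_signatures(
    R: DecompositionResult, threshold: float = 3.0
) -> SignatureFilterResult:
    """Retain signatures whose gene-space kurtosis is ≥ ``threshold``.

    Survivor order is preserved.  Dropping every signature is a hard error:
    it means no component is heavy-tailed, so a different component count or
    decomposition method should be tried.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    sig = R.signatures.to_numpy()
    kurt = np.array([kurtosis(sig[:, j]) for j in range(sig.shape[1])])
    kept = [int(j) for j in range(sig.shape[1]) if kurt[j] >= threshold]
    if not kept:
        raise ValueError(
            "all signatures are Gaussian-like (kurtosis < "
            f"{threshold}); try a different number of components or the "
            "other decomposition method"
        )
    return SignatureFilterResult(kurtosis_values=kurt, kept_indices=kept, threshold=threshold)
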