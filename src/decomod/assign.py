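"""Gene-to-module assignment from retained signatures.

Each retained signature defines one module; a gene joins the module when its
weight sits far enough in the tails.  Two assignment rules are provided:

* **tail-area FDR** — the signature is modeled as a two-component mixture of
  a null (Gaussian) distribution and an alternative carrying the tails.  The
  null is fitted robustly around the median (location = median, scale =
  1.4826·MAD) so the alternative tails do not contaminate it, the null
  proportion η₀ is estimated from the central mass, and each gene receives a
  tail-area false discovery rate
  ``Fdr(z) = η₀ · P(|Z| ≥ |z|) / ECDF(|z|)``, made monotone non-increasing
  in |z|.  Genes with Fdr below the threshold (default 0.001) are assigned.
* **z-score** — the signature is z-transformed with its own mean and sd and
  genes with |z| above a sigma threshold (default 3) are assigned.

Because every signature is thresholded independently, a gene may belong to
any number of modules — overlap is permitted by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DecompositionResult
from .nongaussian import SignatureFilterResult

__all__ = [
    "TailFdrFit",
    "ModuleSet",
    "fit_tail_fdr",
    "assign_fdr",
    "assign_zscore",
    "detect_modules",
]

logger = logging.getLogger(__name__)

ASSIGN_METHODS = ("ICA-FDR", "ICA-Zscore", "IPCA-FDR")


@dataclass
class TailFdrFit:
    """Fitted two-component mixture for one signature."""

    eta0: float
    null_center: float
    null_scale: float
    fdr_per_gene: np.ndarray
    zscores: np.ndarray


@dataclass
class ModuleSet:
    """Overlapping gene modules: membership, weights and provenance."""

    membership: pd.DataFrame  # genes × modules, boolean
    weights: pd.DataFrame  # genes × modules, signature loadings
    method: str
    threshold: float
    # decomposition component backing each module, aligned with module_ids
    source_components: list[str] | None = None

    @property
    def module_ids(self) -> list[str]:
        return list(self.membership.columns)

    def module_genes(self, module_id: str) -> list[str]:
        mask = self.membership[module_id].to_numpy()
        return self.membership.index[mask].tolist()

    def sizes(self) -> pd.Series:
        return self.membership.sum(axis=0)

    def to_long_frame(self) -> pd.DataFrame:
        """Long form: one row per (gene, module) membership, with weight."""
        rows = []
        for m in self.module_ids:
            for g in self.module_genes(m):
                rows.append((g, m, float(self.weights.at[g, m])))
        return pd.DataFrame(rows, columns=["gene", "module", "weight"])


def fit_tail_fdr(signature: np.ndarray) -> TailFdrFit:
    """Fit the median-centered Gaussian null and compute tail-area FDR.

    The empirical two-sided tail ``ECDF(|z|)`` counts genes at least as
    extreme as each gene (inclusive, so it is never 0); η₀ compares the
    observed central mass inside the 75th percentile of |z| with the mass a
    standard Gaussian would put there, capped at 1.  The raw ratio
    ``η₀·2(1−Φ(|z|))/ECDF(|z|)`` is clipped to [0, 1] and smoothed to be
    monotone non-increasing in |z| (a less extreme gene never gets a smaller
    FDR than a more extreme one).
    """
    w = np.asarray(signature, dtype=float)
    if w.size < 50:
        raise ValueError(f"need at least 50 genes to fit the null, got {w.size}")
    center = float(np.median(w))
    mad = float(np.median(np.abs(w - center)))
    scale = 1.4826 * mad
    if scale == 0:
        raise ValueError("degenerate signature: MAD is 0, null scale undefined")
    z = (w - center) / scale
    az = np.abs(z)

    t = float(np.quantile(az, 0.75))
    expected_mass = 2.0 * stats.norm.cdf(t) - 1.0
    observed_mass = float(np.mean(az <= t))
    eta0 = min(1.0, observed_mass / expected_mass) if expected_mass > 0 else 1.0

    order = np.argsort(az, kind="stable")
    n = az.size
    # inclusive two-sided survival ECDF: fraction with |z| >= |z_g|
    ranks = np.empty(n, dtype=float)
    sorted_az = az[order]
    # genes with equal |z| share the same (largest) tail count
    right = np.searchsorted(sorted_az, sorted_az, side="left")
    ranks[order] = (n - right) / n
    raw = np.minimum(1.0, eta0 * 2.0 * stats.norm.sf(az) / ranks)

    # enforce monotonicity: traverse from the most extreme gene inward,
    # carrying the running maximum so fdr never drops as |z| shrinks
    fdr = raw.copy()
    fdr_sorted = fdr[order[::-1]]
    fdr_sorted = np.maximum.accumulate(fdr_sorted)
    fdr[order[::-1]] = fdr_sorted

    return TailFdrFit(eta0=eta0, null_center=center, null_scale=scale, fdr_per_gene=fdr, zscores=z)


def assign_fdr(signature: np.ndarray, q: float = 0.001) -> np.ndarray:
    """Boolean membership: tail-area FDR strictly below ``q``."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0, 1), got {q}")
    fit = fit_tail_fdr(signature)
    return fit.fdr_per_gene < q


def assign_zscore(signature: np.ndarray, k_sigma: float = 3.0) -> np.ndarray:
    """Boolean membership: |z-score| strictly above ``k_sigma``."""
    if k_sigma <= 0:
        raise ValueError(f"k_sigma must be positive, got {k_sigma}")
    w = np.asarray(signature, dtype=float)
    sd = w.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance signature")
    z = (w - w.mean()) / sd
    return np.abs(z) > k_sigma


def detect_modules(
    R: DecompositionResult,
    F: SignatureFilterResult,
    method: str,
    threshold: float | None = None,
) -> ModuleSet:
    """Build the overlapping module set from the retained signatures.

    ``method`` pairs an upstream decomposition with an assignment rule:
    "ICA-FDR" and "ICA-Zscore" require an ICA decomposition, "IPCA-FDR"
    requires IPCA.  Modules are labeled oM1, oM2, … in retained-signature
    order; empty modules are dropped with a logged warning and survivors
    renumbered.
    """
    if method not in ASSIGN_METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {ASSIGN_METHODS}")
    decomp = R.config.method
    expected = "IPCA" if method == "IPCA-FDR" else "ICA"
    if decomp != expected:
        raise ValueError(
            f"method {method!r} requires a {expected} decomposition but the "
            f"result was produced by {decomp}; valid pairings are ICA with "
            "ICA-FDR/ICA-Zscore and IPCA with IPCA-FDR"
        )
    if threshold is None:
        threshold = 3.0 if method == "ICA-Zscore" else 0.001

    sig = R.signatures.to_numpy()
    columns, weights, comp_ids = [], [], []
    for j in F.kept_indices:
        s = sig[:, j]
        if method == "ICA-Zscore":
            member = assign_zscore(s, threshold)
        else:
            member = assign_fdr(s, threshold)
        columns.append(member)
        weights.append(s)
        comp_ids.append(R.signatures.columns[j])

    kept_cols, kept_w, kept_comp = [], [], []
    for i, member in enumerate(columns):
        if member.any():
            kept_cols.append(member)
            kept_w.append(weights[i])
            kept_comp.append(comp_ids[i])
        else:
            logger.warning("signature %d produced an empty module; dropped", F.kept_indices[i] + 1)
    if not kept_cols:
        raise ValueError(
            f"no genes pass the {method} threshold {threshold} in any retained signature"
        )
    module_ids = [f"oM{i + 1}" for i in range(len(kept_cols))]
    membership = pd.DataFrame(
        np.column_stack(kept_cols), index=R.signatures.index, columns=module_ids
    )
    weight_df = pd.DataFrame(
        np.column_stack(kept_w), index=R.signatures.index, columns=module_ids
    )
    return ModuleSet(
        membership=membership,
        weights=weight_df,
        method=method,
        threshold=threshold,
        source_components=kept_comp,
    )
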