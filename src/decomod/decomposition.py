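"""Matrix decomposition into gene signatures and sample patterns.

The expression matrix ``X`` (genes × samples) is factored as
``X ≈ S · P`` where the columns of ``S`` (the *signatures*) are weight
vectors over genes and the rows of ``P`` (the *patterns*) are the paired
profiles over samples.  Two backends are provided:

* **ICA** — symmetric (parallel-extraction) fixed-point FastICA run in gene
  space: each sample is treated as a linear mixture of latent gene-indexed
  sources, so the recovered sources are the signatures and are driven to be
  maximally non-Gaussian across genes (logcosh negentropy contrast,
  ``g(u) = tanh(α·u)``, α = 1 by default).
* **IPCA** — independent principal component analysis: the top-k left
  singular vectors (gene-space PCA loadings) are extracted first and
  deflation-mode FastICA is then applied to those loadings, yielding
  independent loading vectors that are more robust to dense noise.

Conventions: every signature is standardized to mean 0, sd 1 across genes
and sign-oriented so its largest-magnitude entry is positive; the
compensating scale is absorbed into the pattern so ``S · P`` is preserved.
All randomness (the initial unmixing matrix) is drawn from a seeded
generator, making results bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "DecompositionConfig",
    "DecompositionResult",
    "whiten",
    "fastica_parallel",
    "ipca_deflation",
    "decompose",
]

Method = Literal["ICA", "IPCA"]


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class DecompositionConfig:
    """Settings for a decomposition run.

    Parameters
    ----------
    method : "ICA" or "IPCA".
    n_components : number of components k (≤ min(n_genes, n_samples)).
    alpha : logcosh contrast parameter, in [1, 2].
    max_iter : fixed-point iteration cap.
    tol : convergence tolerance on the unmixing-matrix update.
    seed : mandatory seed for the random initial unmixing matrix.
    """

    method: Method
    n_components: int
    alpha: float = 1.0
    max_iter: int = 200
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("ICA", "IPCA"):
            raise ValueError(f"unknown method {self.method!r}; use 'ICA' or 'IPCA'")
        if self.n_components < 1:
            raise ValueError(f"n_components must be ≥ 1, got {self.n_components}")
        if not (1.0 <= self.alpha <= 2.0):
            raise ValueError(f"alpha must be in [1, 2], got {self.alpha}")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be ≥ 1 and tol > 0")


@dataclass
class DecompositionResult:
    """Signatures (genes × k), patterns (k × samples) and provenance."""

    signatures: pd.DataFrame
    patterns: pd.DataFrame
    config: DecompositionConfig
    converged: bool
    n_iter: int
    column_means: np.ndarray = field(repr=False, default=None)

    @property
    def component_ids(self) -> list[str]:
        return list(self.signatures.columns)

    def to_manifest(self) -> dict:
        d = asdict(self.config)
        return {"config": d, "converged": bool(self.converged), "n_iter": int(self.n_iter)}


def _effective_rank(s: np.ndarray) -> int:
    if s.size == 0:
        return 0
    tol = s[0] * max(s.size, 1) * np.finfo(float).eps
    return int((s > tol).sum())


def whiten(X: pd.DataFrame, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project onto the top-k principal directions and whiten.

    Column (per-sample) means are removed, then an SVD of the centered
    matrix gives the top-k gene-space signals, rescaled so that the
    covariance of the whitened rows over genes is the identity.

    Returns
    -------
    Z : (k, n_genes) whitened signals, ``Z Zᵀ / n_genes = I_k``.
    K : (k, n_samples) whitening transform, ``Z = K · Xcᵀ``-style operator
        applied to the centered matrix columns (``Z = (Xc @ K.T).T``).
    mean : (n_samples,) removed column means.
    """
    values = np.asarray(X, dtype=float)
    n_genes, n_samples = values.shape
    if k > min(n_genes, n_samples):
        raise ValueError(f"k={k} exceeds min(dims)={min(n_genes, n_samples)}")
    mean = values.mean(axis=0)
    Xc = values - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = _effective_rank(s)
    if k > rank:
        raise ValueError(f"k={k} exceeds effective rank {rank} of the centered matrix")
    # Z = sqrt(n_genes) * U_k^T ; K maps centered columns onto whitened rows
    Z = np.sqrt(n_genes) * U[:, :k].T
    K = (np.sqrt(n_genes) / s[:k])[:, None] * Vt[:k]
    return Z, K, mean


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W ← (W Wᵀ)^(−1/2) W via eigendecomposition of the symmetric Gram."""
    evals, evecs = np.linalg.eigh(W @ W.T)
    evals = np.clip(evals, np.finfo(float).tiny, None)
    return (evecs * (1.0 / np.sqrt(evals))) @ evecs.T @ W

def _logcosh(U: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    G = np.tanh(alpha * U)
    Gprime = alpha * (1.0 - G**2)
    return G, Gprime


def _ica_parallel_core(
    Z: np.ndarray, alpha: float, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, bool, int]:
    """Symmetric fixed-point FastICA on whitened data Z (k × n)."""
    k, n = Z.shape
    W = _sym_decorrelate(rng.standard_normal((k, k)))
    converged = False
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        U = W @ Z
        G, Gp = _logcosh(U, alpha)
        W_new = _sym_decorrelate(G @ Z.T / n - Gp.mean(axis=1)[:, None] * W)
        lim = float(np.max(np.abs(np.abs(np.diag(W_new @ W.T)) - 1.0)))
        W = W_new
        if lim < tol:
            converged = True
            n_iter = it
            break
    return W, converged, n_iter


def _ica_deflation_core(
    Z: np.ndarray, alpha: float, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, bool, int]:
    """One-unit FastICA with Gram–Schmidt deflation on whitened data Z (k × n)."""
    k, n = Z.shape
    W = np.zeros((k, k))
    all_converged = True
    total_iter = 0
    for j in range(k):
        w = rng.standard_normal(k)
        w -= W[:j].T @ (W[:j] @ w)
        w /= np.linalg.norm(w)
        converged = False
        for it in range(1, max_iter + 1):
            u = w @ Z
            g, gp = _logcosh(u, alpha)
            w_new = Z @ g / n - gp.mean() * w
            w_new -= W[:j].T @ (W[:j] @ w_new)
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new /= norm
            lim = abs(abs(float(w_new @ w)) - 1.0)
            w = w_new
            if lim < tol:
                converged = True
                break
        total_iter = max(total_iter, it)
        all_converged &= converged
        W[j] = w
    return W, all_converged, total_iter


def _finalize(
    X: pd.DataFrame,
    sources: np.ndarray,
    Xc: np.ndarray,
    mean: np.ndarray,
    cfg: DecompositionConfig,
    converged: bool,
    n_iter: int,
) -> DecompositionResult:
    """Standardize signatures, orient signs, derive patterns by projection.

    Patterns are the least-squares coefficients expressing the centered
    matrix in the signature basis, so ``signatures @ patterns`` equals the
    rank-k PCA truncation of the centered data exactly.
    """
    k = sources.shape[1]
    sd = sources.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("degenerate (zero-variance) source extracted")
    mu = sources.mean(axis=0)
    S = (sources - mu) / sd
    flips = np.where(S[np.argmax(np.abs(S), axis=0), np.arange(k)] < 0, -1.0, 1.0)
    S *= flips
    P, *_ = np.linalg.lstsq(S, Xc, rcond=None)
    comp_ids = [f"C{i + 1}" for i in range(k)]
    return DecompositionResult(
        signatures=pd.DataFrame(S, index=X.index, columns=comp_ids),
        patterns=pd.DataFrame(P, index=comp_ids, columns=X.columns),
        config=cfg,
        converged=converged,
        n_iter=n_iter,
        column_means=mean,
    )


def fastica_parallel(X: pd.DataFrame, cfg: DecompositionConfig) -> DecompositionResult:
    """Symmetric FastICA in gene space.

    The matrix is whitened to k signals over genes, then the orthogonal
    unmixing matrix W is estimated by the parallel fixed-point update with
    symmetric decorrelation each sweep.  Signatures are the estimated
    sources (one weight per gene); patterns are the matched least-squares
    sample profiles.  Non-convergence yields ``converged=False`` and a
    warning, never an exception.
    """
    if cfg.method != "ICA":
        raise ValueError("fastica_parallel requires cfg.method == 'ICA'")
    Z, _, mean = whiten(X, cfg.n_components)
    rng = np.random.default_rng(cfg.seed)
    W, converged, n_iter = _ica_parallel_core(Z, cfg.alpha, cfg.max_iter, cfg.tol, rng)
    if not converged:
        warnings.warn(
            f"FastICA (parallel) did not converge in {cfg.max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    sources = (W @ Z).T  # genes × k
    Xc = np.asarray(X, dtype=float) - mean
    return _finalize(X, sources, Xc, mean, cfg, converged, n_iter)


def ipca_deflation(X: pd.DataFrame, cfg: DecompositionConfig) -> DecompositionResult:
    """Independent principal component analysis (deflation extraction).

    PCA first: the top-k left singular vectors of the column-centered
    matrix are the gene-space loadings.  Deflation-mode FastICA with the
    logcosh contrast is then run on those loadings (after whitening their
    scale) to rotate them into independent loading vectors — the
    signatures.  Patterns are the least-squares projections of the samples
    onto the independent loadings.
    """
    if cfg.method != "IPCA":
        raise ValueError("ipca_deflation requires cfg.method == 'IPCA'")
    Z, _, mean = whiten(X, cfg.n_components)  # rows: whitened loadings over genes
    rng = np.random.default_rng(cfg.seed)
    W, converged, n_iter = _ica_deflation_core(Z, cfg.alpha, cfg.max_iter, cfg.tol, rng)
    if not converged:
        warnings.warn(
            f"FastICA (deflation) did not converge in {cfg.max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    sources = (W @ Z).T  # independent loadings, genes × k
    Xc = np.asarray(X, dtype=float) - mean
    return _finalize(X, sources, Xc, mean, cfg, converged, n_iter)


def decompose(X: pd.DataFrame, cfg: DecompositionConfig) -> DecompositionResult:
    """Dispatch to the configured backend (ICA → parallel, IPCA → deflation)."""
    if cfg.method == "ICA":
        return fastica_parallel(X, cfg)
    if cfg.method == "IPCA":
        return ipca_deflation(X, cfg)
    raise ValueError(f"unknown method {cfg.method!r}")
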