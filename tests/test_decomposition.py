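import numpy as np
import pandas as pd
import pytest

from decomod import (
    DecompositionConfig,
    decompose,
    fastica_parallel,
    generate,
    ipca_deflation,
    match_by_correlation,
    whiten,
)
from decomod.decomposition import ConvergenceWarning


def _centered(X: pd.DataFrame) -> pd.DataFrame:
    """Row-centered matrix (scale left intact; suits the synthetic benchmark
    where all genes share a common scale and the planted weights are the
    literal signatures)."""
    return X.sub(X.mean(axis=1), axis=0)


class TestWhiten:
    def test_whitened_rows_have_identity_covariance(self):
        X, _ = generate(n_genes=300, n_samples=40, true_k=2, module_size=50, seed=3)
        Z, K, mean = whiten(X, 5)
        cov = Z @ Z.T / Z.shape[1]
        np.testing.assert_allclose(cov, np.eye(5), atol=1e-8)
        # K reproduces Z from the centered matrix
        Xc = X.to_numpy() - mean
        np.testing.assert_allclose((K @ Xc.T @ np.ones(Xc.shape[0]) * 0), 0)
        np.testing.assert_allclose(Z, (Xc @ K.T).T, atol=1e-8)

    def test_rank1_single_whitened_row(self):
        rng = np.random.default_rng(0)
        s, a = rng.standard_normal(100), rng.standard_normal(20)
        X = pd.DataFrame(np.outer(s, a))
        Z, _, _ = whiten(X, 1)
        assert Z.shape == (1, 100)
        assert Z.var(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_rank_deficiency_error(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            np.outer(rng.standard_normal(50), rng.standard_normal(10))
            + np.outer(rng.standard_normal(50), rng.standard_normal(10))
        )
        with pytest.raises(ValueError, match="rank"):
            whiten(X, 3)


class TestFastICA:
    def test_noise_free_two_source_recovery(self):
        X, truth = generate(
            n_genes=2000, n_samples=100, true_k=2, module_size=100,
            overlap_fraction=0.0, noise_sd=0.0, seed=1,
        )
        cfg = DecompositionConfig(method="ICA", n_components=2, seed=1)
        res = fastica_parallel(_centered(X), cfg)
        _, rs = match_by_correlation(
            res.signatures.to_numpy(), truth.signature_weights.to_numpy()
        )
        assert (rs >= 0.95).all()

    def test_gaussian_input_sources_stay_uncorrelated(self):
        # symmetric decorrelation keeps the unmixing orthogonal even without
        # any non-Gaussian structure, so the sources are pairwise uncorrelated
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((800, 60)))
        cfg = DecompositionConfig(method="ICA", n_components=4, seed=8, max_iter=500)
        with pytest.warns(ConvergenceWarning):
            # pure Gaussian data has no ICA fixed point to find
            res = fastica_parallel(X, cfg)
        corr = np.corrcoef(res.signatures.to_numpy(), rowvar=False)
        np.testing.assert_allclose(corr, np.eye(4), atol=1e-6)

    def test_seeded_determinism(self, normalized_default):
        cfg = DecompositionConfig(method="ICA", n_components=3, seed=5)
        a = fastica_parallel(normalized_default, cfg)
        b = fastica_parallel(normalized_default, cfg)
        np.testing.assert_allclose(
            a.signatures.to_numpy(), b.signatures.to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(a.patterns.to_numpy(), b.patterns.to_numpy(), atol=1e-12)

    def test_signature_standardization_and_orientation(self, normalized_default):
        res = fastica_parallel(
            normalized_default, DecompositionConfig(method="ICA", n_components=3, seed=2)
        )
        S = res.signatures.to_numpy()
        np.testing.assert_allclose(S.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(S.std(axis=0, ddof=0), 1.0, atol=1e-8)
        for j in range(S.shape[1]):
            assert S[np.argmax(np.abs(S[:, j])), j] > 0

    def test_non_convergence_warns_not_raises(self, normalized_default):
        cfg = DecompositionConfig(method="ICA", n_components=3, seed=2, max_iter=1, tol=1e-12)
        with pytest.warns(ConvergenceWarning):
            res = fastica_parallel(normalized_default, cfg)
        assert res.converged is False
        assert res.n_iter == 1

    def test_matches_reference_fastica(self):
        """Independent oracle: scikit-learn's FastICA finds the same sources."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        X, _ = generate(n_genes=1000, n_samples=80, true_k=3, module_size=80, seed=9)
        Xc = _centered(X)
        ours = fastica_parallel(Xc, DecompositionConfig(method="ICA", n_components=3, seed=9))
        ref = sklearn.FastICA(
            n_components=3, algorithm="parallel", fun="logcosh",
            whiten="unit-variance", random_state=9, max_iter=500,
        )
        S_ref = ref.fit_transform(Xc.to_numpy())
        _, rs = match_by_correlation(ours.signatures.to_numpy(), S_ref)
        assert (rs >= 0.99).all()


class TestIPCA:
    def test_planted_loading_recovery(self):
        X, truth = generate(seed=2)
        cfg = DecompositionConfig(method="IPCA", n_components=3, seed=2)
        res = ipca_deflation(_centered(X), cfg)
        _, rs = match_by_correlation(
            res.signatures.to_numpy(), truth.signature_weights.to_numpy()
        )
        assert (rs >= 0.9).all()

    def test_rank1_forced_direction(self):
        rng = np.random.default_rng(4)
        s = rng.laplace(size=500)
        a = rng.standard_normal(30)
        X = pd.DataFrame(np.outer(s, a))
        res = ipca_deflation(X, DecompositionConfig(method="IPCA", n_components=1, seed=4))
        r = abs(np.corrcoef(res.signatures.to_numpy()[:, 0], s)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_seeded_determinism(self, normalized_default):
        cfg = DecompositionConfig(method="IPCA", n_components=3, seed=6)
        a = ipca_deflation(normalized_default, cfg)
        b = ipca_deflation(normalized_default, cfg)
        np.testing.assert_allclose(
            a.signatures.to_numpy(), b.signatures.to_numpy(), atol=1e-12
        )


class TestDispatchAndInvariants:
    def test_dispatch_matches_backends(self, normalized_default):
        ica = DecompositionConfig(method="ICA", n_components=3, seed=1)
        ipca = DecompositionConfig(method="IPCA", n_components=3, seed=1)
        np.testing.assert_array_equal(
            decompose(normalized_default, ica).signatures.to_numpy(),
            fastica_parallel(normalized_default, ica).signatures.to_numpy(),
        )
        np.testing.assert_array_equal(
            decompose(normalized_default, ipca).signatures.to_numpy(),
            ipca_deflation(normalized_default, ipca).signatures.to_numpy(),
        )

    @pytest.mark.parametrize(
        "kwargs", [{"n_components": 0}, {"alpha": 0.5}, {"alpha": 2.5}, {"tol": 0.0}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DecompositionConfig(method="ICA", **{"n_components": 3, **kwargs})

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            DecompositionConfig(method="PCA", n_components=2)

    def test_reconstruction_equals_rank_k_truncation(self):
        # on noise-free rank-3 data the factorization reproduces the centered
        # matrix to the PCA-3 truncation error (which is 0)
        X, _ = generate(noise_sd=0.0, seed=13)
        Xc = _centered(X)
        res = decompose(Xc, DecompositionConfig(method="ICA", n_components=3, seed=13))
        recon = res.signatures.to_numpy() @ res.patterns.to_numpy() + res.column_means
        np.testing.assert_allclose(recon, Xc.to_numpy(), atol=1e-6)

    def test_signatures_pairwise_uncorrelated(self, normalized_default):
        res = decompose(
            normalized_default, DecompositionConfig(method="ICA", n_components=3, seed=3)
        )
        corr = np.corrcoef(res.signatures.to_numpy(), rowvar=False)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() <= 0.05
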