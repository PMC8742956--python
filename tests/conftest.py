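import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from decomod import generate, normalize_expression


@pytest.fixture(scope="session")
def default_fixture():
    """Default synthetic benchmark: 2000×100, 3 overlapping planted modules."""
    X, truth = generate(seed=11)
    return X, truth


@pytest.fixture(scope="session")
def normalized_default(default_fixture):
    X, _ = default_fixture
    return normalize_expression(X)


@pytest.fixture()
def small_matrix():
    """Tiny labeled matrix for structural tests."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.standard_normal((30, 8)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(8)],
    )


def result_from_signatures(S: np.ndarray, method: str = "ICA"):
    """Wrap a raw signature matrix in a DecompositionResult for stage tests."""
    from decomod import DecompositionConfig, DecompositionResult

    n, k = S.shape
    cfg = DecompositionConfig(method=method, n_components=k, seed=0)
    comp = [f"C{j + 1}" for j in range(k)]
    return DecompositionResult(
        signatures=pd.DataFrame(S, index=[f"g{i}" for i in range(n)], columns=comp),
        patterns=pd.DataFrame(np.zeros((k, 3)), index=comp, columns=["s0", "s1", "s2"]),
        config=cfg,
        converged=True,
        n_iter=1,
    )


def match_memberships(est: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Hungarian matching of boolean membership columns; returns matched Jaccards."""
    from decomod import jaccard

    J = np.zeros((est.shape[1], ref.shape[1]))
    for i in range(est.shape[1]):
        for j in range(ref.shape[1]):
            J[i, j] = jaccard(est[:, i], ref[:, j])
    rows, cols = linear_sum_assignment(-J)
    return J[rows, cols]
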