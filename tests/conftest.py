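import numpy as np
import pytest

from bbgraph import SimulationSpec, simulate_latent


@pytest.fixture
def gauss_points():
    """500 standard-Gaussian points in 10-D, fixed seed."""
    return np.random.default_rng(1).normal(size=(500, 10))


@pytest.fixture
def two_batch_data():
    """Default-style 2-batch / 2-type simulated dataset, 400 cells."""
    return simulate_latent(SimulationSpec(n_cells=400, seed=3))


def brute_force_knn(X, query_idx, reference_idx, k, metric="euclidean"):
    """Independent all-pairs oracle: full distance matrix, lexicographic sort.

    Ties broken by lower cell index; a query present in the reference set is
    pinned to distance 0 against itself.
    """
    X = np.asarray(X, dtype=float)
    q = np.asarray(query_idx)
    r = np.asarray(reference_idx)
    if metric == "euclidean":
        D = np.sqrt(((X[q][:, None, :] - X[r][None, :, :]) ** 2).sum(axis=2))
    else:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        Xn = X / np.where(norms > 0, norms, 1.0)
        D = np.clip(1.0 - Xn[q] @ Xn[r].T, 0.0, None)
    for row, cell in enumerate(q):
        hit = np.nonzero(r == cell)[0]
        if hit.size:
            D[row, hit[0]] = 0.0
    idx = np.empty((q.size, k), dtype=np.int64)
    dist = np.empty((q.size, k), dtype=float)
    for row in range(q.size):
        order = np.lexsort((r, D[row]))[:k]
        idx[row] = r[order]
        dist[row] = D[row, order]
    return idx, dist
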