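import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import brentq
from sklearn.base import clone

from bbgraph import (
    BatchBalancedNeighbors,
    BatchLabels,
    batch_balanced_knn,
    bbknn,
    compute_smoothing,
    cross_batch_fraction,
    exact_knn,
    fuzzy_union,
    membership_weights,
)
from bbgraph.errors import BatchSizeError, DomainError, ParameterError
from bbgraph.graph import BalancedNeighborSet, _trim_graph

from conftest import brute_force_knn


def make_bns(indices, distances, k_within, labels):
    indices = np.asarray(indices, dtype=np.int64)
    bl = BatchLabels.from_array(np.asarray(labels), indices.shape[0])
    return BalancedNeighborSet(
        indices=indices, distances=np.asarray(distances, dtype=float),
        k_within=k_within, batch_labels=bl,
        block_sizes=np.full(bl.n_batches, k_within, dtype=np.int64),
    )


class TestBatchBalancedKnn:
    def test_pool_size_and_balance(self, two_batch_data):
        lps = two_batch_data
        bns = batch_balanced_knn(lps.points, lps.batch_labels, k_within=3,
                                 backend="exact")
        assert bns.indices.shape == (400, 6)
        codes = lps.batch_labels.codes
        assert np.all(codes[bns.indices[:, :3]] == 0)
        assert np.all(codes[bns.indices[:, 3:]] == 1)

    def test_single_batch_reduces_to_plain_knn(self, gauss_points):
        bns = batch_balanced_knn(gauss_points, np.zeros(500, dtype=int),
                                 k_within=4, backend="exact")
        nl = exact_knn(gauss_points, np.arange(500), np.arange(500), 4)
        assert np.array_equal(bns.indices, nl.indices)
        assert np.allclose(bns.distances, nl.distances)

    def test_hand_placed_points_match_per_batch_sort(self):
        X = np.array([[0.0], [10.0], [1.0], [2.0], [11.0], [12.0]])
        labels = np.array(["a", "a", "b", "b", "b", "a"])
        bns = batch_balanced_knn(X, labels, k_within=1, backend="exact")
        for b, members in enumerate([[0, 1, 5], [2, 3, 4]]):
            idx, dist = brute_force_knn(X, np.arange(6), np.array(members), 1)
            assert np.array_equal(bns.indices[:, b : b + 1], idx)
            assert np.allclose(bns.distances[:, b : b + 1], dist)

    def test_small_batch_error_names_batch(self, two_batch_data):
        lps = two_batch_data
        labels = lps.batch_labels.labels.copy()
        labels[:398] = "big"
        with pytest.raises(BatchSizeError, match="batch"):
            batch_balanced_knn(lps.points, labels, k_within=5, backend="exact")

    def test_small_batch_clip_policy(self, two_batch_data):
        lps = two_batch_data
        labels = np.asarray(lps.batch_labels.labels, dtype=object).copy()
        labels[:] = "big"
        labels[:2] = "tiny"
        bns = batch_balanced_knn(lps.points, labels, k_within=5, backend="exact",
                                 small_batch="clip")
        assert np.array_equal(bns.block_sizes, [5, 2])
        assert bns.indices.shape[1] == 7


class TestSmoothing:
    def test_kernel_mass_hits_target(self, two_batch_data):
        lps = two_batch_data
        bns = batch_balanced_knn(lps.points, lps.batch_labels, k_within=5,
                                 backend="exact")
        params = compute_smoothing(bns, tol=1e-5)
        adj = np.maximum(bns.distances - params.rho[:, None], 0.0)
        adj[bns.indices == np.arange(400)[:, None]] = np.inf
        mass = np.exp(-adj / params.sigma[:, None]).sum(axis=1)
        ok = params.converged
        assert ok.all()
        assert np.abs(mass - params.target).max() <= 1e-4

    def test_sigma_matches_independent_bisection(self, two_batch_data):
        """Scalar root-finding oracle at 1e-10 tolerance per cell."""
        lps = two_batch_data
        bns = batch_balanced_knn(lps.points, lps.batch_labels, k_within=5,
                                 backend="exact")
        params = compute_smoothing(bns, tol=1e-8)
        target = params.target
        rng = np.random.default_rng(0)
        for i in rng.choice(400, 25, replace=False):
            d = bns.distances[i]
            self_mask = bns.indices[i] == i
            adj = np.maximum(d - params.rho[i], 0.0)[~self_mask]

            def f(sig):
                return np.exp(-adj / sig).sum() - target

            root = brentq(f, 1e-10, 1e6, xtol=1e-10)
            assert params.sigma[i] == pytest.approx(root, rel=1e-3)

    def test_constant_distance_row_clamps_sigma(self):
        # all merged neighbours at the same positive distance: mass is constant
        bns = make_bns(
            indices=[[0, 1, 2, 3], [1, 0, 2, 3], [2, 0, 1, 3], [3, 0, 1, 2]],
            distances=[[0.0, 2.0, 2.0, 2.0]] * 4,
            k_within=2, labels=[0, 0, 1, 1],
        )
        params = compute_smoothing(bns)
        # rho = 2, every non-self term is exp(0)=1 -> mass = 3 for any sigma;
        # target log2(4) = 2 is unreachable, sigma sits at the lower bound
        assert np.allclose(params.rho, 2.0)
        assert np.all(params.sigma <= 1e-10)

    def test_scale_equivariance(self, two_batch_data):
        lps = two_batch_data
        bns = batch_balanced_knn(lps.points, lps.batch_labels, k_within=5,
                                 backend="exact")
        p1 = compute_smoothing(bns)
        bns.distances = bns.distances * 2.0
        p2 = compute_smoothing(bns)
        assert np.allclose(p2.rho, 2.0 * p1.rho)
        assert np.allclose(p2.sigma, 2.0 * p1.sigma, rtol=1e-3)

    def test_rho_ignores_zero_distance_self_edge(self):
        bns = make_bns(
            indices=[[0, 1], [1, 0]], distances=[[0.0, 1.5], [0.0, 1.5]],
            k_within=1, labels=[0, 1],
        )
        params = compute_smoothing(bns)
        assert np.allclose(params.rho, 1.5)


class TestWeightsAndUnion:
    def test_nearest_neighbour_weight_is_exactly_one(self, two_batch_data):
        lps = two_batch_data
        bns = batch_balanced_knn(lps.points, lps.batch_labels, k_within=3,
                                 backend="exact")
        A = membership_weights(bns, compute_smoothing(bns))
        assert A.max(axis=1).toarray().min() == 1.0
        assert A.data.min() > 0.0
        assert A.data.max() <= 1.0
        assert A.diagonal().max() == 0.0

    def test_weights_decrease_with_distance(self):
        bns = make_bns(
            indices=[[0, 1, 2, 3], [1, 0, 2, 3], [2, 3, 0, 1], [3, 2, 0, 1]],
            distances=[[0.0, 1.0, 2.0, 3.0]] * 4,
            k_within=2, labels=[0, 0, 1, 1],
        )
        A = membership_weights(bns, compute_smoothing(bns))
        row = A.getrow(0).toarray().ravel()
        assert row[1] > row[2] > row[3] > 0.0

    @pytest.mark.parametrize("a, b, expected", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.75)])
    def test_union_hand_values(self, a, b, expected):
        A = sp.csr_matrix(np.array([[0.0, a], [b, 0.0]]))
        assert fuzzy_union(A)[0, 1] == expected

    def test_union_idempotent_on_crisp_symmetric_graph(self):
        A = sp.csr_matrix((np.ones(4), ([0, 1, 1, 2], [1, 0, 2, 1])), shape=(3, 3))
        W = fuzzy_union(A)
        assert (W != A).nnz == 0

    def test_union_rejects_out_of_range(self):
        A = sp.csr_matrix(np.array([[0.0, 1.5], [0.0, 0.0]]))
        with pytest.raises(DomainError):
            fuzzy_union(A)


class TestGraphPipeline:
    def test_symmetry_and_range(self, two_batch_data):
        lps = two_batch_data
        W = BatchBalancedNeighbors(backend="exact").fit_transform(
            lps.points, lps.batch_labels.labels)
        assert (W != W.T).nnz == 0
        assert W.data.min() > 0.0
        assert W.data.max() <= 1.0
        assert np.all(np.diff(W.indptr) >= 3)  # at least own-batch neighbours

    def test_single_batch_no_batch_machinery(self, gauss_points):
        W_none = BatchBalancedNeighbors(k_within=6, backend="exact").fit_transform(
            gauss_points, None)
        W_const = BatchBalancedNeighbors(k_within=6, backend="exact").fit_transform(
            gauss_points, np.full(500, "only"))
        assert (W_none != W_const).nnz == 0

    def test_label_permutation_equivariance(self, two_batch_data):
        lps = two_batch_data
        n = lps.n_cells
        W = BatchBalancedNeighbors(backend="exact").fit_transform(
            lps.points, lps.batch_labels.labels)
        perm = np.random.default_rng(4).permutation(n)
        Wp = BatchBalancedNeighbors(backend="exact").fit_transform(
            lps.points[perm], np.asarray(lps.batch_labels.labels)[perm])
        assert np.abs(Wp - W[perm][:, perm]).max() < 1e-12

    def test_duplicated_geometry_mirrors_blocks(self, gauss_points):
        # same coordinates in both batches: cross-batch pools mirror
        # within-batch pools at identical distances
        X = np.vstack([gauss_points[:100], gauss_points[:100]])
        labels = np.repeat([0, 1], 100)
        bns = batch_balanced_knn(X, labels, k_within=3, backend="exact")
        assert np.allclose(bns.distances[:, :3], bns.distances[:, 3:])
        assert np.array_equal(bns.indices[:, :3] % 100, bns.indices[:, 3:] % 100)

    def test_trim_preserves_symmetry_and_support(self, two_batch_data):
        lps = two_batch_data
        g_full = bbknn(lps.points, lps.batch_labels, k_within=5, backend="exact")
        g_trim = bbknn(lps.points, lps.batch_labels, k_within=5, backend="exact",
                       trim=4)
        W, Wt = g_full.connectivities, g_trim.connectivities
        assert (Wt != Wt.T).nnz == 0
        assert Wt.nnz <= W.nnz
        # surviving edges keep their original weights
        diff = (W - Wt).multiply(Wt != 0)
        assert abs(diff).max() == 0.0

    def test_trim_requires_positive(self, two_batch_data):
        with pytest.raises(ParameterError):
            _trim_graph(sp.eye(3, format="csr"), 0)

    def test_cross_batch_enrichment_over_vanilla(self, two_batch_data):
        lps = two_batch_data
        Wb = bbknn(lps.points, lps.batch_labels, k_within=3, backend="exact")
        Wv = bbknn(lps.points, np.zeros(400, dtype=int), k_within=6,
                   backend="exact")
        _, mb = cross_batch_fraction(Wb.connectivities, lps.batch_labels)
        _, mv = cross_batch_fraction(Wv.connectivities, lps.batch_labels)
        assert mb >= 10 * mv

    def test_estimator_follows_sklearn_protocol(self, two_batch_data):
        lps = two_batch_data
        est = BatchBalancedNeighbors(k_within=2, backend="exact")
        assert clone(est).get_params()["k_within"] == 2
        est.set_params(trim=8)
        est.fit(lps.points, lps.batch_labels.labels)
        assert est.connectivities_.shape == (400, 400)
        assert est.rho_.shape == (400,)
        assert list(est.batches_) == ["batch0", "batch1"]

    def test_graph_bundle_params(self, two_batch_data):
        lps = two_batch_data
        g = bbknn(lps.points, lps.batch_labels, k_within=2, backend="exact", seed=7)
        for key in ("k_within", "metric", "backend", "seed", "n_batches", "batch_order"):
            assert key in g.params
        assert g.params["seed"] == 7
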