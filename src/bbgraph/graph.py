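"""Batch-balanced neighbour graphs.

Batch effects displace cells of the same biological type in latent space, so a
vanilla kNN graph fractures by batch: cells connect almost exclusively within
their own batch.  The batch-balanced construction counters this by running the
neighbour search *independently within every batch*, giving each cell an equal
quota of ``k_within`` neighbours per batch, then merging the per-batch pools
and converting distances into fuzzy connectivities with the smoothed-kNN
kernel used by UMAP-style graph pipelines:

    w_ij = exp(-max(0, d_ij - rho_i) / sigma_i)

where ``rho_i`` is cell *i*'s distance to its nearest (strictly positive
distance) merged neighbour and ``sigma_i`` is calibrated by bisection so the
total kernel mass of row *i* equals ``log2(K_total)``.  The directed weights
are symmetrised by the probabilistic union ``W = A + A^T - A∘A^T``.

The method assumes shared cell types exist across batches and that the batch
displacement is smaller than between-type distances; when that fails, forced
cross-batch edges connect unrelated types (see the methods note).

The resulting sparse symmetric matrix is a drop-in neighbour graph for
graph-based clustering, embedding and trajectory tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .errors import BatchSizeError, DomainError, EmptyInputError, ParameterError
from .neighbors import (
    NeighborList,
    RPForest,
    exact_knn,
    validate_points,
)

logger = logging.getLogger("bbgraph")

BACKENDS = ("exact", "approximate")


@dataclass
class BatchLabels:
    """Per-cell categorical batch assignment.

    ``batches`` is the ordered (sorted-unique) list of distinct identifiers;
    ``codes`` maps each cell to its position in that list.
    """

    labels: np.ndarray
    batches: np.ndarray
    codes: np.ndarray
    counts: np.ndarray

    @classmethod
    def from_array(cls, labels, n_cells: int | None = None) -> "BatchLabels":
        arr = np.asarray(labels)
        if arr.ndim != 1:
            raise ParameterError("batch labels must be a 1-D vector")
        if n_cells is not None and arr.size != n_cells:
            raise ParameterError(
                f"batch labels length {arr.size} does not match n_cells={n_cells}"
            )
        if arr.size == 0:
            raise EmptyInputError("batch label vector is empty")
        batches, codes = np.unique(arr, return_inverse=True)
        counts = np.bincount(codes, minlength=batches.size)
        return cls(labels=arr, batches=batches, codes=codes.astype(np.int64),
                   counts=counts.astype(np.int64))

    @property
    def n_batches(self) -> int:
        return int(self.batches.size)

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass
class BalancedNeighborSet:
    """Merged per-batch neighbour pools, one block per batch in batch order.

    Row *i* holds cell *i*'s ``k_within`` nearest cells of batch 1, then of
    batch 2, etc.  Each block is sorted by distance; the row as a whole is not.
    With the clip policy a small batch contributes all of its cells instead of
    ``k_within``; ``block_sizes`` records the per-batch block widths.
    """

    indices: np.ndarray
    distances: np.ndarray
    k_within: int
    batch_labels: BatchLabels
    block_sizes: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    @property
    def k_total(self) -> int:
        return self.indices.shape[1]

    def block(self, b: int) -> slice:
        starts = np.concatenate([[0], np.cumsum(self.block_sizes)])
        return slice(int(starts[b]), int(starts[b + 1]))


@dataclass
class SmoothingParams:
    """Per-cell kernel calibration: nearest-neighbour offset and bandwidth.

    ``sigma`` solves sum_j exp(-max(0, d_ij - rho_i)/sigma_i) = target with
    target = log2(K_total), clamped to the declared bounds when the target is
    unreachable (degenerate rows where the kernel mass is constant).
    """

    rho: np.ndarray
    sigma: np.ndarray
    target: float
    converged: np.ndarray = field(default=None)


@dataclass
class ConnectivityGraph:
    """Symmetric fuzzy connectivity graph plus its directed distance companion."""

    connectivities: sp.csr_matrix
    distances: sp.csr_matrix
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.connectivities.shape[0]


def batch_balanced_knn(points, batches, k_within: int = 3, metric: str = "euclidean",
                       backend: str = "approximate", seed: int = 0,
                       n_trees: int = 20, leaf_size: int = 64,
                       search_k: int | None = None,
                       small_batch: str = "error") -> BalancedNeighborSet:
    """Find each cell's ``k_within`` nearest neighbours in every batch independently.

    Every cell — whatever its own batch — queries each batch's cells and keeps
    the ``k_within`` closest, so the merged pool holds exactly ``k_within * B``
    neighbours drawn equally from the ``B`` batches.  A cell is its own
    neighbour at distance 0 within its own batch.

    Parameters
    ----------
    points
        ``(n_cells, n_dims)`` latent coordinates (typically PC scores).
    batches
        Per-cell batch labels (vector) or a :class:`BatchLabels`.
    k_within
        Neighbours per batch; default 3 keeps the merged pool modest when many
        batches are present.
    backend
        ``"exact"`` (brute-force, deterministic) or ``"approximate"``
        (random-projection forest, seeded).
    small_batch
        ``"error"`` raises when a batch has fewer than ``k_within`` cells;
        ``"clip"`` takes all cells of the small batch instead.
    """
    X = validate_points(points)
    if not isinstance(batches, BatchLabels):
        batches = BatchLabels.from_array(batches, n_cells=X.shape[0])
    if k_within < 1:
        raise ParameterError("k_within must be >= 1")
    if backend not in BACKENDS:
        raise ParameterError(f"backend must be one of {BACKENDS}, got {backend!r}")
    if small_batch not in ("error", "clip"):
        raise ParameterError("small_batch must be 'error' or 'clip'")

    n = X.shape[0]
    all_cells = np.arange(n, dtype=np.int64)
    block_sizes = np.empty(batches.n_batches, dtype=np.int64)
    blocks_idx, blocks_d = [], []
    for b, batch_id in enumerate(batches.batches):
        ref = np.nonzero(batches.codes == b)[0]
        if ref.size < k_within:
            if small_batch == "error":
                raise BatchSizeError(
                    f"batch {batch_id!r} has {ref.size} cells, fewer than k_within={k_within}; "
                    "reduce k_within or enable the clip policy"
                )
            k_b = int(ref.size)
        else:
            k_b = k_within
        if backend == "exact":
            nl = exact_knn(X, all_cells, ref, k_b, metric=metric)
        else:
            forest = RPForest(X, ref, n_trees=n_trees, leaf_size=leaf_size,
                              seed=int(seed) + b, metric=metric)
            nl = forest.query(X, all_cells, k_b, search_k=search_k)
        block_sizes[b] = k_b
        blocks_idx.append(nl.indices)
        blocks_d.append(nl.distances)
    return BalancedNeighborSet(
        indices=np.concatenate(blocks_idx, axis=1),
        distances=np.concatenate(blocks_d, axis=1),
        k_within=k_within,
        batch_labels=batches,
        block_sizes=block_sizes,
    )


def compute_smoothing(bns: BalancedNeighborSet, tol: float = 1e-5,
                      max_iter: int = 64) -> SmoothingParams:
    """Calibrate the per-cell kernel offset ``rho`` and bandwidth ``sigma``.

    ``rho_i`` is the smallest strictly positive merged distance of cell *i*
    (0 if all merged distances are 0), so the zero-distance self edge never
    collapses the kernel.  ``sigma_i`` is found by bisection so that the kernel
    mass sum_j exp(-max(0, d_ij - rho_i)/sigma_i) over the merged pool —
    excluding the self edge, which carries no information and is dropped from
    the graph — equals log2(K_total) within ``tol``.  This matches the
    smoothed-kNN calibration of reference UMAP-style graph constructions,
    whose mass likewise skips the self slot.  The mass is non-decreasing in
    sigma; when
    the target lies outside the reachable range (e.g. every merged distance
    <= rho, making the mass constant), sigma is clamped to the search bound
    [1e-12 * mean-distance, 1e3 * max-distance] and a warning is logged.
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    d = bns.distances
    n, K = d.shape
    target = float(np.log2(K))

    pos = d > 0
    with np.errstate(invalid="ignore"):
        rho = np.where(pos.any(axis=1), np.min(np.where(pos, d, np.inf), axis=1), 0.0)
    adj = np.maximum(d - rho[:, None], 0.0)
    # the self edge contributes nothing to the mass at any sigma
    self_slot = bns.indices == np.arange(n)[:, None]
    adj[self_slot] = np.inf

    mean_d = d.mean(axis=1)
    max_d = d.max(axis=1)
    degenerate = max_d <= 0.0

    lo = np.where(degenerate, 1.0, 1e-12 * np.where(mean_d > 0, mean_d, 1.0))
    hi = np.where(degenerate, 1.0, 1e3 * np.where(max_d > 0, max_d, 1.0))

    def mass(sig):
        return np.exp(-adj / sig[:, None]).sum(axis=1)

    m_lo = mass(lo)
    m_hi = mass(hi)
    clamp_lo = m_lo > target + tol
    clamp_hi = m_hi < target - tol

    sigma = 0.5 * (lo + hi)
    active = ~(degenerate | clamp_lo | clamp_hi)
    lo_w, hi_w = lo.copy(), hi.copy()
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        sigma_a = 0.5 * (lo_w[active] + hi_w[active])
        sigma[active] = sigma_a
        m = np.exp(-adj[active] / sigma_a[:, None]).sum(axis=1)
        done = np.abs(m - target) <= tol
        too_high = m > target
        idx = np.nonzero(active)[0]
        hi_w[idx[too_high]] = sigma_a[too_high]
        lo_w[idx[~too_high]] = sigma_a[~too_high]
        converged[idx[done]] = True
        active[idx[done]] = False

    sigma[clamp_lo] = lo[clamp_lo]
    sigma[clamp_hi] = hi[clamp_hi]
    sigma[degenerate] = 1.0
    n_clamped = int(clamp_lo.sum() + clamp_hi.sum())
    if n_clamped:
        logger.warning(
            "sigma bisection: %d/%d cells clamped to a search bound "
            "(kernel-mass target %.4f unreachable)", n_clamped, n, target,
        )
    converged |= clamp_lo | clamp_hi | degenerate
    return SmoothingParams(rho=rho, sigma=sigma, target=target, converged=converged)


def membership_weights(bns: BalancedNeighborSet, sp_params: SmoothingParams) -> sp.csr_matrix:
    """Directed membership strengths A[i, j] = exp(-max(0, d_ij - rho_i)/sigma_i).

    One entry per merged neighbour; the diagonal (self edges) is removed.
    All retained entries lie in (0, 1]; the nearest merged neighbour of every
    cell (d = rho) receives weight exactly 1.
    """
    n, K = bns.distances.shape
    w = np.exp(-np.maximum(bns.distances - sp_params.rho[:, None], 0.0)
               / sp_params.sigma[:, None])
    rows = np.repeat(np.arange(n, dtype=np.int64), K)
    cols = bns.indices.ravel()
    data = w.ravel()
    off_diag = rows != cols
    A = sp.coo_matrix((data[off_diag], (rows[off_diag], cols[off_diag])), shape=(n, n))
    return A.tocsr()


def fuzzy_union(A: sp.spmatrix) -> sp.csr_matrix:
    """Probabilistic-union symmetrisation W = A + A^T - A∘A^T.

    Interpreting directed weights as membership probabilities, an undirected
    edge exists when either directed edge does.  The result is exactly
    symmetric, its support is the union of the supports of A and A^T, and
    entries stay in (0, 1] when A's entries are in [0, 1].
    """
    A = sp.csr_matrix(A)
    if A.nnz and (A.data.min() < 0.0 or A.data.max() > 1.0):
        raise DomainError("membership weights must lie in [0, 1]")
    T = A.T.tocsr()
    U = (A + T).tocsr()  # union support
    r, c = U.nonzero()
    a = np.asarray(A[r, c]).ravel()
    b = np.asarray(T[r, c]).ravel()
    # complement form of a + b - a*b: exact at a=1 and exactly symmetric
    W = sp.csr_matrix((1.0 - (1.0 - a) * (1.0 - b), (r, c)), shape=A.shape)
    W.eliminate_zeros()
    return W


def _trim_graph(W: sp.csr_matrix, trim: int) -> sp.csr_matrix:
    """Keep each row's ``trim`` strongest connectivities, then re-symmetrise.

    An edge survives if either endpoint retained it (union pattern), so the
    result stays symmetric.  Guards against hub cells when many batches
    inflate the merged pool.
    """
    if trim < 1:
        raise ParameterError("trim must be >= 1")
    W = sp.csr_matrix(W)
    n = W.shape[0]
    keep_rows, keep_cols = [], []
    for i in range(n):
        start, end = W.indptr[i], W.indptr[i + 1]
        cols = W.indices[start:end]
        vals = W.data[start:end]
        if cols.size > trim:
            order = np.lexsort((cols, -vals))[:trim]
            cols = cols[order]
        keep_rows.append(np.full(cols.size, i, dtype=np.int64))
        keep_cols.append(cols.astype(np.int64))
    rows = np.concatenate(keep_rows)
    cols = np.concatenate(keep_cols)
    K = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=W.shape).tocsr()
    mask = ((K + K.T) > 0).astype(float)
    out = sp.csr_matrix(W.multiply(mask))
    out.eliminate_zeros()
    return out


def _distance_companion(bns: BalancedNeighborSet) -> sp.csr_matrix:
    n, K = bns.distances.shape
    rows = np.repeat(np.arange(n, dtype=np.int64), K)
    cols = bns.indices.ravel()
    off_diag = rows != cols
    D = sp.coo_matrix(
        (bns.distances.ravel()[off_diag], (rows[off_diag], cols[off_diag])),
        shape=(n, n),
    )
    return D.tocsr()


class BatchBalancedNeighbors(BaseEstimator):
    """Batch-balanced kNN graph transformer.

    Builds, for a cells × dims coordinate matrix ``X`` and per-cell batch
    labels ``y``, the batch-balanced fuzzy connectivity graph: each cell gets
    ``k_within`` nearest neighbours from every batch, the merged distance
    pools are kernel-smoothed per cell (bandwidth calibrated to a kernel mass
    of log2(k_within * n_batches)) and symmetrised by probabilistic union.

    Follows scikit-learn conventions: parameters are set in ``__init__``,
    ``fit(X, y)`` computes the graph, fitted attributes carry a trailing
    underscore, and ``fit_transform`` returns the sparse connectivity matrix
    (cf. ``KNeighborsTransformer``).

    Parameters
    ----------
    k_within : int, default=3
        Neighbours to draw from each batch.
    metric : {"euclidean", "angular"}, default="euclidean"
        Distance in the latent space; euclidean matches the usual PC-space
        setting, angular (1 - cosine) is offered for direction-dominated
        representations.
    backend : {"approximate", "exact"}, default="approximate"
        Neighbour search engine.  The approximate backend is a seeded
        random-projection tree forest with near-linear scaling; the exact
        backend is brute force.
    trim : int or None, default=None
        If set, keep only the ``trim`` strongest connectivities per cell
        (symmetry restored by union pattern).  Off by default.
    n_trees, leaf_size, search_k
        Forest shape and search budget for the approximate backend;
        ``search_k=None`` means ``n_trees * k_within * 32``.
    small_batch : {"error", "clip"}, default="error"
        Policy for batches smaller than ``k_within``.
    smoothing_tol, smoothing_max_iter
        Bisection stopping rule for the per-cell bandwidth.
    random_state : int, default=0
        Seed for the approximate index; the exact backend is fully
        deterministic.

    Attributes
    ----------
    connectivities_ : scipy.sparse.csr_matrix
        Symmetric fuzzy connectivity graph, entries in (0, 1].
    distances_ : scipy.sparse.csr_matrix
        Directed merged kNN distances as found.
    neighbor_indices_, neighbor_distances_ : ndarray
        The merged per-batch neighbour pools, one sorted block per batch.
    rho_, sigma_ : ndarray
        Per-cell kernel offset and calibrated bandwidth.
    batches_ : ndarray
        Ordered distinct batch identifiers.

    Examples
    --------
    >>> import numpy as np
    >>> from bbgraph import BatchBalancedNeighbors
    >>> X = np.random.default_rng(0).normal(size=(100, 5))
    >>> y = np.repeat(["a", "b"], 50)
    >>> W = BatchBalancedNeighbors(k_within=3, backend="exact").fit_transform(X, y)
    >>> W.shape
    (100, 100)
    """

    def __init__(self, k_within: int = 3, metric: str = "euclidean",
                 backend: str = "approximate", trim: int | None = None,
                 n_trees: int = 20, leaf_size: int = 64,
                 search_k: int | None = None, small_batch: str = "error",
                 smoothing_tol: float = 1e-5, smoothing_max_iter: int = 64,
                 random_state: int = 0):
        self.k_within = k_within
        self.metric = metric
        self.backend = backend
        self.trim = trim
        self.n_trees = n_trees
        self.leaf_size = leaf_size
        self.search_k = search_k
        self.small_batch = small_batch
        self.smoothing_tol = smoothing_tol
        self.smoothing_max_iter = smoothing_max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        """Compute the batch-balanced graph for coordinates ``X`` and batches ``y``.

        ``y=None`` treats all cells as one batch, reducing the method to a
        plain smoothed kNN graph with ``k = k_within``.
        """
        X = validate_points(X)
        if y is None:
            y = np.zeros(X.shape[0], dtype=np.int64)
        batches = y if isinstance(y, BatchLabels) else BatchLabels.from_array(y, X.shape[0])

        bns = batch_balanced_knn(
            X, batches, k_within=self.k_within, metric=self.metric,
            backend=self.backend, seed=self.random_state, n_trees=self.n_trees,
            leaf_size=self.leaf_size, search_k=self.search_k,
            small_batch=self.small_batch,
        )
        sp_params = compute_smoothing(bns, tol=self.smoothing_tol,
                                      max_iter=self.smoothing_max_iter)
        A = membership_weights(bns, sp_params)
        W = fuzzy_union(A)
        if self.trim is not None:
            W = _trim_graph(W, self.trim)

        self.n_features_in_ = X.shape[1]
        self.neighbor_indices_ = bns.indices
        self.neighbor_distances_ = bns.distances
        self.block_sizes_ = bns.block_sizes
        self.batches_ = bns.batch_labels.batches
        self.batch_counts_ = bns.batch_labels.counts
        self.rho_ = sp_params.rho
        self.sigma_ = sp_params.sigma
        self.connectivities_ = W
        self.distances_ = _distance_companion(bns)
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the symmetric sparse connectivity matrix."""
        return self.fit(X, y).connectivities_

    def graph_(self) -> ConnectivityGraph:
        """Bundle the fitted matrices and parameters as a :class:`ConnectivityGraph`."""
        if not hasattr(self, "connectivities_"):
            raise ParameterError("estimator is not fitted")
        return ConnectivityGraph(
            connectivities=self.connectivities_,
            distances=self.distances_,
            params={
                "k_within": self.k_within,
                "metric": self.metric,
                "backend": self.backend,
                "trim": self.trim,
                "seed": self.random_state,
                "n_batches": int(self.batches_.size),
                "batch_order": [str(b) for b in self.batches_],
            },
        )


def bbknn(points, batches, k_within: int = 3, metric: str = "euclidean",
          backend: str = "approximate", trim: int | None = None,
          seed: int = 0, **kwargs) -> ConnectivityGraph:
    """One-call batch-balanced graph construction.

    Thin functional wrapper over :class:`BatchBalancedNeighbors`; returns the
    connectivity graph together with its directed distance companion and the
    parameters used.
    """
    est = BatchBalancedNeighbors(k_within=k_within, metric=metric, backend=backend,
                                 trim=trim, random_state=seed, **kwargs)
    est.fit(points, batches)
    return est.graph_()
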