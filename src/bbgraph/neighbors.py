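"""k-nearest-neighbour search over index subsets of a point set.

Two backends are provided: an exact search (chunked all-pairs distances with a
deterministic tie-break) and an approximate search built on a forest of
random-projection trees, in the style of annoy-like indices.  Both operate on
arbitrary subsets of a parent coordinate matrix, which is what batch-balanced
graph construction needs: every cell queries each batch's cells separately.

Distances are the metric's native value (never squared): ``euclidean`` or
``angular`` (1 minus cosine similarity).  Ties at equal distance are broken by
the lower cell index so results are reproducible across runs and platforms.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, ParameterError

METRICS = ("euclidean", "angular")

_FOREST_FORMAT_VERSION = 1


def validate_points(points) -> np.ndarray:
    """Coerce ``points`` to a finite float64 ``(n_cells, n_dims)`` matrix."""
    X = np.asarray(points, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ParameterError(
            f"points must be a 2-D matrix with n_cells >= 1 and n_dims >= 1, got shape {X.shape}"
        )
    if not np.isfinite(X).all():
        raise ParameterError("points contains non-finite entries")
    return X


def _check_metric(metric: str) -> str:
    if metric not in METRICS:
        raise ParameterError(f"metric must be one of {METRICS}, got {metric!r}")
    return metric


def _as_index_array(idx, n: int, name: str) -> np.ndarray:
    a = np.asarray(idx, dtype=np.int64).ravel()
    if a.size == 0:
        raise EmptyInputError(f"{name} index set is empty")
    if a.min() < 0 or a.max() >= n:
        raise ParameterError(f"{name} indices out of range [0, {n})")
    if np.unique(a).size != a.size:
        raise ParameterError(f"{name} indices contain duplicates")
    return a


def _metric_prep(X: np.ndarray, metric: str) -> np.ndarray:
    """Return coordinates in which the metric is computable by a dot/cdist call.

    For the angular metric rows are L2-normalised; zero rows are left at zero
    (their cosine similarity to anything is taken as 0, i.e. distance 1).
    """
    if metric == "euclidean":
        return X
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    safe = np.where(norms > 0.0, norms, 1.0)
    return X / safe


def _dist_block(Q: np.ndarray, R: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return cdist(Q, R)
    return np.clip(1.0 - Q @ R.T, 0.0, None)


@dataclass
class NeighborList:
    """Per-query neighbour indices (into the parent point set) and distances.

    Each row is sorted by non-decreasing distance, ties broken by lower index;
    indices within a row are unique.
    """

    indices: np.ndarray
    distances: np.ndarray

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def _select_k(D: np.ndarray, ref_cells: np.ndarray, k: int):
    """Smallest-k selection per row with (distance, cell index) ordering.

    Boundary ties (several reference cells exactly at the k-th distance) are
    resolved by the lower cell index; ``np.argpartition`` alone cannot promise
    that, so rows with boundary ties are re-sorted exhaustively.
    """
    n_q, n_r = D.shape
    rows = np.arange(n_q)[:, None]
    if k < n_r:
        part = np.argpartition(D, k - 1, axis=1)[:, :k]
    else:
        part = np.tile(np.arange(n_r), (n_q, 1))
    dpart = D[rows, part]
    kth = dpart.max(axis=1)
    tied = (D <= kth[:, None]).sum(axis=1) > k

    order = np.lexsort((ref_cells[part], dpart), axis=1)
    sel = part[rows, order][:, :k]
    out_idx = ref_cells[sel]
    out_d = D[rows, sel]

    for i in np.nonzero(tied)[0]:
        cand = np.nonzero(D[i] <= kth[i])[0]
        o = np.lexsort((ref_cells[cand], D[i, cand]))[:k]
        out_idx[i] = ref_cells[cand[o]]
        out_d[i] = D[i, cand[o]]
    return out_idx, out_d


def exact_knn(points, query_idx, reference_idx, k: int, metric: str = "euclidean") -> NeighborList:
    """Exact k nearest neighbours of each query cell among the reference cells.

    A query cell that is itself a member of the reference set is returned as
    its own neighbour at distance exactly 0.

    Parameters
    ----------
    points
        ``(n_cells, n_dims)`` coordinate matrix the index sets refer into.
    query_idx, reference_idx
        Integer index subsets of ``0..n_cells-1``.
    k
        Neighbours to return; must satisfy ``k <= len(reference_idx)``.
    metric
        ``"euclidean"`` or ``"angular"`` (1 - cosine similarity).
    """
    X = validate_points(points)
    _check_metric(metric)
    q = _as_index_array(query_idx, X.shape[0], "query")
    r = _as_index_array(reference_idx, X.shape[0], "reference")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > r.size:
        raise ParameterError(
            f"k={k} exceeds the reference set size {r.size}"
        )
    P = _metric_prep(X, metric)
    R = P[r]

    pos = np.full(X.shape[0], -1, dtype=np.int64)
    pos[r] = np.arange(r.size)

    out_idx = np.empty((q.size, k), dtype=np.int64)
    out_d = np.empty((q.size, k), dtype=np.float64)
    chunk = max(1, int(4_000_000 // max(r.size, 1)))
    for start in range(0, q.size, chunk):
        qc = q[start : start + chunk]
        D = _dist_block(P[qc], R, metric)
        self_rows = np.nonzero(pos[qc] >= 0)[0]
        D[self_rows, pos[qc[self_rows]]] = 0.0
        oi, od = _select_k(D, r, k)
        out_idx[start : start + chunk] = oi
        out_d[start : start + chunk] = od
    return NeighborList(indices=out_idx, distances=out_d)


# ---------------------------------------------------------------------------
# Random-projection tree forest
# ---------------------------------------------------------------------------

@dataclass
class _Tree:
    """One random-projection binary tree over reference-set positions.

    Nodes are stored in parallel arrays; ``children[i] == (-1, -1)`` marks a
    leaf whose member positions sit in ``leaf_points[i]``.
    """

    dirs: list = field(default_factory=list)
    offsets: list = field(default_factory=list)
    children: list = field(default_factory=list)
    leaf_points: list = field(default_factory=list)

    def new_node(self) -> int:
        self.dirs.append(None)
        self.offsets.append(0.0)
        self.children.append((-1, -1))
        self.leaf_points.append(None)
        return len(self.dirs) - 1


class RPForest:
    """Forest of random-projection trees for approximate kNN search.

    Each tree recursively splits the reference points by a hyperplane: the
    split direction is the (normalised) difference of two cluster centroids
    obtained by a short two-means refinement of a random point pair, and the
    offset is the median projection.  Nodes with at most ``leaf_size`` members
    become leaves, and every reference point lands in exactly one leaf per tree.
    Splits that fail to separate the points (coincident or collinear data)
    fall back to a random balanced partition so depth stays finite.

    Queries run a best-first traversal over all trees at once, expanding the
    frontier by hyperplane margin until at least ``search_k`` candidate points
    have been inspected, then rank candidates by true metric distance.  The
    approximation can only miss true neighbours, never invent closer ones, and
    an exhaustive budget (``search_k >= n_reference``) reproduces the exact
    search output.
    """

    def __init__(self, points, reference_idx, n_trees: int = 20, leaf_size: int = 64,
                 seed: int = 0, metric: str = "euclidean"):
        X = validate_points(points)
        _check_metric(metric)
        if leaf_size < 1:
            raise ParameterError("leaf_size must be >= 1")
        if n_trees < 1:
            raise ParameterError("n_trees must be >= 1")
        r = _as_index_array(reference_idx, X.shape[0], "reference")
        self.metric = metric
        self.leaf_size = int(leaf_size)
        self.n_trees = int(n_trees)
        self.seed = int(seed)
        self.reference_idx = r
        self.n_points_indexed = r.size
        self._ref_coords = _metric_prep(X, metric)[r].copy()
        seqs = np.random.SeedSequence(self.seed).spawn(self.n_trees)
        self.trees = [self._build_tree(np.random.default_rng(s)) for s in seqs]

    # -- construction -------------------------------------------------------

    def _build_tree(self, rng: np.random.Generator) -> _Tree:
        P = self._ref_coords
        tree = _Tree()
        root = tree.new_node()
        stack = [(root, np.arange(P.shape[0], dtype=np.int64))]
        while stack:
            nid, idx = stack.pop()
            if idx.size <= self.leaf_size:
                tree.leaf_points[nid] = idx
                continue
            direction, offset, mask = self._split(P, idx, rng)
            tree.dirs[nid] = direction
            tree.offsets[nid] = offset
            left, right = tree.new_node(), tree.new_node()
            tree.children[nid] = (left, right)
            stack.append((left, idx[mask]))
            stack.append((right, idx[~mask]))
        return tree

    def _split(self, P, idx, rng):
        # two-means refinement of a random point pair: the split hyperplane is
        # the perpendicular bisector of the refined centroids, which adapts to
        # local cluster structure far better than a raw random pair
        direction = None
        a, b = rng.choice(idx.size, size=2, replace=False)
        c0, c1 = P[idx[a]].astype(float), P[idx[b]].astype(float)
        for _ in range(4):
            d0 = ((P[idx] - c0) ** 2).sum(axis=1)
            d1 = ((P[idx] - c1) ** 2).sum(axis=1)
            m = d0 < d1
            n_left = int(m.sum())
            if n_left == 0 or n_left == idx.size:
                break
            c0, c1 = P[idx[m]].mean(axis=0), P[idx[~m]].mean(axis=0)
        d = c1 - c0
        nrm = np.linalg.norm(d)
        if nrm > 0.0:
            direction = d / nrm
        if direction is None:  # coincident sample points
            direction = rng.standard_normal(P.shape[1])
            direction /= np.linalg.norm(direction)
        proj = P[idx] @ direction
        offset = float(np.median(proj))
        mask = proj < offset
        n_left = int(mask.sum())
        if n_left == 0 or n_left == idx.size:
            # degenerate projection: random balanced partition keeps depth finite
            mask = np.zeros(idx.size, dtype=bool)
            mask[rng.permutation(idx.size)[: idx.size // 2]] = True
        return direction, offset, mask

    # -- query --------------------------------------------------------------

    def default_search_k(self, k: int) -> int:
        return self.n_trees * k * 32

    def query(self, points, query_idx, k: int, search_k: int | None = None) -> NeighborList:
        X = validate_points(points)
        q = _as_index_array(query_idx, X.shape[0], "query")
        if k < 1:
            raise ParameterError("k must be >= 1")
        if k > self.n_points_indexed:
            raise ParameterError(
                f"k={k} exceeds the number of indexed reference points {self.n_points_indexed}"
            )
        if search_k is None:
            search_k = self.default_search_k(k)
        if search_k < k:
            raise ParameterError("search_k must be >= k")
        P = _metric_prep(X, self.metric)
        r = self.reference_idx
        pos = np.full(X.shape[0], -1, dtype=np.int64)
        pos[r] = np.arange(r.size)

        out_idx = np.empty((q.size, k), dtype=np.int64)
        out_d = np.empty((q.size, k), dtype=np.float64)
        seen = np.zeros(r.size, dtype=bool)
        for row, cell in enumerate(q):
            cand = self._candidates(P[cell], search_k, seen)
            D = _dist_block(P[cell][None, :], self._ref_coords[cand], self.metric)
            self_pos = pos[cell]
            if self_pos >= 0:
                D[0, cand == self_pos] = 0.0
            oi, od = _select_k(D, r[cand], k)
            out_idx[row] = oi[0]
            out_d[row] = od[0]
        return NeighborList(indices=out_idx, distances=out_d)

    def _candidates(self, qvec: np.ndarray, search_k: int, seen: np.ndarray) -> np.ndarray:
        budget = min(search_k, self.n_points_indexed)
        heap = []
        for t, tree in enumerate(self.trees):
            heapq.heappush(heap, (-np.inf, t, 0))
        cand: list[np.ndarray] = []
        n_cand = 0
        while heap and n_cand < budget:
            neg_pri, t, nid = heapq.heappop(heap)
            tree = self.trees[t]
            left, right = tree.children[nid]
            if left < 0:  # leaf
                pts = tree.leaf_points[nid]
                fresh = pts[~seen[pts]]
                if fresh.size:
                    seen[fresh] = True
                    cand.append(fresh)
                    n_cand += fresh.size
                continue
            # signed-margin priorities: a node's priority is the minimum over
            # its root path of the signed margins (negative on the wrong side
            # of a split), so leaves consistent with the query drain first
            margin = float(qvec @ tree.dirs[nid] - tree.offsets[nid])
            near, far = (left, right) if margin < 0 else (right, left)
            pri = -neg_pri
            heapq.heappush(heap, (-min(pri, abs(margin)), t, near))
            heapq.heappush(heap, (-min(pri, -abs(margin)), t, far))
        out = np.concatenate(cand) if cand else np.empty(0, dtype=np.int64)
        seen[out] = False  # reset scratch for the next query
        return out

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        """Portable JSON serialization of the index (versioned header)."""
        trees = []
        for tree in self.trees:
            trees.append({
                "dirs": [None if d is None else d.tolist() for d in tree.dirs],
                "offsets": list(tree.offsets),
                "children": [list(c) for c in tree.children],
                "leaf_points": [None if p is None else p.tolist() for p in tree.leaf_points],
            })
        return json.dumps({
            "format": "bbgraph-rp-forest",
            "version": _FOREST_FORMAT_VERSION,
            "metric": self.metric,
            "leaf_size": self.leaf_size,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "reference_idx": self.reference_idx.tolist(),
            "ref_coords": self._ref_coords.tolist(),
            "trees": trees,
        })

    @classmethod
    def from_json(cls, payload: str) -> "RPForest":
        obj = json.loads(payload)
        if obj.get("format") != "bbgraph-rp-forest" or obj.get("version") != _FOREST_FORMAT_VERSION:
            raise ParameterError("unrecognized forest serialization header")
        forest = cls.__new__(cls)
        forest.metric = obj["metric"]
        forest.leaf_size = obj["leaf_size"]
        forest.n_trees = obj["n_trees"]
        forest.seed = obj["seed"]
        forest.reference_idx = np.asarray(obj["reference_idx"], dtype=np.int64)
        forest.n_points_indexed = forest.reference_idx.size
        forest._ref_coords = np.asarray(obj["ref_coords"], dtype=np.float64)
        forest.trees = []
        for t in obj["trees"]:
            tree = _Tree(
                dirs=[None if d is None else np.asarray(d) for d in t["dirs"]],
                offsets=list(t["offsets"]),
                children=[tuple(c) for c in t["children"]],
                leaf_points=[None if p is None else np.asarray(p, dtype=np.int64)
                             for p in t["leaf_points"]],
            )
            forest.trees.append(tree)
        return forest


def build_forest(points, reference_idx, n_trees: int = 20, leaf_size: int = 64,
                 seed: int = 0, metric: str = "euclidean") -> RPForest:
    """Build a random-projection tree forest over the reference subset."""
    return RPForest(points, reference_idx, n_trees=n_trees, leaf_size=leaf_size,
                    seed=seed, metric=metric)


def approx_knn(index: RPForest, points, query_idx, k: int,
               search_k: int | None = None) -> NeighborList:
    """Approximate kNN via best-first traversal of a prebuilt forest."""
    return index.query(points, query_idx, k, search_k=search_k)
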