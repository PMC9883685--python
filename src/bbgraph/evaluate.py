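"""Batch-mixing and backend-fidelity metrics.

The central mixing statistic is a kBET-style test: for a sample of cells,
compare each cell's neighbourhood batch composition against the global batch
proportions with a Pearson chi-squared test; the fraction of neighbourhoods
rejecting the null of well-mixedness (at level ``alpha``) summarises how
batch-segregated the graph or point cloud is — lower is better mixed.  The
chi-squared reference distribution is used directly; note that for very small
expected counts per batch (e.g. two batches at small ``k_test``) the discrete
counts make the nominal level only approximate.

Also provided: per-cell cross-batch edge fractions of a connectivity graph,
recall of the approximate neighbour backend against the exact oracle, and a
wall-clock scaling benchmark over a dataset series.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .errors import ParameterError
from .graph import (
    BatchBalancedNeighbors,
    BatchLabels,
    ConnectivityGraph,
)
from .neighbors import RPForest, exact_knn, validate_points

logger = logging.getLogger("bbgraph")


@dataclass
class MixingReport:
    """kBET-style batch-mixing summary.

    ``rejection_rate`` is the fraction of the ``n_tested`` sampled
    neighbourhoods whose batch composition rejects the well-mixed null at
    level ``alpha``; ``per_cell_cross_batch_fraction`` covers every cell.
    """

    rejection_rate: float
    alpha: float
    k_test: int
    n_tested: int
    per_cell_cross_batch_fraction: np.ndarray
    mean_cross_batch_fraction: float


@dataclass
class RecallReport:
    """Approximate-backend recall against the exact search on identical inputs."""

    per_query_recall: np.ndarray
    mean_recall: float


def _as_graph_matrix(graph) -> sp.csr_matrix | None:
    if isinstance(graph, ConnectivityGraph):
        return sp.csr_matrix(graph.connectivities)
    if sp.issparse(graph):
        return sp.csr_matrix(graph)
    return None


def _graph_neighborhood(W: sp.csr_matrix, i: int, k_test: int) -> np.ndarray:
    """Top-``k_test`` neighbours of cell i by connectivity weight.

    Rows with fewer than ``k_test`` edges are padded with graph-distance-2
    neighbours ranked by two-hop weight.
    """
    row = W.getrow(i)
    cols = row.indices
    vals = row.data
    keep = cols != i
    cols, vals = cols[keep], vals[keep]
    order = np.lexsort((cols, -vals))
    nb = cols[order[:k_test]]
    if nb.size < k_test:
        two_hop = (row @ W).tocoo()
        mask = ~np.isin(two_hop.col, np.concatenate([nb, [i]]))
        c2, v2 = two_hop.col[mask], two_hop.data[mask]
        order2 = np.lexsort((c2, -v2))
        nb = np.concatenate([nb, c2[order2[: k_test - nb.size]]])
    return nb


def cross_batch_fraction(graph, batches) -> tuple[np.ndarray, float]:
    """Per-cell fraction of graph edges crossing to another batch, plus mean.

    Accepts a :class:`ConnectivityGraph` or any sparse adjacency; edges are
    counted unweighted on the row support.  Isolated cells get fraction 0 with
    a logged warning.
    """
    W = _as_graph_matrix(graph)
    if W is None:
        raise ParameterError("cross_batch_fraction expects a graph (sparse matrix)")
    n = W.shape[0]
    if not isinstance(batches, BatchLabels):
        batches = BatchLabels.from_array(batches, n)
    if batches.n_batches < 2:
        raise ParameterError("cross-batch fraction undefined for a single batch")
    codes = batches.codes
    frac = np.zeros(n)
    indptr, indices = W.indptr, W.indices
    degrees = np.diff(indptr)
    isolated = degrees == 0
    if isolated.any():
        logger.warning("%d isolated cells (no edges); cross-batch fraction set to 0",
                       int(isolated.sum()))
    cross = codes[indices] != np.repeat(codes, degrees)
    sums = np.add.reduceat(cross, indptr[:-1][degrees > 0])
    frac[degrees > 0] = sums / degrees[degrees > 0]
    return frac, float(frac.mean())


def kbet_rejection_rate(graph_or_points, batches, k_test: int = 50,
                        alpha: float = 0.05, n_samples: int | None = None,
                        seed: int = 0) -> MixingReport:
    """Chi-squared test of local vs global batch composition over sampled cells.

    For each sampled cell, take its ``k_test`` nearest neighbours — the
    strongest connectivities when a graph is supplied, exact kNN on the raw
    coordinates otherwise (the uncorrected baseline; the cell itself is
    excluded) — and compute chi2 = sum_b (n_b - E_b)^2 / E_b with
    ``E_b = k_test * N_b / N``.  The neighbourhood is rejected when the
    chi-squared upper-tail probability at B-1 degrees of freedom falls below
    ``alpha``.

    Parameters
    ----------
    graph_or_points
        A :class:`ConnectivityGraph`, a sparse adjacency matrix, or a dense
        ``(n, d)`` coordinate matrix.
    k_test
        Neighbourhood size; must be >= the number of batches so every
        expected count is positive.  Default 50.
    n_samples
        Cells to test, sampled uniformly without replacement; default
        ``min(1000, n)``.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must be in (0, 1)")
    W = _as_graph_matrix(graph_or_points)
    if W is not None:
        n = W.shape[0]
    else:
        X = validate_points(graph_or_points)
        n = X.shape[0]
    if not isinstance(batches, BatchLabels):
        batches = BatchLabels.from_array(batches, n)
    B = batches.n_batches
    if B < 2:
        raise ParameterError("batch-mixing test undefined for a single batch")
    if k_test < B:
        raise ParameterError(f"k_test={k_test} must be >= n_batches={B}")
    if k_test >= n:
        raise ParameterError(f"k_test={k_test} must be < n_cells={n}")
    if n_samples is None:
        n_samples = min(1000, n)
    n_samples = int(min(n_samples, n))

    rng = np.random.default_rng(seed)
    tested = rng.choice(n, size=n_samples, replace=False)
    tested.sort()

    codes = batches.codes
    expected = k_test * batches.counts / n

    if W is not None:
        hoods = [_graph_neighborhood(W, int(i), k_test) for i in tested]
        per_cell_frac, _ = cross_batch_fraction(W, batches)
    else:
        nl = exact_knn(X, np.arange(n), np.arange(n), min(k_test + 1, n))
        knn = np.array([row[row != i][:k_test] for i, row in zip(range(n), nl.indices)])
        hoods = [knn[i] for i in tested]
        per_cell_frac = (codes[knn] != codes[:, None]).mean(axis=1)

    rejected = 0
    for nb in hoods:
        counts = np.bincount(codes[nb], minlength=B)
        stat = float(((counts - expected) ** 2 / expected).sum())
        if stats.chi2.sf(stat, B - 1) < alpha:
            rejected += 1
    return MixingReport(
        rejection_rate=rejected / n_samples,
        alpha=alpha,
        k_test=k_test,
        n_tested=n_samples,
        per_cell_cross_batch_fraction=per_cell_frac,
        mean_cross_batch_fraction=float(per_cell_frac.mean()),
    )


def recall_vs_exact(points, reference_idx, query_idx, k: int,
                    n_trees: int = 20, leaf_size: int = 64,
                    search_k: int | None = None, seed: int = 0,
                    metric: str = "euclidean") -> RecallReport:
    """Fraction of the exact k nearest neighbours the forest backend recovers.

    A returned index tied with the exact k-th distance counts as correct even
    if the exact list broke the tie the other way.
    """
    X = validate_points(points)
    ex = exact_knn(X, query_idx, reference_idx, k, metric=metric)
    forest = RPForest(X, reference_idx, n_trees=n_trees, leaf_size=leaf_size,
                      seed=seed, metric=metric)
    ap = forest.query(X, query_idx, k, search_k=search_k)
    kth = ex.distances[:, -1]
    tol = 1e-9 * np.maximum(kth, 1.0)
    per_query = np.empty(ex.indices.shape[0])
    for i in range(ex.indices.shape[0]):
        in_exact = np.isin(ap.indices[i], ex.indices[i])
        tied = ap.distances[i] <= kth[i] + tol[i]
        per_query[i] = float(np.count_nonzero(in_exact | tied)) / k
    return RecallReport(per_query_recall=per_query, mean_recall=float(per_query.mean()))


def scaling_benchmark(series, backends=("approximate", "exact"), k_within: int = 3,
                      seed: int = 0, **bbknn_kwargs):
    """Wall-clock timing of graph construction over a dataset series.

    Runs the full graph build per dataset and backend and fits a log-log
    slope of time against cell count per backend (NaN with fewer than two
    datasets).  Reporting only: wall time is hardware-dependent, so no
    assertion belongs on these numbers.  Returns ``(table, slopes)`` with a
    tidy DataFrame of (n_cells, backend, wall_time_s).
    """
    rows = []
    for lps in series:
        for backend in backends:
            est = BatchBalancedNeighbors(k_within=k_within, backend=backend,
                                         random_state=seed, **bbknn_kwargs)
            t0 = time.perf_counter()
            est.fit(lps.points, lps.batch_labels)
            rows.append({"n_cells": lps.n_cells, "backend": backend,
                         "wall_time_s": time.perf_counter() - t0})
    table = pd.DataFrame(rows)
    slopes = {}
    for backend in backends:
        sub = table[table.backend == backend]
        if len(sub) >= 2:
            slope = np.polyfit(np.log(sub.n_cells), np.log(sub.wall_time_s), 1)[0]
        else:
            slope = float("nan")
        slopes[backend] = float(slope)
    return table, slopes
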