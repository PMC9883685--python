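"""Synthetic batched single-cell data in latent space.

Generates the benchmark family used throughout the test suite and the scaling
study: ``B`` batches sharing ``T`` cell types, where each type is an isotropic
Gaussian cluster around a centroid and each batch displaces *all* of its cells
by one shared random vector — the simplest model of a batch effect as a global
technical shift.  Type centroids are placed mutually equidistant (a scaled
regular simplex), so the ratio ``batch_shift / type_separation`` cleanly
switches between the regime where batch alignment is expected to work
(shift < separation: matching types remain mutual nearest across batches) and
the regime where its core assumption is violated (shift > separation).

The default specification follows the benchmark design of two equally sized
batches of two matching cell types, with total cell count scalable in powers
of two.

A count-level generator (:func:`simulate_counts`) maps latent points through a
fixed random linear map to per-gene Poisson rates, for end-to-end tests of the
counts → PCA → graph path.  It does not model dropout, per-gene batch factors
or differentiation paths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError
from .graph import BatchLabels


@dataclass
class SimulationSpec:
    """Parameters of one synthetic batched dataset.

    All distances are unitless latent-space distances.  ``noise_sd`` is the
    within-cluster standard deviation per dimension; defaults put the batch
    shift (5) well below the type separation (10) with both large relative to
    the noise (1), i.e. the regime batch alignment is designed for.

    ``proportions`` is an optional ``(n_batches, n_types)`` matrix of per-batch
    type fractions (rows sum to 1); ``None`` means equal proportions.
    """

    n_cells: int = 2048
    n_batches: int = 2
    n_types: int = 2
    dim: int = 10
    type_separation: float = 10.0
    batch_shift: float = 5.0
    noise_sd: float = 1.0
    proportions: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cells", "n_batches", "n_types", "dim"):
            if int(getattr(self, name)) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.type_separation < 0 or self.batch_shift < 0:
            raise ParameterError("distances and noise_sd must be non-negative")
        if self.dim < self.n_types - 1:
            raise ParameterError(
                f"dim={self.dim} too small to place {self.n_types} mutually "
                f"equidistant type centroids (need dim >= n_types - 1)"
            )
        if self.proportions is not None:
            P = np.asarray(self.proportions, dtype=float)
            if P.shape != (self.n_batches, self.n_types):
                raise ParameterError(
                    f"proportions must have shape ({self.n_batches}, {self.n_types})"
                )
            if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0):
                raise ParameterError("proportions rows must be non-negative and sum to 1")


@dataclass
class LabelledPointSet:
    """Simulated coordinates with batch labels and ground-truth type labels."""

    points: np.ndarray
    batch_labels: BatchLabels
    type_labels: np.ndarray
    spec: SimulationSpec = None

    @property
    def n_cells(self) -> int:
        return self.points.shape[0]


def _type_centroids(n_types: int, dim: int, separation: float) -> np.ndarray:
    """Vertices of a regular simplex with pairwise distance ``separation``."""
    C = np.zeros((n_types, dim))
    if n_types > 1:
        C[:, :n_types] = np.eye(n_types) * (separation / np.sqrt(2.0))
    C -= C.mean(axis=0)
    return C


def _allocate(total: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` into integer counts."""
    raw = fractions * total
    counts = np.floor(raw).astype(np.int64)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def simulate_latent(spec: SimulationSpec) -> LabelledPointSet:
    """Draw one batched latent-space dataset from ``spec``.

    Cells of batch *b*, type *t* are sampled i.i.d. from
    ``N(centroid_t + shift_b, noise_sd^2 I)`` where ``shift_b`` is one random
    direction of norm ``batch_shift`` per batch.  Cells are emitted grouped by
    batch, then by type; counts follow the proportions with any remainder
    assigned deterministically (largest remainder).  Fully reproducible from
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    B, T, dim = spec.n_batches, spec.n_types, spec.dim
    centroids = _type_centroids(T, dim, spec.type_separation)

    shifts = np.zeros((B, dim))
    for b in range(B):
        v = rng.standard_normal(dim)
        nrm = np.linalg.norm(v)
        if nrm > 0 and spec.batch_shift > 0:
            shifts[b] = v / nrm * spec.batch_shift

    if spec.proportions is None:
        P = np.full((B, T), 1.0 / T)
    else:
        P = np.asarray(spec.proportions, dtype=float)

    batch_sizes = _allocate(spec.n_cells, np.full(B, 1.0 / B))
    pts, b_lab, t_lab = [], [], []
    for b in range(B):
        type_counts = _allocate(int(batch_sizes[b]), P[b])
        for t in range(T):
            m = int(type_counts[t])
            if m == 0:
                continue
            pts.append(centroids[t] + shifts[b]
                       + rng.standard_normal((m, dim)) * spec.noise_sd)
            b_lab.append(np.full(m, f"batch{b}"))
            t_lab.append(np.full(m, f"type{t}"))
    points = np.concatenate(pts, axis=0)
    batch_labels = BatchLabels.from_array(np.concatenate(b_lab), points.shape[0])
    return LabelledPointSet(points=points, batch_labels=batch_labels,
                           type_labels=np.concatenate(t_lab), spec=spec)


def derive_seed(base_seed: int, tag: int) -> int:
    """Deterministic child seed (< 2^31) from a base seed and an integer tag."""
    return int(np.random.SeedSequence([int(base_seed), int(tag)]).generate_state(1)[0] % (2**31))


def benchmark_series(base_spec: SimulationSpec, powers: list[int]) -> list[LabelledPointSet]:
    """One dataset per power p with n_cells = 2**p, all else held fixed.

    Mirrors the scaling-study design (total cell count scaled in powers of
    two); per-dataset seeds are derived deterministically from the base seed
    and the power.
    """
    if not powers:
        raise ParameterError("powers must be non-empty")
    out = []
    for p in powers:
        spec = replace(base_spec, n_cells=2 ** int(p),
                       seed=derive_seed(base_spec.seed, int(p)))
        out.append(simulate_latent(spec))
    return out


def simulate_counts(spec: SimulationSpec, n_genes: int = 200,
                    library_size: float = 5000.0):
    """Map latent points to a Poisson count matrix for end-to-end tests.

    Latent coordinates pass through a fixed random linear map (seeded from the
    spec) into gene space, are softmax-normalised per cell into relative
    expression, and scaled to ``library_size`` expected counts per cell before
    Poisson sampling.  Returns ``(counts, labelled_points, gene_ids)`` where
    ``counts`` is a sparse ``n_cells x n_genes`` integer matrix and
    ``labelled_points`` carries the underlying latent data and labels.
    """
    if n_genes < spec.dim:
        raise ParameterError(f"n_genes={n_genes} must be >= dim={spec.dim}")
    if library_size <= 0:
        raise ParameterError("library_size must be > 0")
    lps = simulate_latent(spec)
    rng = np.random.default_rng(derive_seed(spec.seed, 987_001))
    M = rng.standard_normal((spec.dim, n_genes)) / np.sqrt(spec.dim)
    G = lps.points @ M
    G -= G.max(axis=1, keepdims=True)  # softmax stability
    rel = np.exp(G)
    rel /= rel.sum(axis=1, keepdims=True)
    counts = rng.poisson(rel * library_size)
    gene_ids = np.array([f"gene{j}" for j in range(n_genes)])
    return sp.csr_matrix(counts), lps, gene_ids
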