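# Methods

## The batch-balanced graph

`bbgraph` builds a neighbour graph over cells embedded in a latent space
(usually principal-component scores of log-normalised expression). Instead of
one global kNN search, the search runs independently inside every
user-defined batch: cell *i* receives its `k_within` nearest cells of batch
*b*, for every *b*, so the merged pool of `K = k_within · B` neighbours is
balanced across batches by construction. This is the defining property of the
method and is what forces cross-batch edges to exist wherever matching
populations exist.

**Assumption.** The construction is only meaningful when (a) at least some
cell types are shared across batches and (b) the technical displacement
between batches is smaller than the separation between distinct cell types.
When (b) fails, the forced quota connects *unrelated* types across batches;
the synthetic generator exposes both regimes (see below), and the failure
mode is deliberate, not guarded against.

### Distances and tie-breaking

Metrics: `euclidean` (default — appropriate for PC space) and `angular`
(1 − cosine similarity) for direction-dominated representations. Distances
are kept as native metric values, never squared, because the smoothing kernel
consumes raw distances. Ties at equal distance are always broken by the lower
cell index so every output is reproducible across runs and platforms. A cell
querying a batch that contains it is its own neighbour at distance exactly 0
(pinned, not recomputed, so floating-point noise cannot displace it).

### Exact backend

Chunked all-pairs distances (`scipy.spatial.distance.cdist` for euclidean, a
clipped dot product on L2-normalised rows for angular), with an
`argpartition` fast path and an exhaustive re-sort of any row that has ties
at the k-th distance boundary. O(n·m) per batch of size m; it is the oracle
the approximate backend is measured against.

### Approximate backend: random-projection forest

An annoy-style forest of binary trees, built per batch:

- **Split rule** — direction = normalised difference of two cluster centroids
  obtained by refining a random point pair with 4 two-means (Lloyd)
  iterations; offset = median projection. The two-means refinement adapts
  hyperplanes to local cluster structure and measurably improves recall over
  a raw random-pair direction. Splits that fail to separate the node
  (coincident points) fall back to a seeded random balanced partition, so
  tree depth is always finite.
- **Leaves** hold at most `leaf_size` (default 64) points; every reference
  point lands in exactly one leaf per tree.
- **Query** — one best-first frontier over all trees at once, ordered by
  signed margins: a node's priority is the minimum over its root path of the
  signed hyperplane margins (negative when the query sits on the far side),
  so leaves consistent with the query drain first. Traversal stops once
  `search_k` distinct candidates have been inspected; candidates are then
  ranked by true metric distance. The approximation can therefore only *miss*
  true neighbours, never invent closer ones, and an exhaustive budget
  (`search_k ≥ n`) reproduces the exact output bit for bit.

Defaults: `n_trees = 20`, `leaf_size = 64`, `search_k = n_trees · k · 32`.
These were calibrated on 50-dimensional Gaussian benchmarks (5000 points,
k = 3) to give mean recall ≈ 0.96 against the exact oracle; 10 trees give
≈ 0.83 under the same budget rule. Build and query are fully deterministic
given the seed (per-tree seeds are spawned from one `SeedSequence`). The
index serialises to versioned JSON (`RPForest.to_json`/`from_json`).

### Smoothing and symmetrisation

The merged distance pool of each cell is converted to fuzzy memberships with
the smoothed-kNN kernel used by UMAP-style graph constructions:

- `ρ_i` = the smallest *strictly positive* merged distance (0 if none). Zero
  distance self-edges or duplicates never define ρ, so the kernel cannot
  collapse.
- `σ_i` solves `Σ_j exp(−max(0, d_ij − ρ_i)/σ_i) = log2(K)` by bisection,
  where the sum runs over the merged pool *excluding the self slot*. The
  self edge is dropped from the graph and carries no information; excluding
  it also makes the single-batch reduction agree elementwise (≈ 4e-6) with
  the reference fuzzy-simplicial-set implementation in umap-learn, whose
  calibration likewise skips the self slot.
- Bisection: tolerance 1e-5 on the kernel mass, at most 64 iterations,
  search interval `[1e-12 · mean(d_i), 1e3 · max(d_i)]` per cell. The mass is
  non-decreasing in σ; if the target lies outside the reachable range (e.g.
  every merged distance ≤ ρ, making the mass constant) σ clamps to the
  nearest bound and a warning is logged. Rows whose distances are all zero
  (degenerate duplicates) get σ = 1; their weights are all 1 regardless.
- Directed weights `a_ij = exp(−max(0, d_ij − ρ_i)/σ_i) ∈ (0, 1]`; the
  nearest merged neighbour always receives weight exactly 1.
- Symmetrisation is the probabilistic union `w = a + aᵀ − a∘aᵀ`, computed in
  the complement form `1 − (1−a)(1−aᵀ)` on the union support, which is exact
  at a = 1 and exactly symmetric in floating point.

`trim` (off by default) optionally keeps only the `trim` strongest
connectivities per cell and restores symmetry by keeping any edge either
endpoint retained — a guard against hub cells when many batches inflate `K`.
Batches smaller than `k_within` raise a named error by default; the explicit
`small_batch="clip"` policy takes all cells of the small batch instead, and
the per-batch block widths are recorded so nothing is silent.

### Defaults

| parameter | default | why |
|---|---|---|
| `k_within` | 3 | keeps `K = k·B` modest when many batches are present |
| `metric` | euclidean | PC-space geometry |
| `backend` | approximate | near-linear scaling; exact available as oracle |
| `n_trees` / `leaf_size` / `search_k` | 20 / 64 / `20·k·32` | recall-calibrated (above) |
| smoothing tol / max_iter | 1e-5 / 64 | bandwidth solved far below weight precision |
| `trim` | off | pruning is an extension, not part of the core method |

## Synthetic data

`simulate_latent` draws `B` batches sharing `T` cell types directly in latent
space: type centroids sit at the vertices of a regular simplex with pairwise
distance `type_separation`; each batch adds one shared random displacement of
norm `batch_shift`; cells are isotropic Gaussians (`noise_sd`) around
centroid + displacement. Counts are allocated by largest remainder, so equal
proportions differ by at most one cell. Defaults — 2 equal batches × 2
matching types, 2048 cells, dim 10, separation 10, shift 5, noise 1 — encode
the benchmark design of two equally sized batches of two matching cell types
with the shift below the separation (the regime the method targets);
`batch_shift > type_separation` gives the assumption-violated regime used to
demonstrate failure, not success. `benchmark_series` scales the total cell
count in powers of two with per-power seeds derived deterministically from
the base seed.

What the generator does **not** emulate: count-level noise models (dropout,
per-gene batch factors, differentiation paths), unequal library sizes,
non-isotropic clusters. Passing tests therefore demonstrate the graph
machinery and its invariants, not performance on any real tissue.
`simulate_counts` adds a deliberately simple count layer (fixed random linear
map → softmax → Poisson at a given library size) purely to exercise the
counts → PCA → graph path end to end.

## Evaluation

- **Mixing** — a kBET-style test: for sampled cells, Pearson
  `χ² = Σ_b (n_b − E_b)²/E_b` with `E_b = k_test · N_b / N` over the
  neighbourhood batch counts, rejected when the χ² upper tail at B−1 degrees
  of freedom is below α. The χ² reference distribution is used directly
  rather than a permutation null; this is transparent and analytically
  testable, but at small expected counts the discreteness of the counts makes
  the nominal level approximate — with B = 2 and k_test = 50 the true null
  rejection of the χ² test is ≈ 0.065, while B = 4 gives ≈ 0.051, which is
  why the null-calibration study uses 4 batches. Defaults: α = 0.05,
  k_test = 50, n_samples = min(1000, n), sampling uniform without
  replacement, seeded. Graph neighbourhoods are the top-`k_test` edges by
  weight, padded with two-hop neighbours (ranked by two-hop weight) when a
  row is sparser than `k_test`; raw-coordinate neighbourhoods are exact kNN
  with the cell itself excluded.
- **Cross-batch fraction** — per cell, the unweighted fraction of graph edges
  whose endpoint lies in another batch; isolated cells get 0 with a logged
  warning. Before the union, the directed pools are balanced by construction
  and the fraction is exactly (B−1)/B.
- **Recall** — fraction of exact k-nearest found by the forest, per query;
  indices tied with the exact k-th distance count as found.
- **Scaling** — wall-clock time of the full graph build per dataset and
  backend with a fitted log-log slope. This is reported, never asserted:
  wall time is hardware-dependent. On the development machine the
  approximate backend fits slope ≈ 1.0 over 2^11–2^15 cells and the exact
  backend ≈ 1.6 (quadratic asymptotics damped by constant overheads at the
  smaller sizes).

## Numerical and design choices

- Batch identifiers are ordered by sorted uniqueness; all outputs are
  invariant (up to permutation) under consistent reordering of cells and
  labels.
- One integer seed threads through every random component (forest build,
  sampling, simulation); the exact backend is deterministic with no seed.
- The graph is written as two MatrixMarket files (connectivities, distances;
  1-based on disk, 0-based in memory) plus a JSON sidecar carrying every
  construction parameter, so a run is fully reconstructable from its outputs.
- PCA from counts (CLI path) is the upstream convention, not part of the
  method: library-size normalisation to 1e4, log1p, column centering, top
  components with a deterministic sign convention (largest-|loading| entry
  positive).

## Known limitations

- The forced quota fabricates cross-batch edges between unrelated types when
  no shared population exists — inherent to the method family, visible in the
  large-shift regime of the simulator.
- kBET rejection rates on balanced graphs remain well above α even when
  mixing is good: neighbourhoods padded through two-hop edges lean towards
  the own batch, and the χ² test is sensitive to any residual imbalance at
  n_samples = 1000. Comparisons between graphs on the same points are
  meaningful; absolute rates should not be read as calibrated p-values.
- The RP forest targets moderate dimensionality (tens of dimensions, the
  PC-space regime). No GPU path, no product quantisation, no incremental
  updates.
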