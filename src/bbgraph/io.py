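"""Readers and writers for the interchange formats at the package boundary.

Sparse matrices travel as MatrixMarket (MTX, 1-based on disk, 0-based in
memory), coordinates and cell metadata as headered CSV, parameters as JSON
sidecars.  All readers validate alignment between a matrix and its sidecar
files and raise named errors instead of silently coercing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.decomposition import PCA

from .errors import AlignmentError, ParameterError, SchemaError
from .graph import ConnectivityGraph
from .simulate import LabelledPointSet

logger = logging.getLogger("bbgraph")


def _sib(prefix: Path, suffix: str) -> Path:
    """Sibling path ``<prefix><suffix>`` (prefixes may contain dots)."""
    return prefix.parent / (prefix.name + suffix)


@dataclass
class DatasetBundle:
    """A counts matrix and/or coordinate matrix with aligned cell metadata."""

    counts: sp.csr_matrix | None
    coords: np.ndarray | None
    cell_ids: np.ndarray
    metadata: pd.DataFrame
    batch_column: str

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def batch_labels(self) -> np.ndarray:
        return self.metadata[self.batch_column].to_numpy()


def _read_id_column(path) -> np.ndarray:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
    return ids


def read_mtx_bundle(matrix_path, barcodes_path, features_path, metadata_path,
                    batch_column: str) -> DatasetBundle:
    """Load an MTX counts matrix with barcode/feature sidecars and cell metadata.

    Orientation is auto-detected: the matrix dimension matching the barcode
    count is taken as cells (transposed input is accepted and flipped, with a
    logged decision).  Raises :class:`AlignmentError` on dimension mismatches
    or duplicate barcodes, :class:`SchemaError` on a missing batch column.
    """
    M = sp.csr_matrix(mmread(str(matrix_path)))
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    if np.unique(barcodes).size != barcodes.size:
        raise AlignmentError("barcodes file contains duplicate cell identifiers")
    n_b, n_f = barcodes.size, features.size
    if M.shape == (n_b, n_f):
        logger.info("MTX orientation: cells x genes (%d x %d)", *M.shape)
    elif M.shape == (n_f, n_b):
        logger.info("MTX orientation: genes x cells (%d x %d); transposing", *M.shape)
        M = sp.csr_matrix(M.T)
    else:
        raise AlignmentError(
            f"MTX shape {M.shape} matches neither (barcodes, features)=({n_b}, {n_f}) "
            f"nor its transpose"
        )
    if (M.data < 0).any():
        raise AlignmentError("counts matrix contains negative entries")
    meta = pd.read_csv(metadata_path)
    if batch_column not in meta.columns:
        raise SchemaError(
            f"batch column {batch_column!r} not in metadata columns {list(meta.columns)}"
        )
    if "cell_id" in meta.columns:
        meta = meta.set_index("cell_id")
        missing = [b for b in barcodes if b not in meta.index]
        if missing:
            raise AlignmentError(f"{len(missing)} barcodes missing from metadata")
        meta = meta.loc[barcodes].reset_index()
    elif len(meta) != n_b:
        raise AlignmentError(
            f"metadata has {len(meta)} rows but matrix has {n_b} cells and no cell_id column"
        )
    return DatasetBundle(counts=M, coords=None, cell_ids=barcodes, metadata=meta,
                         batch_column=batch_column)


def compute_reduction(counts, n_components: int = 50, seed: int = 0,
                      target_sum: float = 1e4):
    """PCA-like reduction of a counts matrix to latent coordinates.

    Pipeline: per-cell library-size normalisation to ``target_sum``, log1p,
    column centering, projection onto the top ``n_components`` principal axes.
    The sign convention (largest-magnitude loading positive per component)
    makes the output deterministic.  All-zero cells are dropped with a logged
    warning; returns ``(coords, kept)`` where ``kept`` indexes the retained
    rows of the input.
    """
    C = sp.csr_matrix(counts).astype(np.float64)
    n, g = C.shape
    lib = np.asarray(C.sum(axis=1)).ravel()
    kept = np.nonzero(lib > 0)[0]
    if kept.size < n:
        logger.warning("dropping %d all-zero cells before reduction", n - kept.size)
    if kept.size == 0:
        raise ParameterError("all cells have zero counts")
    if n_components > min(kept.size, g):
        raise ParameterError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)="
            f"{min(kept.size, g)}"
        )
    C = C[kept]
    X = np.log1p(C.multiply(target_sum / lib[kept, None]).toarray())
    pca = PCA(n_components=n_components, random_state=seed)
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components),
                        np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    return coords * flip, kept


def write_graph(graph: ConnectivityGraph, out_prefix, params: dict | None = None) -> dict:
    """Write connectivities/distances as MTX plus a JSON parameter sidecar.

    Returns the mapping of role -> written path.  A read-back via
    :func:`read_graph` reproduces the sparse triplets exactly.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "connectivities": _sib(prefix, ".connectivities.mtx"),
        "distances": _sib(prefix, ".distances.mtx"),
        "params": _sib(prefix, ".params.json"),
    }
    mmwrite(str(paths["connectivities"]), sp.coo_matrix(graph.connectivities))
    mmwrite(str(paths["distances"]), sp.coo_matrix(graph.distances))
    all_params = dict(graph.params)
    if params:
        all_params.update(params)
    with open(paths["params"], "w") as fh:
        json.dump(all_params, fh, indent=2, default=str)
    return {k: str(v) for k, v in paths.items()}


def read_graph(prefix) -> ConnectivityGraph:
    """Read back a graph written by :func:`write_graph`."""
    prefix = Path(prefix)
    W = sp.csr_matrix(mmread(str(_sib(prefix, ".connectivities.mtx"))))
    D = sp.csr_matrix(mmread(str(_sib(prefix, ".distances.mtx"))))
    with open(_sib(prefix, ".params.json")) as fh:
        params = json.load(fh)
    return ConnectivityGraph(connectivities=W, distances=D, params=params)


def write_latent_bundle(lps: LabelledPointSet, out_prefix) -> dict:
    """Write simulated coordinates + metadata as headered CSVs."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    coords_path = _sib(prefix, ".coords.csv")
    meta_path = _sib(prefix, ".metadata.csv")
    dims = [f"dim{j}" for j in range(lps.points.shape[1])]
    pd.DataFrame(lps.points, columns=dims).to_csv(coords_path, index=False)
    pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(lps.n_cells)],
        "batch": lps.batch_labels.labels,
        "type": lps.type_labels,
    }).to_csv(meta_path, index=False)
    return {"coords": str(coords_path), "metadata": str(meta_path)}


def read_latent_bundle(coords_path, metadata_path, batch_column: str = "batch") -> DatasetBundle:
    """Read a coordinates CSV and aligned metadata CSV."""
    coords = pd.read_csv(coords_path).to_numpy(dtype=np.float64)
    meta = pd.read_csv(metadata_path)
    if batch_column not in meta.columns:
        raise SchemaError(
            f"batch column {batch_column!r} not in metadata columns {list(meta.columns)}"
        )
    if len(meta) != coords.shape[0]:
        raise AlignmentError(
            f"metadata has {len(meta)} rows but coordinates have {coords.shape[0]}"
        )
    if "cell_id" in meta.columns:
        ids = meta["cell_id"].astype(str).to_numpy()
        if np.unique(ids).size != ids.size:
            raise AlignmentError("metadata cell_id column contains duplicates")
    else:
        ids = np.array([f"cell{i}" for i in range(coords.shape[0])])
    return DatasetBundle(counts=None, coords=coords, cell_ids=ids, metadata=meta,
                         batch_column=batch_column)


def write_counts_bundle(counts, cell_ids, gene_ids, metadata: pd.DataFrame,
                        out_prefix) -> dict:
    """Write a counts matrix as MTX with barcode/feature TSVs and metadata CSV."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": _sib(prefix, ".mtx"),
        "barcodes": _sib(prefix, ".barcodes.tsv"),
        "features": _sib(prefix, ".features.tsv"),
        "metadata": _sib(prefix, ".metadata.csv"),
    }
    mmwrite(str(paths["matrix"]), sp.coo_matrix(counts))
    pd.Series(cell_ids).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    pd.Series(gene_ids).to_csv(paths["features"], sep="\t", index=False, header=False)
    metadata.to_csv(paths["metadata"], index=False)
    return {k: str(v) for k, v in paths.items()}
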