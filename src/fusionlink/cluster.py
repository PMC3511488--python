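"""Parallel gene-clustering routes: Ward meta-clades on pooled profiles
and a self-organizing map on the per-patient replicate matrix.

The dendrogram route cuts a Euclidean/Ward tree into a small number of
meta-clades labeled by letters in left-to-right leaf order.  The SOM
route trains a rectangular Kohonen map on the per-gene expression
patterns across patient arrays, then Ward-clusters the 240 codebook
vectors into numbered meta-clades that each gene inherits from its
best-matching node.
"""
from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import cdist

DEND = "DEND"
SOM = "SOM"


class ClusterError(ValueError):
    pass


@dataclass
class MetaClade:
    """A labeled gene cluster from either clustering route."""

    label: str
    genes: pd.Index
    route_tag: str  # DEND or SOM
    expression_side: str | None = None  # optional above/below annotation


@dataclass
class SOMGrid:
    """Trained rectangular Kohonen map."""

    rows: int
    cols: int
    codebooks: np.ndarray  # (rows*cols) x n_features, row-major node order
    bmu: pd.Series  # gene -> flat node index
    columns: pd.Index  # feature (sample) identifiers
    patients: pd.Series | None  # sample -> patient alignment, if known
    neighbor_similarity: np.ndarray  # rows x cols mean distance to adjacent nodes
    quantization_errors: list[float]  # per-epoch mean gene-to-BMU distance

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_coords(self) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])


# ----------------------------------------------------------------------
def _leaf_order_labels(z: np.ndarray, assignments: np.ndarray, labels) -> dict[int, str]:
    """Map fcluster ids to display labels in left-to-right dendrogram order."""
    order: list[int] = []
    for leaf in leaves_list(z):
        cid = assignments[leaf]
        if cid not in order:
            order.append(cid)
    return {cid: labels[pos] for pos, cid in enumerate(order)}


def _clade_labels(route_tag: str, k: int) -> list[str]:
    if route_tag == DEND:
        letters = string.ascii_uppercase
        if k <= len(letters):
            return list(letters[:k])
        return [f"C{i + 1}" for i in range(k)]
    return [str(i + 1) for i in range(k)]


def hcluster_metaclades(
    profiles: pd.DataFrame | pd.Series,
    k: int,
    route_tag: str = DEND,
    labels: list[str] | None = None,
) -> list[MetaClade]:
    """Agglomerative Euclidean/Ward clustering of per-gene profiles cut
    at exactly ``k`` clades, labeled in left-to-right dendrogram order."""
    if isinstance(profiles, pd.Series):
        profiles = profiles.to_frame()
    n = len(profiles)
    if k < 2 or k > n:
        raise ClusterError(f"k must lie in [2, {n}], got {k}")
    z = linkage(profiles.to_numpy(dtype=float), method="ward")
    assignments = fcluster(z, t=k, criterion="maxclust")
    if labels is None:
        labels = _clade_labels(route_tag, k)
    mapping = _leaf_order_labels(z, assignments, labels)
    clades = []
    for cid, label in sorted(mapping.items(), key=lambda kv: kv[1]):
        genes = profiles.index[assignments == cid]
        clades.append(MetaClade(label=label, genes=genes, route_tag=route_tag))
    return clades


# ----------------------------------------------------------------------
def _pca_plane_init(data: np.ndarray, rows: int, cols: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Spread initial codebooks over the data's first principal plane."""
    center = data.mean(axis=0)
    centered = data - center
    try:
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - pathological input
        return center + rng.normal(0, 1e-3, size=(rows * cols, data.shape[1]))
    scale = s / max(np.sqrt(max(len(data) - 1, 1)), 1.0)
    a = np.linspace(-2, 2, rows)[:, None] * (scale[0] * vt[0])[None, :]
    if len(s) > 1 and scale[1] > 0:
        b = np.linspace(-2, 2, cols)[:, None] * (scale[1] * vt[1])[None, :]
    else:
        b = np.zeros((cols, data.shape[1]))
    grid = a[:, None, :] + b[None, :, :] + center
    return grid.reshape(rows * cols, data.shape[1])


def train_som(
    patient_matrix: pd.DataFrame,
    rows: int = 20,
    cols: int = 12,
    epochs: int = 200,
    seed: int = 0,
    init: str = "pca",
    patients: pd.Series | None = None,
) -> SOMGrid:
    """Batch-train a rectangular Kohonen map on per-gene row vectors.

    A Gaussian neighborhood with radius decaying linearly from
    ``max(rows, cols)/2`` to 1 smooths the batch updates; with PCA-plane
    initialization the whole procedure is deterministic, and random
    initialization is reproducible from ``seed``.
    """
    if rows * cols < 4:
        raise ClusterError("grid must have at least 4 nodes")
    if patient_matrix.empty:
        raise ClusterError("empty matrix")
    if epochs < 1:
        raise ClusterError("epochs must be >= 1")
    data = patient_matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if init == "pca":
        codebooks = _pca_plane_init(data, rows, cols, rng)
    elif init == "random":
        lo, hi = data.min(axis=0), data.max(axis=0)
        codebooks = rng.uniform(lo, hi, size=(rows * cols, data.shape[1]))
    else:
        raise ClusterError(f"unknown init {init!r}")

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    grid_d2 = cdist(coords, coords, "sqeuclidean")

    sigma0 = max(rows, cols) / 2.0
    sigma_end = 1.0
    qe_history: list[float] = []
    bmu = np.zeros(len(data), dtype=int)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma0 + (sigma_end - sigma0) * frac
        d2 = cdist(data, codebooks, "sqeuclidean")
        bmu = np.argmin(d2, axis=1)
        qe_history.append(float(np.sqrt(d2[np.arange(len(data)), bmu]).mean()))
        h = np.exp(-grid_d2 / (2.0 * sigma * sigma))  # nodes x nodes
        w = h[:, bmu]  # nodes x genes
        denom = w.sum(axis=1)
        numer = w @ data
        update = denom > 1e-300
        codebooks = np.where(update[:, None], numer / np.maximum(denom, 1e-300)[:, None],
                             codebooks)
    # final assignment against the converged codebooks
    d2 = cdist(data, codebooks, "sqeuclidean")
    bmu = np.argmin(d2, axis=1)
    qe_history.append(float(np.sqrt(d2[np.arange(len(data)), bmu]).mean()))

    neighbor = _neighbor_similarity(codebooks, rows, cols)
    if patients is None and isinstance(patient_matrix.columns, pd.Index):
        patients = None
    return SOMGrid(
        rows=rows,
        cols=cols,
        codebooks=codebooks,
        bmu=pd.Series(bmu, index=patient_matrix.index, name="bmu"),
        columns=patient_matrix.columns,
        patients=patients,
        neighbor_similarity=neighbor,
        quantization_errors=qe_history,
    )


def _neighbor_similarity(codebooks: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Per-node mean Euclidean distance to 4-adjacent codebooks (the
    gray-scale similarity map)."""
    cb = codebooks.reshape(rows, cols, -1)
    out = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            dists = []
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    dists.append(np.linalg.norm(cb[r, c] - cb[rr, cc]))
            out[r, c] = float(np.mean(dists))
    return out


# ----------------------------------------------------------------------
def som_metaclades(grid: SOMGrid, k: int) -> tuple[list[MetaClade], np.ndarray]:
    """Ward/Euclidean clustering of the codebook vectors cut at ``k``;
    each gene inherits its node's meta-clade.  Returns the clades plus
    the rows x cols node -> label map."""
    if k > grid.n_nodes:
        raise ClusterError(f"k must not exceed {grid.n_nodes} nodes")
    if k < 2:
        raise ClusterError("k must be >= 2")
    z = linkage(grid.codebooks, method="ward")
    assignments = fcluster(z, t=k, criterion="maxclust")
    mapping = _leaf_order_labels(z, assignments, _clade_labels(SOM, k))
    node_labels = np.array([mapping[cid] for cid in assignments])
    clades = []
    for label in _clade_labels(SOM, k):
        nodes = np.nonzero(node_labels == label)[0]
        genes = grid.bmu.index[np.isin(grid.bmu.to_numpy(), nodes)]
        clades.append(MetaClade(label=label, genes=genes, route_tag=SOM))
    return clades, node_labels.reshape(grid.rows, grid.cols)


def tissue_cell_ratio(metaclades: list[MetaClade], side: pd.Series) -> pd.Series:
    """Per meta-clade ratio of above-PC1 (tissue-over-cell) to below-PC1
    gene counts; an empty denominator yields the ``inf`` sentinel and an
    empty clade ``nan``."""
    out = {}
    for clade in metaclades:
        missing = clade.genes.difference(side.index)
        if len(missing):
            raise ClusterError(f"genes without a side label: {list(missing[:5])}")
        labels = side.loc[clade.genes]
        n_above = int((labels == "above").sum())
        n_below = int((labels == "below").sum())
        if n_above == 0 and n_below == 0:
            out[clade.label] = float("nan")
        elif n_below == 0:
            out[clade.label] = float("inf")
        else:
            out[clade.label] = n_above / n_below
    return pd.Series(out, name="tissue_cell_ratio")
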