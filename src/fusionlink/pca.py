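"""Two-variable PCA of pooled-tissue vs cell expression and the
grid-density elimination of background genes.

The pooled tissue profile and the isolated tumor-cell profile are highly
correlated: most genes express proportionally in both and line up along
the first principal component of the (tissue, cell) scatter.  Those genes
carry no tissue-vs-cell contrast and are treated as background.  A
rectangular grid is overlaid on the scatter and every point falling in a
cell whose occupancy exceeds a percentile of the per-cell counts is
eliminated; the surviving genes are the differentially expressed set,
split into the genes above the first PC (tissue-over-cell side) and
below it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class PCAError(ValueError):
    pass


@dataclass
class PCAResult:
    """2-D PCA of per-gene (tissue, cell) expression points."""

    center: np.ndarray  # mean of (tissue, cell)
    pc1_direction: np.ndarray  # unit vector, oriented into the (+,+) quadrant
    pc2_direction: np.ndarray  # unit vector, positive side toward the tissue axis
    variance_fraction: float  # fraction of total variance on PC1
    scores: pd.DataFrame  # per gene: pc1, pc2 coordinates
    points: pd.DataFrame  # per gene: tissue, cell input coordinates


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid over the scatter's bounding box.

    The percentile threshold is computed over occupied cells only: empty
    cells carry no density information, and at realistic study sizes the
    scatter leaves most of a fine grid empty.
    """

    n_bins_x: int = 50
    n_bins_y: int = 50
    percentile: float = 90.0

    def validate(self) -> None:
        if self.n_bins_x < 2 or self.n_bins_y < 2:
            raise PCAError("grid needs at least 2 bins per axis")
        if not (0 < self.percentile < 100):
            raise PCAError("percentile must be in (0, 100)")


@dataclass
class TrimResult:
    retained_genes: pd.Index
    above_pc1: pd.Index  # positive signed PC2 score (tissue-over-cell side)
    below_pc1: pd.Index
    grid_spec: GridSpec
    count_threshold: float  # per-cell count above which points were removed


# ----------------------------------------------------------------------
def fit_pca2(tissue_pooled: pd.Series, cell_profile: pd.Series) -> PCAResult:
    """Eigendecomposition of the 2x2 covariance of (tissue, cell) pairs.

    Sign conventions: PC1 points into the (+,+) quadrant; PC2 is PC1
    rotated so that its positive side faces the tissue axis, making a
    positive PC2 score mean tissue-over-cell expression.
    """
    if not tissue_pooled.index.equals(cell_profile.index):
        common = tissue_pooled.index.intersection(cell_profile.index)
        if len(common) != len(tissue_pooled) or len(common) != len(cell_profile):
            raise PCAError("tissue and cell profiles must share one gene set")
        cell_profile = cell_profile.loc[tissue_pooled.index]
    if len(tissue_pooled) < 3:
        raise PCAError("need at least 3 genes")
    pts = np.column_stack([tissue_pooled.to_numpy(float), cell_profile.to_numpy(float)])
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    total = float(np.trace(cov))
    if total <= 0:
        raise PCAError("degenerate input: zero variance")
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    pc1 = evecs[:, 1]
    # orient PC1 into the (+,+) quadrant (first-component-positive if mixed)
    if pc1[0] < 0 or (pc1[0] == 0 and pc1[1] < 0):
        pc1 = -pc1
    pc2 = np.array([pc1[1], -pc1[0]])  # rotate -90 deg: tissue side positive
    scores = (pts - center) @ np.column_stack([pc1, pc2])
    return PCAResult(
        center=center,
        pc1_direction=pc1,
        pc2_direction=pc2,
        variance_fraction=float(evals[1] / total),
        scores=pd.DataFrame(scores, index=tissue_pooled.index, columns=["pc1", "pc2"]),
        points=pd.DataFrame(pts, index=tissue_pooled.index, columns=["tissue", "cell"]),
    )


# ----------------------------------------------------------------------
def _cell_indices(coords: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = coords.min(), coords.max()
    if hi == lo:
        return np.zeros(len(coords), dtype=int)
    idx = np.floor((coords - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def grid_density_trim(pca: PCAResult, grid_spec: GridSpec = GridSpec()) -> TrimResult:
    """Eliminate genes in over-dense grid cells of the (tissue, cell)
    scatter; split the survivors by the sign of their PC2 score.

    A point is removed when its cell's count *strictly* exceeds the
    ``percentile`` of counts over occupied cells; with all occupied
    counts equal, nothing is removed.
    """
    grid_spec.validate()
    if pca.points.empty:
        raise PCAError("empty input")
    ix = _cell_indices(pca.points["tissue"].to_numpy(), grid_spec.n_bins_x)
    iy = _cell_indices(pca.points["cell"].to_numpy(), grid_spec.n_bins_y)
    flat = ix * grid_spec.n_bins_y + iy
    cells, inverse, counts = np.unique(flat, return_inverse=True, return_counts=True)
    threshold = float(np.percentile(counts, grid_spec.percentile))
    keep = counts[inverse] <= threshold
    retained = pca.points.index[keep]
    pc2 = pca.scores["pc2"]
    above = retained[pc2.loc[retained].to_numpy() > 0]
    below = retained[pc2.loc[retained].to_numpy() <= 0]  # PC1-line ties go below
    return TrimResult(
        retained_genes=retained,
        above_pc1=above,
        below_pc1=below,
        grid_spec=grid_spec,
        count_threshold=threshold,
    )


def partition_by_pc1(trim: TrimResult, pca: PCAResult) -> tuple[pd.Index, pd.Index]:
    """Above = retained genes whose tissue value exceeds the PC1 line at
    their cell value (positive perpendicular offset toward the tissue
    axis); genes exactly on the line fall below."""
    pc2 = pca.scores["pc2"].loc[trim.retained_genes]
    above = trim.retained_genes[pc2.to_numpy() > 0]
    below = trim.retained_genes[pc2.to_numpy() <= 0]
    return above, below


def side_labels(trim: TrimResult) -> pd.Series:
    """Per-gene ``above``/``below`` label for the retained genes."""
    lab = pd.Series("below", index=trim.retained_genes, name="side")
    lab.loc[trim.above_pc1] = "above"
    return lab
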