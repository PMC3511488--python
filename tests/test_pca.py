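"""Two-variable PCA, grid-density background elimination and the
above/below-PC1 partition."""
import numpy as np
import pandas as pd
import pytest

import fusionlink as fl
from fusionlink.pca import PCAError, _cell_indices


def _series_pair(tissue, cell):
    idx = pd.Index([f"g{i}" for i in range(len(tissue))])
    return pd.Series(tissue, index=idx), pd.Series(cell, index=idx)


class TestFitPCA2:
    def test_perfect_correlation(self):
        t, c = _series_pair([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0])
        res = fl.fit_pca2(t, c)
        assert res.variance_fraction == pytest.approx(1.0)
        np.testing.assert_allclose(res.pc1_direction, [1 / np.sqrt(2)] * 2)

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(50, 2)) @ np.array([[1.0, 0.6], [0.0, 0.8]])
        t, c = _series_pair(pts[:, 0], pts[:, 1])
        res = fl.fit_pca2(t, c)
        evals, evecs = np.linalg.eigh(np.cov(pts.T))
        assert res.variance_fraction == pytest.approx(evals[1] / evals.sum())
        v = evecs[:, 1] if evecs[0, 1] > 0 else -evecs[:, 1]
        np.testing.assert_allclose(np.abs(res.pc1_direction @ v), 1.0, atol=1e-12)

    def test_reconstruction_from_scores(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 2))
        t, c = _series_pair(pts[:, 0], pts[:, 1])
        res = fl.fit_pca2(t, c)
        basis = np.column_stack([res.pc1_direction, res.pc2_direction])
        rebuilt = res.center + res.scores.to_numpy() @ basis.T
        np.testing.assert_allclose(rebuilt, pts, atol=1e-12)

    def test_variance_fraction_invariant_to_axis_swap_and_rescale(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.7], [0.0, 0.4]])
        t, c = _series_pair(pts[:, 0], pts[:, 1])
        vf = fl.fit_pca2(t, c).variance_fraction
        assert fl.fit_pca2(c, t).variance_fraction == pytest.approx(vf)
        assert fl.fit_pca2(3.0 * t, 3.0 * c).variance_fraction == pytest.approx(vf)

    def test_zero_variance_is_degenerate(self):
        t, c = _series_pair([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        with pytest.raises(PCAError):
            fl.fit_pca2(t, c)


class TestGridDensityTrim:
    def test_uniform_occupancy_retains_everything(self):
        # one point per cell: all counts tie, strict inequality keeps all
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        t, c = _series_pair(xs.ravel(), ys.ravel())
        res = fl.grid_density_trim(fl.fit_pca2(t, c), fl.GridSpec(5, 5, 90.0))
        assert len(res.retained_genes) == 25

    def test_dense_cell_eliminated_sparse_kept(self):
        rng = np.random.default_rng(3)
        dense = np.full((100, 2), 0.5) + rng.normal(0, 1e-3, size=(100, 2))
        sparse = np.column_stack([np.linspace(1, 9, 30), np.linspace(9, 1, 30)])
        pts = np.vstack([dense, sparse])
        t, c = _series_pair(pts[:, 0], pts[:, 1])
        res = fl.grid_density_trim(fl.fit_pca2(t, c), fl.GridSpec(10, 10, 90.0))
        retained = set(res.retained_genes)
        assert all(f"g{i}" not in retained for i in range(100))
        assert sum(f"g{100 + i}" in retained for i in range(30)) >= 28

    def test_planted_offdiagonal_genes_survive(self):
        rng = np.random.default_rng(7)
        diag = rng.normal(size=1000)
        band = np.column_stack([diag, diag + rng.normal(0, 0.05, 1000)])
        planted = np.column_stack(
            [rng.uniform(-2, 2, 50), rng.uniform(-2, 2, 50) + 3.0]
        )
        pts = np.vstack([band, planted])
        t, c = _series_pair(pts[:, 0], pts[:, 1])
        res = fl.grid_density_trim(fl.fit_pca2(t, c), fl.GridSpec(50, 50, 90.0))
        retained = set(res.retained_genes)
        assert all(f"g{1000 + i}" in retained for i in range(50))

    @pytest.mark.parametrize("low,high", [(50.0, 90.0), (70.0, 95.0)])
    def test_raising_percentile_never_removes_more(self, low, high):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(500, 2))
        t, c = _series_pair(pts[:, 0], pts[:, 1])
        pca = fl.fit_pca2(t, c)
        kept_low = set(fl.grid_density_trim(pca, fl.GridSpec(20, 20, low)).retained_genes)
        kept_high = set(fl.grid_density_trim(pca, fl.GridSpec(20, 20, high)).retained_genes)
        assert kept_low <= kept_high

    def test_partition_is_disjoint_cover(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(300, 2))
        t, c = _series_pair(pts[:, 0], pts[:, 1])
        res = fl.grid_density_trim(fl.fit_pca2(t, c), fl.GridSpec(10, 10, 90.0))
        assert set(res.above_pc1) | set(res.below_pc1) == set(res.retained_genes)
        assert not (set(res.above_pc1) & set(res.below_pc1))

    def test_invalid_grid_rejected(self):
        t, c = _series_pair([0.0, 1.0, 2.0], [0.0, 1.1, 1.9])
        pca = fl.fit_pca2(t, c)
        with pytest.raises(PCAError):
            fl.grid_density_trim(pca, fl.GridSpec(1, 10, 90.0))
        with pytest.raises(PCAError):
            fl.grid_density_trim(pca, fl.GridSpec(10, 10, 100.0))

    def test_degenerate_axis_collapses_to_single_bin(self):
        assert list(_cell_indices(np.array([2.0, 2.0, 2.0]), 5)) == [0, 0, 0]


class TestPartitionByPC1:
    def test_tissue_heavy_gene_is_above(self):
        # diagonal cloud plus one gene far on the tissue side
        t, c = _series_pair([0.0, 1.0, 2.0, 3.0, 2.0], [0.0, 1.0, 2.0, 3.0, 0.0])
        pca = fl.fit_pca2(t, c)
        trim = fl.grid_density_trim(pca, fl.GridSpec(4, 4, 90.0))
        above, below = fl.partition_by_pc1(trim, pca)
        assert "g4" in set(above)

    def test_gene_on_the_line_falls_below(self):
        t, c = _series_pair([0.0, 1.0, 2.0, 3.0, 2.0], [0.0, 1.0, 2.0, 3.0, 0.0])
        pca = fl.fit_pca2(t, c)
        on_line = pca.scores.index[np.abs(pca.scores["pc2"].to_numpy()) < 1e-12]
        trim = fl.grid_density_trim(pca, fl.GridSpec(4, 4, 90.0))
        _, below = fl.partition_by_pc1(trim, pca)
        assert set(on_line) & set(trim.retained_genes) <= set(below)

    def test_matches_cross_product_oracle(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.9], [0.0, 0.3]])
        t, c = _series_pair(pts[:, 0], pts[:, 1])
        pca = fl.fit_pca2(t, c)
        trim = fl.grid_density_trim(pca, fl.GridSpec(15, 15, 95.0))
        above, below = fl.partition_by_pc1(trim, pca)
        v = pts - pca.center
        cross = v[:, 0] * pca.pc1_direction[1] - v[:, 1] * pca.pc1_direction[0]
        oracle_above = set(pca.points.index[cross > 0]) & set(trim.retained_genes)
        assert set(above) == oracle_above
        assert set(below) == set(trim.retained_genes) - oracle_above
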