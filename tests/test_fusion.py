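"""The tumor-fraction-free slope model: ratio transforms, per-gene fits,
codebook correlation maps and target classification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fusionlink as fl
from fusionlink.fusion import FusionModelError


class TestRatioTransforms:
    def test_worked_example(self):
        assert fl.observed_to_tumor_ratio(10.0, 0.1) == 91.0

    def test_pure_tumor_is_identity(self):
        for obs in (0.3, 1.0, 7.5):
            assert fl.observed_to_tumor_ratio(obs, 1.0) == pytest.approx(obs)

    def test_unit_ratio_is_fraction_invariant(self):
        for f in (0.05, 0.4, 1.0):
            assert fl.observed_to_tumor_ratio(1.0, f) == 1.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(FusionModelError):
            fl.observed_to_tumor_ratio(2.0, 0.0)
        with pytest.raises(FusionModelError):
            fl.tumor_to_observed_ratio(2.0, -0.5)

    @settings(max_examples=200, derandomize=True)
    @given(
        f=st.floats(min_value=1e-6, max_value=1.0),
        r=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_transforms_are_mutual_inverses(self, f, r):
        obs = fl.tumor_to_observed_ratio(r, f)
        if obs <= 0:  # forward map can leave the valid ratio domain
            return
        back = fl.observed_to_tumor_ratio(obs, f)
        assert back == pytest.approx(r, rel=1e-9, abs=1e-9)


def _panel(values, patients=None):
    patients = patients or [f"P{i + 1}" for i in range(len(values))]
    return fl.FusionPanel(R=pd.Series(values, index=patients))


class TestFitGeneSlope:
    def test_proportional_intensity_is_positive(self):
        panel = _panel([0.1, 0.2, 0.4, 0.8])
        fit = fl.fit_gene_slope(pd.Series([1.0, 2.0, 4.0, 8.0], index=panel.R.index,
                                          name="g"), panel)
        assert fit.pcc == pytest.approx(1.0)
        assert fit.slope_sign == "positive"

    def test_constant_intensity_is_null(self):
        panel = _panel([0.1, 0.2, 0.4])
        fit = fl.fit_gene_slope(pd.Series([3.0, 3.0, 3.0], index=panel.R.index,
                                          name="g"), panel)
        assert fit.slope == 0.0
        assert fit.slope_sign == "null"

    def test_constant_fusion_is_degenerate(self):
        panel = _panel([0.5, 0.5, 0.5])
        with pytest.raises(FusionModelError):
            fl.fit_gene_slope(pd.Series([1.0, 2.0, 3.0], index=panel.R.index), panel)

    def test_needs_three_patients(self):
        panel = _panel([0.1, 0.9])
        with pytest.raises(FusionModelError):
            fl.fit_gene_slope(pd.Series([1.0, 2.0], index=panel.R.index), panel)

    def test_sign_invariant_to_positive_rescaling_of_fusion(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.1, 1.0, 7)
        y = 2.0 + 3.0 * x + rng.normal(0, 0.05, 7)
        base = fl.fit_gene_slope(
            pd.Series(y, index=[f"P{i}" for i in range(7)], name="g"),
            _panel(x, [f"P{i}" for i in range(7)]),
        )
        scaled = fl.fit_gene_slope(
            pd.Series(y, index=[f"P{i}" for i in range(7)], name="g"),
            _panel(123.4 * x, [f"P{i}" for i in range(7)]),
        )
        assert base.slope_sign == scaled.slope_sign == "positive"
        assert scaled.pcc == pytest.approx(base.pcc)
        assert scaled.p_value == pytest.approx(base.p_value)

    def test_noise_free_planted_modules_recover_sign(self):
        mods = (
            fl.PlantedModule("up", tuple(range(10)), 5.0),
            fl.PlantedModule("down", tuple(range(10, 20)), 0.2),
        )
        c = fl.generate_cohort(
            fl.SimConfig(n_genes=60, noise_sd=0.0, planted_modules=mods,
                         nontumor_equals_reference=True, seed=3)
        )
        fits = fl.fit_gene_slopes(c.tissue, c.fusion)
        assert (fits.loc[c.truth.module_genes("up"), "sign"] == "positive").all()
        assert (fits.loc[c.truth.module_genes("down"), "sign"] == "negative").all()

    def test_collapsed_fit_uses_one_point_per_patient(self, small_cohort):
        fits = fl.fit_gene_slopes(small_cohort.tissue, small_cohort.fusion)
        assert (fits["n_points"] == 7).all()
        fits_all = fl.fit_gene_slopes(small_cohort.tissue, small_cohort.fusion,
                                      collapse_replicates=False)
        assert (fits_all["n_points"] == 14).all()


class TestCodebookCorrelationMap:
    def _grid(self, codebooks, patients):
        n_nodes = len(codebooks)
        return fl.SOMGrid(
            rows=1, cols=n_nodes, codebooks=np.asarray(codebooks, dtype=float),
            bmu=pd.Series(dtype=int),
            columns=pd.Index(patients.index), patients=patients,
            neighbor_similarity=np.zeros((1, n_nodes)),
            quantization_errors=[],
        )

    def test_affine_codebook_is_perfectly_correlated(self):
        patients = pd.Series([f"P{i}" for i in range(5)],
                             index=[f"s{i}" for i in range(5)])
        panel = _panel([0.1, 0.2, 0.3, 0.5, 0.8], list(patients))
        grid = self._grid([2.0 + 3.0 * panel.R.to_numpy()], patients)
        pcc = fl.codebook_correlation_map(grid, panel)
        assert pcc[0, 0] == pytest.approx(1.0)

    def test_orthogonal_codebook_is_uncorrelated(self):
        patients = pd.Series([f"P{i}" for i in range(4)],
                             index=[f"s{i}" for i in range(4)])
        panel = _panel([1.0, 2.0, 3.0, 4.0], list(patients))
        codebook = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to centered R
        grid = self._grid([codebook], patients)
        assert fl.codebook_correlation_map(grid, panel)[0, 0] == pytest.approx(0.0)

    def test_matches_direct_pcc_oracle(self):
        rng = np.random.default_rng(14)
        patients = pd.Series([f"P{i}" for i in range(6)],
                             index=[f"s{i}" for i in range(6)])
        panel = _panel(list(rng.uniform(0.1, 1.0, 6)), list(patients))
        codebooks = rng.normal(size=(4, 6))
        grid = self._grid(codebooks, patients)
        pcc = fl.codebook_correlation_map(grid, panel).ravel()
        for j in range(4):
            expected = np.corrcoef(codebooks[j], panel.R.to_numpy())[0, 1]
            assert pcc[j] == pytest.approx(expected)

    def test_replicate_columns_carry_patient_abundance(self, small_cohort):
        tissue = small_cohort.tissue
        from fusionlink.preprocess import log_ratio

        grid = fl.train_som(log_ratio(tissue).values, rows=4, cols=4, epochs=10,
                            seed=0, patients=tissue.patients)
        pcc = fl.codebook_correlation_map(grid, small_cohort.fusion)
        assert pcc.shape == (4, 4)
        assert np.all(np.abs(pcc) <= 1 + 1e-12)


class TestClassifyTargets:
    def _shared(self, genes):
        return pd.DataFrame({"pathway": ["pw"] * len(genes), "gene": genes})

    def _fits(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "intercept", "slope", "pcc", "p_value",
                           "n_points", "sign"],
        ).set_index("gene_id")

    def test_all_positive_means_no_controls(self):
        fits = self._fits([("g1", 0, 2.0, 0.9, 0.01, 7, "positive"),
                           ("g2", 0, 1.0, 0.8, 0.02, 7, "positive")])
        report = fl.classify_targets(self._shared(["g1", "g2"]), fits)
        assert list(report.candidates.index) == ["g1", "g2"]
        assert report.controls.empty

    def test_null_gene_excluded_under_significance_gate(self):
        fits = self._fits([("g1", 0, 2.0, 0.9, 0.01, 7, "positive"),
                           ("g2", 0, 0.5, 0.2, 0.60, 7, "null")])
        report = fl.classify_targets(self._shared(["g1", "g2"]), fits,
                                     require_significance=True)
        assert "g2" not in set(report.candidates.index) | set(report.controls.index)

    def test_zero_slope_excluded_by_default(self):
        fits = self._fits([("g1", 0, 0.0, 0.0, 1.0, 7, "null")])
        report = fl.classify_targets(self._shared(["g1"]), fits)
        assert report.candidates.empty and report.controls.empty

    def test_missing_fit_rejected(self):
        fits = self._fits([("g1", 0, 1.0, 0.9, 0.01, 7, "positive")])
        with pytest.raises(FusionModelError):
            fl.classify_targets(self._shared(["g1", "gX"]), fits)

    def test_pathway_annotation_joined(self):
        shared = pd.DataFrame({"pathway": ["pw1", "pw2"], "gene": ["g1", "g1"]})
        fits = self._fits([("g1", 0, -1.0, -0.9, 0.01, 7, "negative")])
        report = fl.classify_targets(shared, fits)
        assert report.controls.loc["g1", "pathways"] == "pw1,pw2"
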