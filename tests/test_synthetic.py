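import numpy as np
import pandas as pd
import pytest

from ecocouple import quadrant as quad
from ecocouple import synthetic as syn


class TestCoupledStacks:
    def test_seed_determinism(self):
        spec = syn.SyntheticRasterSpec(seed=5)
        h1, e1 = syn.generate_coupled_stacks(spec)
        h2, e2 = syn.generate_coupled_stacks(syn.SyntheticRasterSpec(seed=5))
        for a, b in zip(h1.grids + e1.grids, h2.grids + e2.grids):
            assert np.array_equal(a.values, b.values)
            assert np.array_equal(a.mask, b.mask)

    def test_different_seed_differs(self):
        h1, _ = syn.generate_coupled_stacks(syn.SyntheticRasterSpec(seed=1))
        h2, _ = syn.generate_coupled_stacks(syn.SyntheticRasterSpec(seed=2))
        assert not np.array_equal(h1.grids[0].values, h2.grids[0].values)

    def test_block_means_follow_planted_trends(self):
        spec = syn.SyntheticRasterSpec(noise_sd=0.5, nodata_fraction=0.0, seed=3)
        hfi, _ = syn.generate_coupled_stacks(spec)
        delta = hfi.grid(2010).values - hfi.grid(2000).values
        for b in spec.blocks:
            dh, _ = spec.block_trend(b)
            block_mean = delta[b.row0:b.row1, b.col0:b.col1].mean()
            assert block_mean == pytest.approx(dh, abs=0.3)

    def test_masks_identical_across_epochs_and_stacks(self):
        spec = syn.SyntheticRasterSpec(nodata_fraction=0.1, seed=4)
        hfi, eqi = syn.generate_coupled_stacks(spec)
        ref = hfi.grids[0].mask
        for g in hfi.grids + eqi.grids:
            assert np.array_equal(g.mask, ref)
        assert 0.0 < ref.mean() < 0.2

    def test_overlapping_blocks_rejected(self):
        blocks = [syn.Block(0, 60, 0, 40, "coordination"),
                  syn.Block(0, 60, 30, 60, "conflict")]
        with pytest.raises(ValueError, match="overlap"):
            syn.SyntheticRasterSpec(blocks=blocks)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            syn.SyntheticRasterSpec(shape=(1, 5))

    def test_trend_sign_contradiction_rejected(self):
        trends = {"coordination": (-6.0, 4.0), "good_for_nature": (-5.0, 4.0),
                  "degradation": (-4.0, -4.0), "conflict": (10.0, -5.0),
                  "insignificant": (0.0, 0.0)}
        with pytest.raises(ValueError, match="contradict"):
            syn.SyntheticRasterSpec(trend_magnitudes=trends)

    def test_weak_trend_below_threshold_rejected(self):
        trends = {"coordination": (0.1, 4.0), "good_for_nature": (-5.0, 4.0),
                  "degradation": (-4.0, -4.0), "conflict": (10.0, -5.0),
                  "insignificant": (0.0, 0.0)}
        with pytest.raises(ValueError, match="does not exceed"):
            syn.SyntheticRasterSpec(trend_magnitudes=trends)

    def test_calibrated_spec_sits_at_stated_threshold_multiple(self):
        spec = syn.calibrated_quadrant_spec(noise_sd=0.3, factor=3.0)
        sig_h, sig_e = spec.change_sigmas()
        weak = [b for b in spec.blocks if b.cls == "coordination"][-1]
        assert weak.trend[0] / (0.1 * sig_h) == pytest.approx(3.0, abs=1e-6)
        assert weak.trend[1] / (0.1 * sig_e) == pytest.approx(3.0, abs=1e-6)

    def test_zero_noise_planting_recovered_exactly_downstream(self):
        fracs = dict.fromkeys(
            ["coordination", "good_for_nature", "degradation", "conflict"], 0.25)
        spec = syn.SyntheticRasterSpec(blocks=syn.strip_layout((20, 20), fracs),
                                       shape=(20, 20), noise_sd=0.0,
                                       nodata_fraction=0.0, seed=0)
        hfi, eqi = syn.generate_coupled_stacks(spec)
        qmap = quad.classify_quadrant(quad.period_change(hfi, eqi, 2000, 2010))
        assert (qmap.names() == spec.class_map()).all()


class TestSemTable:
    def test_single_path_correlation_matches_population_algebra(self):
        ms = syn.LatentModelSpec.standardized(
            ["A", "B"], {("A", "B"): 0.6},
            {"A": ["a1"], "B": ["b1"]}, {"a1": 0.9, "b1": 0.9}, n=5000, seed=0)
        table, truth = syn.generate_sem_table(ms)
        assert truth.paths.loc["B", "A"] == pytest.approx(0.6)
        r = table["a1"].corr(table["b1"])
        assert r == pytest.approx(0.9 * 0.6 * 0.9, abs=0.03)

    def test_zero_paths_give_independent_blocks(self):
        ms = syn.LatentModelSpec.standardized(
            ["A", "B"], {("A", "B"): 0.0},
            {"A": ["a1"], "B": ["b1"]}, {"a1": 0.9, "b1": 0.9}, n=4000, seed=1)
        table, _ = syn.generate_sem_table(ms)
        assert abs(table["a1"].corr(table["b1"])) < 0.05

    def test_noiseless_unit_loadings_reproduce_latents(self):
        ms = syn.LatentModelSpec(
            ["A"], np.zeros((1, 1)), {"A": ["a1", "a2"]},
            {"a1": 1.0, "a2": 1.0}, {}, {"a1": 0.0, "a2": 0.0}, n=50, seed=2)
        table, _ = syn.generate_sem_table(ms)
        assert np.allclose(table["a1"], table["a2"])

    def test_non_lower_triangular_rejected(self):
        B = np.zeros((2, 2)); B[0, 1] = 0.3
        with pytest.raises(ValueError, match="lower-triangular"):
            syn.LatentModelSpec(["A", "B"], B, {"A": ["a1"], "B": ["b1"]},
                                {"a1": 0.9, "b1": 0.9}, {}, {}, n=100)

    def test_infeasible_standardized_paths_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            syn.LatentModelSpec.standardized(
                ["A", "B", "C"], {("A", "C"): 0.9, ("B", "C"): 0.9},
                {"A": ["a"], "B": ["b"], "C": ["c"]},
                {"a": 0.9, "b": 0.9, "c": 0.9}, n=200)

    def test_default_model_latent_correlations_are_valid(self):
        ms = syn.default_latent_model(n=500, seed=0)
        corr = ms.latent_cov()
        assert np.allclose(np.diag(corr), 1.0, atol=1e-9)
        assert np.linalg.eigvalsh(corr).min() > 0


class TestDriverRasters:
    def test_planted_correlation_recovered(self):
        layers = syn.generate_driver_rasters((100, 100), {("PRE", "TEM"): 0.8}, seed=0)
        r = np.corrcoef(layers["PRE"].values.ravel(), layers["TEM"].values.ravel())[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_orthogonal_by_default(self):
        layers = syn.generate_driver_rasters((80, 80), None, seed=1)
        r = np.corrcoef(layers["NL"].values.ravel(), layers["GDP"].values.ravel())[0, 1]
        assert abs(r) < 0.05

    def test_infeasible_correlation_matrix_rejected(self):
        pairs = {("PRE", "TEM"): 0.95, ("TEM", "ET"): 0.95, ("PRE", "ET"): -0.95}
        with pytest.raises(ValueError, match="positive semi-definite"):
            syn.generate_driver_rasters((10, 10), pairs)

    def test_deterministic_for_seed(self):
        a = syn.generate_driver_rasters((20, 20), {("NL", "PD"): 0.5}, seed=9)
        b = syn.generate_driver_rasters((20, 20), {("NL", "PD"): 0.5}, seed=9)
        assert np.array_equal(a["NL"].values, b["NL"].values)


class TestDriversFromResponse:
    def test_cross_covariance_matches_latent_model(self):
        ms = syn.default_latent_model(n=5000, seed=0)
        rng = np.random.default_rng(0)
        response = rng.normal(size=5000)
        table = syn.generate_drivers_from_response(response, ms, seed=1)
        z = (response - response.mean()) / response.std()
        truth = syn._standardized_truth(ms)
        expected = truth.latent_corr.loc["Veg", "CCD"] * truth.loadings["FVC"]
        got = float(np.corrcoef(table["FVC"], z)[0, 1])
        assert got == pytest.approx(expected, abs=0.05)
        assert list(table.columns) == syn.DRIVER_NAMES
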