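import numpy as np
import pandas as pd
import pytest

from conftest import fake_fit, two_latent_table

from ecocouple import plspm, synthetic as syn


def chained_ols_paths(table, spec):
    """Oracle: standardized OLS of each endogenous manifest on its predecessors."""
    Z = (table - table.mean()) / table.std(ddof=0)
    out = {}
    for latent in spec.endogenous:
        y = Z[spec.blocks[latent][0]].to_numpy()
        preds = [spec.blocks[p][0] for p in spec.predecessors(latent)]
        X = Z[preds].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        for p, b in zip(spec.predecessors(latent), beta):
            out[(p, latent)] = float(b)
    return out


class TestFit:
    def test_single_indicator_model_reduces_to_chained_ols(self, rng):
        names = ["Ter", "Hum", "Clm", "Veg", "CCD"]
        blocks = {n: [f"{n.lower()}_x"] for n in names}
        edges = plspm.default_path_model().edges
        spec = plspm.PathModelSpec(names, blocks, edges)
        ms = syn.LatentModelSpec.standardized(
            names, syn.DEFAULT_TRUE_PATHS, blocks,
            {c: 1.0 for b in blocks.values() for c in b}, n=800, seed=0)
        table, _ = syn.generate_sem_table(ms)
        fit = plspm.fit_pls_pm(table, spec)
        oracle = chained_ols_paths(table, spec)
        for (s, d), b in oracle.items():
            assert fit.path_coefficients.loc[d, s] == pytest.approx(b, abs=1e-8)
        # scores equal the standardized indicators themselves
        for n in names:
            col = table[blocks[n][0]]
            z = (col - col.mean()) / col.std(ddof=0)
            assert np.allclose(np.abs(fit.scores[n]), np.abs(z), atol=1e-8)

    def test_latent_scores_standardized(self):
        table, _ = two_latent_table(0.4, n=600, seed=1)
        fit = plspm.fit_pls_pm(table, plspm.PathModelSpec(
            ["A", "B"], {"A": ["a1", "a2"], "B": ["b1", "b2"]}, [("A", "B")]))
        assert np.allclose(fit.scores.mean(), 0, atol=1e-8)
        assert np.allclose(fit.scores.std(ddof=0), 1, atol=1e-8)
        assert fit.converged

    def test_no_structure_estimates_near_zero(self):
        table, _ = two_latent_table(0.0, n=2000, seed=2)
        fit = plspm.fit_pls_pm(table, plspm.PathModelSpec(
            ["A", "B"], {"A": ["a1", "a2"], "B": ["b1", "b2"]}, [("A", "B")]))
        assert abs(fit.path_coefficients.loc["B", "A"]) < 0.05

    def test_parameter_recovery_on_default_model(self):
        errs = []
        for seed in range(10):
            ms = syn.default_latent_model(n=5000, seed=seed)
            table, truth = syn.generate_sem_table(ms)
            fit = plspm.fit_pls_pm(table)
            errs.extend(abs(fit.path_coefficients.loc[d, s] - v)
                        for (s, d), v in syn.DEFAULT_TRUE_PATHS.items())
        assert np.mean(errs) < 0.06

    def test_loadings_positive_under_sign_convention(self):
        ms = syn.default_latent_model(n=1000, seed=3)
        table, _ = syn.generate_sem_table(ms)
        fit = plspm.fit_pls_pm(table)
        for latent, inds in fit.spec.blocks.items():
            assert sum(fit.loadings[c] for c in inds) > 0

    def test_inner_schemes_agree_to_first_decimals(self):
        ms = syn.default_latent_model(n=3000, seed=4)
        table, _ = syn.generate_sem_table(ms)
        fits = {s: plspm.fit_pls_pm(table, plspm.default_path_model(inner_scheme=s))
                for s in ("path", "centroid", "factorial")}
        for s, d in fits["path"].spec.edges:
            vals = [f.path_coefficients.loc[d, s] for f in fits.values()]
            assert max(vals) - min(vals) < 0.03

    def test_constant_indicator_rejected(self):
        table, _ = two_latent_table(0.3, n=300, seed=5)
        table["a1"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            plspm.fit_pls_pm(table, plspm.PathModelSpec(
                ["A", "B"], {"A": ["a1", "a2"], "B": ["b1", "b2"]}, [("A", "B")]))

    def test_gof_invariant_to_indicator_order(self):
        ms = syn.default_latent_model(n=800, seed=6)
        table, _ = syn.generate_sem_table(ms)
        fit1 = plspm.fit_pls_pm(table)
        spec = plspm.default_path_model()
        shuffled = plspm.PathModelSpec(
            spec.latent_names,
            {k: list(reversed(v)) for k, v in spec.blocks.items()},
            spec.edges)
        fit2 = plspm.fit_pls_pm(table, shuffled)
        assert fit1.gof == pytest.approx(fit2.gof, abs=1e-10)


class TestGof:
    @pytest.mark.parametrize("comm,r2,expect,label", [
        (1.0, 0.25, 0.5, "strong"),
        (1.0, 0.0, 0.0, "poor"),
        (0.81, 0.16, 0.36, "strong"),   # boundary closed from above
        (0.5, 0.05, np.sqrt(0.025), "weak"),
    ])
    def test_formula_and_labels(self, comm, r2, expect, label):
        value = float(np.sqrt(comm * r2))
        assert value == pytest.approx(expect)
        assert plspm.gof_label(value) == (value, label)

    @pytest.mark.parametrize("value,label", [
        (0.10, "weak"), (0.25, "medium"), (0.36, "strong"), (0.0999, "poor")])
    def test_threshold_boundaries(self, value, label):
        assert plspm.gof_label(value)[1] == label


class TestEffects:
    def test_single_indirect_path(self):
        fit = fake_fit(["Ter", "Hum", "CCD"],
                       [("Ter", "Hum"), ("Hum", "CCD"), ("Ter", "CCD")],
                       {("Ter", "Hum"): -0.4, ("Hum", "CCD"): 0.5, ("Ter", "CCD"): -0.2})
        eff = plspm.effects(fit)
        assert eff.effect("Ter", "CCD", "indirect") == pytest.approx(-0.20)
        assert eff.effect("Ter", "CCD", "total") == pytest.approx(-0.40)

    def test_multi_path_enumeration(self):
        fit = fake_fit(
            ["Hum", "Clm", "Veg", "CCD"],
            [("Hum", "Clm"), ("Clm", "Veg"), ("Veg", "CCD"),
             ("Hum", "Veg"), ("Hum", "CCD"), ("Clm", "CCD")],
            {("Hum", "Clm"): 0.3, ("Clm", "Veg"): 0.4, ("Veg", "CCD"): 0.5,
             ("Hum", "Veg"): 0.2, ("Hum", "CCD"): 0.1, ("Clm", "CCD"): 0.0})
        eff = plspm.effects(fit)
        assert eff.effect("Hum", "CCD", "indirect") == pytest.approx(0.16)
        assert eff.effect("Hum", "CCD", "total") == pytest.approx(0.26)

    def test_absent_pair_has_zero_effects(self):
        fit = fake_fit(["A", "B", "C"], [("A", "B")], {("A", "B"): 0.5})
        eff = plspm.effects(fit)
        assert eff.effect("B", "C", "total") == 0.0
        assert eff.effect("A", "C", "total") == 0.0

    def test_matches_matrix_power_identity_on_random_dags(self, rng):
        for _ in range(25):
            p = int(rng.integers(3, 7))
            names = [f"L{i}" for i in range(p)]
            edges, coeffs = [], {}
            for i in range(p):
                for j in range(i + 1, p):
                    if rng.random() < 0.6:
                        edges.append((names[i], names[j]))
                        coeffs[(names[i], names[j])] = float(rng.normal() * 0.5)
            if not edges:
                continue
            fit = fake_fit(names, edges, coeffs)
            eff = plspm.effects(fit)
            total = plspm.total_effects_matrix(fit)
            for _, row in eff.table.iterrows():
                assert row["total"] == pytest.approx(
                    total.loc[row["target"], row["source"]], abs=1e-10)
                assert row["total"] == pytest.approx(
                    row["direct"] + row["indirect"], abs=1e-12)


class TestBootstrap:
    def test_strong_path_flagged_highly_significant(self):
        table, _ = two_latent_table(0.6, n=1000, seed=0)
        spec = plspm.PathModelSpec(["A", "B"],
                                   {"A": ["a1", "a2"], "B": ["b1", "b2"]}, [("A", "B")])
        boot = plspm.bootstrap_inference(table, spec, B=199, seed=0)
        assert boot.table.stars.iloc[0] == "***"
        assert boot.table.ci_lo.iloc[0] > 0.4

    def test_near_degenerate_sampling_variability(self):
        # Huge n is a proxy for resampling the same empirical distribution:
        # the bootstrap SE must shrink toward 0.
        small, _ = two_latent_table(0.5, n=200, seed=1)
        big, _ = two_latent_table(0.5, n=8000, seed=1)
        spec = plspm.PathModelSpec(["A", "B"],
                                   {"A": ["a1", "a2"], "B": ["b1", "b2"]}, [("A", "B")])
        se_small = plspm.bootstrap_inference(small, spec, B=150, seed=2).table.se.iloc[0]
        se_big = plspm.bootstrap_inference(big, spec, B=150, seed=2).table.se.iloc[0]
        assert se_big < se_small / 3

    def test_minimum_resamples_enforced(self):
        table, _ = two_latent_table(0.5, n=200, seed=3)
        with pytest.raises(ValueError, match="at least 100"):
            plspm.bootstrap_inference(table, B=50)


class TestSpecValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="forward"):
            plspm.PathModelSpec(["A", "B"], {"A": ["a"], "B": ["b"]},
                                [("A", "B"), ("B", "A")])

    def test_duplicate_indicator_rejected(self):
        with pytest.raises(ValueError, match="more than one block"):
            plspm.PathModelSpec(["A", "B"], {"A": ["x"], "B": ["x"]}, [("A", "B")])

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            plspm.PathModelSpec(["A", "B"], {"A": ["a"], "B": []}, [("A", "B")])
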