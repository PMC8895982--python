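import numpy as np
import pandas as pd
import pytest

from magicgp.gp import (
    MCMCSettings,
    PredictorSpec,
    fit_censored,
    fit_gaussian,
    fit_lognormal_count,
    fit_ordinal_threshold,
    predict_new_lines,
)
from magicgp.simulate import SimulationConfig, simulate_ordinal_trait

FAST = MCMCSettings(n_iter=2000, burn_in=400, thin=2, seed=9)


def _per_line_spec(line=True, markers=True, epi=False):
    return PredictorSpec(include_replicate=False, include_line=line,
                         include_markers=markers, include_epistasis=epi)


def _sim_gaussian(kernel_pair, rng, s2L=0.3, s2g=1.0, s2e=1.0):
    G, _ = kernel_pair
    n = G.n_lines
    L = rng.standard_normal(n) * np.sqrt(s2L)
    g = G.eigenvectors @ (np.sqrt(np.clip(G.eigenvalues, 0, None) * s2g)
                          * rng.standard_normal(n))
    y = L + g + rng.standard_normal(n) * np.sqrt(s2e)
    return pd.Series(y, index=G.line_ids), L, g


class TestPredictorSpec:
    def test_table_of_five_models(self):
        expected = {1: ("L",), 2: ("G",), 3: ("G", "GxG"),
                    4: ("L", "G"), 5: ("L", "G", "GxG")}
        for m, terms in expected.items():
            assert tuple(PredictorSpec.from_model_number(m).term_names) == terms

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PredictorSpec(include_line=False, include_markers=False)
        with pytest.raises(ValueError):
            PredictorSpec(include_markers=False, include_epistasis=True)
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, burn_in=200)


class TestGaussian:
    def test_zero_variance_response_collapses(self, kernel_pair):
        G, _ = kernel_pair
        y = pd.Series(5.0, index=G.line_ids)
        fit = fit_gaussian(y, _per_line_spec(), kernel_pair, FAST)
        assert np.allclose(fit.fitted, 5.0, atol=0.3)
        assert fit.variance_components.loc["residual", "mean"] < 0.5

    def test_seed_determinism(self, kernel_pair, rng):
        y, *_ = _sim_gaussian(kernel_pair, rng)
        a = fit_gaussian(y, _per_line_spec(), kernel_pair, FAST)
        b = fit_gaussian(y, _per_line_spec(), kernel_pair, FAST)
        pd.testing.assert_frame_equal(a.variance_components, b.variance_components)
        np.testing.assert_array_equal(a.fitted, b.fitted)

    def test_nesting_reduces_residual_variance(self, kernel_pair, rng):
        y, *_ = _sim_gaussian(kernel_pair, rng, s2g=2.0, s2e=0.5)
        small = fit_gaussian(y, _per_line_spec(markers=False), kernel_pair, FAST)
        big = fit_gaussian(y, _per_line_spec(), kernel_pair, FAST)
        r_small = small.variance_components.loc["residual", "mean"]
        r_big = big.variance_components.loc["residual", "mean"]
        assert r_big <= r_small + 0.15  # within MCMC noise

    def test_missing_values_rejected(self, kernel_pair):
        G, _ = kernel_pair
        y = pd.Series(np.nan, index=G.line_ids)
        with pytest.raises(ValueError, match="missing"):
            fit_gaussian(y, _per_line_spec(), kernel_pair, FAST)


class TestCensored:
    def test_degenerate_intervals_match_gaussian(self, kernel_pair, rng):
        y, *_ = _sim_gaussian(kernel_pair, rng)
        obs = pd.DataFrame({"line": y.index, "value": y.to_numpy(),
                            "lower": y.to_numpy(), "upper": y.to_numpy()})
        settings = MCMCSettings(n_iter=6000, burn_in=1000, thin=2, seed=5)
        a = fit_censored(obs, _per_line_spec(), kernel_pair, settings)
        b = fit_gaussian(y, _per_line_spec(), kernel_pair, settings)
        np.testing.assert_allclose(
            a.effects["G"]["mean"], b.effects["G"]["mean"], atol=0.1)
        np.testing.assert_allclose(a.fitted, b.fitted, atol=0.15)

    def test_wide_bounds_revert_to_linear_predictor(self, kernel_pair, rng):
        y, *_ = _sim_gaussian(kernel_pair, rng)
        obs = pd.DataFrame({"line": y.index, "value": y.to_numpy(),
                            "lower": y.to_numpy(), "upper": y.to_numpy()})
        j = 7
        obs.loc[j, ["value", "lower", "upper"]] = [np.nan, -1e6, 1e6]
        fit = fit_censored(obs, _per_line_spec(), kernel_pair,
                           MCMCSettings(n_iter=4000, burn_in=800, thin=2, seed=5))
        # a data-free interval observation cannot pull its line's fit:
        # its fitted value stays near the shrinkage-null (0) rather than any
        # extreme, and remains finite
        assert abs(fit.fitted[j]) < 2.0

    def test_inverted_bounds_rejected(self, kernel_pair):
        G, _ = kernel_pair
        obs = pd.DataFrame({"line": G.line_ids, "value": 0.0,
                            "lower": 1.0, "upper": -1.0})
        with pytest.raises(ValueError, match="a < b"):
            fit_censored(obs, _per_line_spec(), kernel_pair, FAST)


@pytest.fixture(scope="module")
def ordinal_fit(small_geno, kernel_pair):
    cfg = SimulationConfig(
        n_lines=60, n_markers=400, n_replicates=6, seed=2,
        variance_components={"sigma2_L": 0.2, "sigma2_g": 0.5,
                             "sigma2_gA": 0.0, "sigma2_e": 1.0},
        thresholds=(-1.0, 0.0, 1.0), fixed_effects=(0.0,) * 6)
    tab, _ = simulate_ordinal_trait(small_geno, kernel_pair, cfg)
    spec = PredictorSpec(include_replicate=True, include_line=False,
                         include_markers=True, include_epistasis=False)
    return fit_ordinal_threshold(tab, spec, kernel_pair,
                                 MCMCSettings(n_iter=3000, burn_in=600,
                                              thin=2, seed=3))


class TestOrdinal:
    def test_probabilities_normalize(self, ordinal_fit):
        sums = ordinal_fit.fitted_probs.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_thresholds_increase_in_every_draw(self, ordinal_fit):
        diffs = np.diff(ordinal_fit.gamma_draws, axis=1)
        assert (diffs > 0).all()

    def test_residual_variance_fixed_at_one(self, ordinal_fit):
        assert ordinal_fit.variance_components.loc["residual", "mean"] == 1.0
        assert ordinal_fit.residual_fixed

    def test_single_category_rejected(self, kernel_pair):
        G, _ = kernel_pair
        tab = pd.DataFrame({"line": G.line_ids, "replicate": "r1", "value": 5})
        with pytest.raises(ValueError, match="degenerate ordinal"):
            fit_ordinal_threshold(tab, PredictorSpec(), kernel_pair, FAST)

    def test_empty_intermediate_category_warns(self, kernel_pair):
        G, _ = kernel_pair
        vals = np.where(np.arange(G.n_lines) % 2, 2, 5)  # labels 3,4 unobserved
        tab = pd.DataFrame({"line": G.line_ids, "replicate": "r1", "value": vals})
        spec = PredictorSpec(include_replicate=True, include_line=True,
                             include_markers=False, include_epistasis=False)
        with pytest.warns(UserWarning, match="unobserved"):
            fit = fit_ordinal_threshold(tab, spec, kernel_pair, FAST)
        assert fit.category_labels == [2, 3, 4, 5]


class TestLognormalCount:
    def test_constant_counts_back_transform(self, kernel_pair):
        G, _ = kernel_pair
        tab = pd.DataFrame({"line": np.repeat(G.line_ids, 2),
                            "replicate": np.tile(["r1", "r2"], G.n_lines),
                            "value": 5})
        spec = PredictorSpec(include_replicate=True, include_line=True,
                             include_markers=False, include_epistasis=False)
        fit = fit_lognormal_count(tab, spec, kernel_pair, FAST)
        np.testing.assert_allclose(fit.fitted_counts, 5.0, atol=0.6)

    def test_draw_for_draw_equivalence_with_gaussian(self, kernel_pair, rng):
        G, _ = kernel_pair
        counts = rng.integers(0, 9, size=G.n_lines * 2)
        tab = pd.DataFrame({"line": np.repeat(G.line_ids, 2),
                            "replicate": np.tile(["r1", "r2"], G.n_lines),
                            "value": counts})
        spec = PredictorSpec(include_replicate=True, include_line=False,
                             include_markers=True, include_epistasis=False)
        a = fit_lognormal_count(tab, spec, kernel_pair, FAST)
        logt = tab.assign(value=np.log(tab["value"] + 1.0))
        b = fit_gaussian(logt, spec, kernel_pair, FAST)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)
        np.testing.assert_array_equal(a.var_draws["G"], b.var_draws["G"])

    def test_negative_counts_rejected(self, kernel_pair):
        G, _ = kernel_pair
        tab = pd.DataFrame({"line": G.line_ids, "replicate": "r1", "value": -1})
        with pytest.raises(ValueError, match="nonnegative"):
            fit_lognormal_count(tab, PredictorSpec(), kernel_pair, FAST)


class TestPrediction:
    def test_training_line_reproduced_through_identity_rows(self, kernel_pair, rng):
        G, GxG = kernel_pair
        y, *_ = _sim_gaussian(kernel_pair, rng)
        fit = fit_gaussian(y, _per_line_spec(), kernel_pair, FAST,
                           include_intercept=False)
        n = G.n_lines
        rows_L = np.eye(n)[:5]
        pred = predict_new_lines(
            fit, {"L": rows_L, "G": G.matrix[:5]}, new_line_ids=G.line_ids[:5])
        expected = (fit.effects["L"]["mean"].to_numpy()[:5]
                    + fit.effects["G"]["mean"].to_numpy()[:5])
        np.testing.assert_allclose(pred["prediction"], expected, atol=1e-8)

    def test_duplicate_kernel_row_gives_identical_prediction(self, kernel_pair, rng):
        G, _ = kernel_pair
        y, *_ = _sim_gaussian(kernel_pair, rng)
        fit = fit_gaussian(y, _per_line_spec(line=False), kernel_pair, FAST)
        rows = np.vstack([G.matrix[3], G.matrix[3]])
        pred = predict_new_lines(fit, {"G": rows})
        assert pred["prediction"].iloc[0] == pytest.approx(pred["prediction"].iloc[1])

    def test_held_out_lines_recover_genetic_values(self):
        """Correlation(predicted, true g) > 0.5 for 50 held-out lines at
        high heritability with 400 training lines."""
        from magicgp.kernels import epistatic_kernel, vanraden_g
        from magicgp.simulate import simulate_magic_genotypes

        cfg = SimulationConfig(n_lines=450, n_markers=600, seed=61)
        geno = simulate_magic_genotypes(cfg)
        G = vanraden_g(geno)
        rng = np.random.default_rng(62)
        g_true = G.eigenvectors @ (np.sqrt(np.clip(G.eigenvalues, 0, None) * 1.0)
                                   * rng.standard_normal(450))
        y = g_true + rng.standard_normal(450) * np.sqrt(0.25)  # h2 = 0.8 scale-wise
        train, test = geno.line_ids[:400], geno.line_ids[400:]
        G_train = G.subset(train)
        fit = fit_gaussian(pd.Series(y[:400], index=train),
                           _per_line_spec(line=False), (G_train,),
                           MCMCSettings(n_iter=4000, burn_in=800, thin=2, seed=63))
        rows = G.cross_rows(test, train)
        pred = predict_new_lines(fit, {"G": rows}, new_line_ids=test)
        r = np.corrcoef(pred["prediction"], g_true[400:])[0, 1]
        assert r > 0.5

    def test_mismatched_rows_rejected(self, kernel_pair, rng):
        G, _ = kernel_pair
        y, *_ = _sim_gaussian(kernel_pair, rng)
        fit = fit_gaussian(y, _per_line_spec(line=False), kernel_pair, FAST)
        with pytest.raises(ValueError, match="training lines expected"):
            predict_new_lines(fit, {"G": np.ones((1, 3))})
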