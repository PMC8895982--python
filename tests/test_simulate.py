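import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from magicgp.kernels import epistatic_kernel, identity_kernel, vanraden_g
from magicgp.simulate import (
    SimulationConfig,
    simulate_censored_trait,
    simulate_count_trait,
    simulate_magic_genotypes,
    simulate_ordinal_trait,
    simulate_tr_vpd_curves,
)


def _id_kernels(n):
    """Identity G and GxG stand-ins for tests that bypass marker structure."""
    k = identity_kernel([f"M{i+1:03d}" for i in range(n)])
    from magicgp.kernels import Kernel, eigendecompose
    G = eigendecompose(Kernel("G", k.line_ids, k.matrix))
    return G, eigendecompose(Kernel("GxG", k.line_ids, k.matrix))


class TestGenotypes:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_lines=20, n_markers=150, seed=7)
        a = simulate_magic_genotypes(cfg)
        b = simulate_magic_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_single_founder_monomorphic(self):
        cfg = SimulationConfig(n_lines=15, n_markers=60, n_founders=1, seed=3)
        g = simulate_magic_genotypes(cfg)
        assert (g.dosages.max(axis=0) == g.dosages.min(axis=0)).all()

    def test_fully_inbred_dosages(self, small_geno):
        assert set(np.unique(small_geno.dosages)) <= {0.0, 2.0}

    def test_heterozygosity_rate(self):
        cfg = SimulationConfig(n_lines=40, n_markers=300, seed=5, het_rate=0.1)
        g = simulate_magic_genotypes(cfg)
        frac = (g.dosages == 1.0).mean()
        assert 0.05 < frac < 0.15

    def test_allele_frequencies_track_founder_panel(self):
        """Mosaic lines sample founders ~uniformly, so per-marker allele
        frequencies should match the founder-panel mixture within 3 SE."""
        cfg = SimulationConfig(n_lines=500, n_markers=300, seed=11,
                               maf_range=(0.1, 0.5), segment_length_mean=20)
        g = simulate_magic_genotypes(cfg)
        freq = g.dosages.mean(axis=0) / 2.0
        # founder-panel frequency is k/8 by construction; recover it from the
        # observed frequency rounded to the nearest eighth
        panel = np.round(freq * 8) / 8
        se = np.sqrt(panel * (1 - panel) / cfg.n_lines) + 1e-12
        assert (np.abs(freq - panel) < 3 * se + 0.5 / cfg.n_lines).mean() > 0.95

    def test_bad_dimensions(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_lines=0, n_markers=10)


class TestOrdinalTrait:
    def test_sign_of_residual_decides_with_zero_threshold(self):
        n = 600
        cfg = SimulationConfig(
            n_lines=n, n_markers=10, n_replicates=1, seed=13,
            variance_components={"sigma2_L": 0, "sigma2_g": 0,
                                 "sigma2_gA": 0, "sigma2_e": 1},
            thresholds=(0.0,), fixed_effects=(0.0,))
        tab, _ = simulate_ordinal_trait(
            simulate_magic_genotypes(cfg), _id_kernels(n), cfg)
        p1 = (tab["value"] == 1).mean()
        se = np.sqrt(0.25 / len(tab))
        assert abs(p1 - 0.5) < 3 * se

    def test_no_genetic_signal_gives_iid_replicates(self):
        n, reps = 150, 8
        cfg = SimulationConfig(
            n_lines=n, n_markers=10, n_replicates=reps, seed=17,
            variance_components={"sigma2_L": 0, "sigma2_g": 0,
                                 "sigma2_gA": 0, "sigma2_e": 1},
            thresholds=(-0.5, 0.5), fixed_effects=(0.0,) * reps)
        tab, truth = simulate_ordinal_trait(
            simulate_magic_genotypes(cfg), _id_kernels(n), cfg)
        assert np.allclose(truth.genetic_value, 0.0)
        line_means = tab.groupby("line")["value"].mean()
        # between-line variance of means ~ within-variance / reps under iid
        within = tab.groupby("line")["value"].var().mean()
        assert line_means.var() < 2.0 * within / reps * 3

    def test_category_frequencies_match_probit_probabilities(self):
        gamma = tuple(norm.ppf([0.05, 0.15, 0.35, 0.6, 0.8, 0.95]))
        n = 400
        cfg = SimulationConfig(
            n_lines=n, n_markers=10, n_replicates=4, seed=19,
            variance_components={"sigma2_L": 0, "sigma2_g": 0,
                                 "sigma2_gA": 0, "sigma2_e": 1},
            thresholds=gamma, fixed_effects=(0.0,) * 4)
        tab, _ = simulate_ordinal_trait(
            simulate_magic_genotypes(cfg), _id_kernels(n), cfg)
        expected = np.diff(np.concatenate(
            ([0.0], norm.cdf(gamma), [1.0])))
        counts = tab["value"].value_counts(normalize=True).sort_index().to_numpy()
        se = np.sqrt(expected * (1 - expected) / len(tab))
        assert np.all(np.abs(counts - expected) < 3 * se + 1e-3)

    def test_labels_span_threshold_categories(self, small_geno, kernel_pair):
        cfg = SimulationConfig(
            n_lines=60, n_markers=400, n_replicates=12, seed=1,
            thresholds=tuple(np.linspace(-1.5, 1.5, 6)),
            fixed_effects=(0.0,) * 12)
        tab, _ = simulate_ordinal_trait(small_geno, kernel_pair, cfg)
        assert tab["value"].between(2, 8).all()

    def test_nonincreasing_thresholds_rejected(self, small_geno, kernel_pair):
        cfg = SimulationConfig(n_lines=60, n_markers=400, seed=1)
        cfg.thresholds = (1.0, 0.0)  # bypasses __post_init__; op must re-check
        with pytest.raises(ValueError, match="increasing"):
            simulate_ordinal_trait(small_geno, kernel_pair, cfg)


class TestCountTrait:
    def test_deterministic_inverse_transform(self):
        n = 25
        cfg = SimulationConfig(
            n_lines=n, n_markers=10, n_replicates=3, seed=23,
            variance_components={"sigma2_L": 0, "sigma2_g": 0,
                                 "sigma2_gA": 0, "sigma2_e": 0},
            fixed_effects=(np.log(6.0),) * 3)
        tab, _ = simulate_count_trait(
            simulate_magic_genotypes(cfg), _id_kernels(n), cfg)
        assert (tab["value"] == 5).all()

    def test_zero_latent_gives_zero_counts(self):
        n = 25
        cfg = SimulationConfig(
            n_lines=n, n_markers=10, n_replicates=2, seed=29,
            variance_components={"sigma2_L": 0, "sigma2_g": 0,
                                 "sigma2_gA": 0, "sigma2_e": 0},
            fixed_effects=(0.0, 0.0))
        tab, _ = simulate_count_trait(
            simulate_magic_genotypes(cfg), _id_kernels(n), cfg)
        assert (tab["value"] == 0).all()

    def test_log_scale_variance_partition(self):
        """Line-mean vs within-line variance of log(y+1) reflects the
        generating heritable fraction (0.5) within 20% relative error."""
        n, reps = 400, 10
        s2 = 0.25
        cfg = SimulationConfig(
            n_lines=n, n_markers=10, n_replicates=reps, seed=31,
            variance_components={"sigma2_L": s2, "sigma2_g": 0.0,
                                 "sigma2_gA": 0.0, "sigma2_e": s2},
            fixed_effects=(2.0,) * reps)
        tab, truth = simulate_count_trait(
            simulate_magic_genotypes(cfg), _id_kernels(n), cfg)
        z = np.log(tab["value"].to_numpy() + 1.0)
        tab = tab.assign(z=z)
        within = tab.groupby("line")["z"].var().mean()
        between = tab.groupby("line")["z"].mean().var() - within / reps
        frac = between / (between + within)
        assert abs(frac - 0.5) < 0.1


class TestCensoredTrait:
    def test_degenerate_interval_at_zero_sd(self, small_geno, kernel_pair):
        cfg = SimulationConfig(n_lines=60, n_markers=400, seed=1, n_replicates=1,
                               fixed_effects=(0.0,))
        tab, _ = simulate_censored_trait(small_geno, kernel_pair, cfg, obs_sd=0.0)
        np.testing.assert_array_equal(tab["lower"], tab["value"])
        np.testing.assert_array_equal(tab["upper"], tab["value"])

    def test_bounds_bracket_value(self, small_geno, kernel_pair):
        cfg = SimulationConfig(n_lines=60, n_markers=400, seed=1, n_replicates=1,
                               fixed_effects=(0.0,))
        tab, _ = simulate_censored_trait(small_geno, kernel_pair, cfg, obs_sd=1.5)
        assert (tab["lower"] < tab["value"]).all()
        assert (tab["value"] < tab["upper"]).all()

    def test_negative_sd_rejected(self, small_geno, kernel_pair):
        cfg = SimulationConfig(n_lines=60, n_markers=400, seed=1)
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_censored_trait(small_geno, kernel_pair, cfg, obs_sd=-1.0)

    def test_total_variance_matches_generating_model(self):
        """var(y) ~ s2L + s2g*mean(diag G) + s2gA*mean(diag GxG) + s2e."""
        cfg = SimulationConfig(
            n_lines=1000, n_markers=400, seed=37, n_replicates=1,
            variance_components={"sigma2_L": 0.5, "sigma2_g": 0.8,
                                 "sigma2_gA": 0.3, "sigma2_e": 1.0},
            fixed_effects=(0.0,))
        geno = simulate_magic_genotypes(cfg)
        G = vanraden_g(geno)
        GxG = epistatic_kernel(G)
        tab, _ = simulate_censored_trait(geno, (G, GxG), cfg, obs_sd=0.0)
        expected = (0.5 + 0.8 * np.diag(G.matrix).mean()
                    + 0.3 * np.diag(GxG.matrix).mean() + 1.0)
        assert abs(tab["value"].var() / expected - 1.0) < 0.15


class TestTRCurves:
    def test_noiseless_linear_curves_are_exact(self):
        cs = simulate_tr_vpd_curves(10, fraction_linear=1.0, noise_sd=0.0, seed=41)
        for line, sub in cs.curves.groupby("line"):
            tr_truth = cs.truth.set_index("line").loc[line]
            fitted = np.polyfit(sub["vpd"], sub["tr"], 1)
            assert fitted[0] == pytest.approx(tr_truth["slope1"], abs=1e-10)

    def test_segmented_curves_are_continuous(self):
        grid = np.arange(0.4, 5.41, 0.1)
        cs = simulate_tr_vpd_curves(
            30, vpd_grid=grid, fraction_linear=0.0, noise_sd=0.0, seed=43)
        t = cs.truth.set_index("line")
        for line, sub in cs.curves.groupby("line"):
            row = t.loc[line]
            bp, b0, s1, s2 = row["breakpoint"], row["intercept"], row["slope1"], row["slope2"]
            lhs = b0 + s1 * bp
            rhs = b0 + s1 * bp + s2 * 0.0
            assert lhs == pytest.approx(rhs)
            # model evaluations just left/right of bp agree in the limit
            eps = 1e-9
            left = b0 + s1 * (bp - eps)
            right = b0 + s1 * bp + s2 * eps
            assert left == pytest.approx(right, abs=1e-6)

    def test_determinism(self):
        a = simulate_tr_vpd_curves(12, seed=47)
        b = simulate_tr_vpd_curves(12, seed=47)
        pd.testing.assert_frame_equal(a.curves, b.curves)

    def test_breakpoint_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            simulate_tr_vpd_curves(5, vpd_grid=np.linspace(2.4, 5.4, 8),
                                   breakpoint_range=(2.3, 2.5))
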