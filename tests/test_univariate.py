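"""Random-effects prediction-interval screen: components, intervals, p, q."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metabeq import (
    RunConfig,
    equivalence_p_value,
    new_line_prediction_interval,
    pvalue_histogram,
    storey_qvalues,
    variance_components_mom,
)
from metabeq import test_all_metabolites as screen_metabolites
from metabeq.matrix import ConfigError
from metabeq.simulate import SyntheticConfig, apply_perturbations, simulate_panel
from tests.conftest import make_matrix


class TestVarianceComponents:
    def test_hand_worked_one_way_anova(self):
        # SSW = 6 on 3 df, SSB = 64 on 2 df -> MSW 2, MSB 32, components 2 and 15
        vc = variance_components_mom({"A": (1, 3), "B": (5, 7), "C": (9, 11)})
        assert vc.ms_within == pytest.approx(2.0)
        assert vc.ms_between == pytest.approx(32.0)
        assert vc.sigma2_error == pytest.approx(2.0)
        assert vc.sigma2_line == pytest.approx(15.0)
        assert vc.df_between == 2 and vc.df_within == 3
        assert not vc.negative_truncated

    def test_constant_data_zero_components(self):
        vc = variance_components_mom({"A": (4, 4), "B": (4, 4), "C": (4, 4)})
        assert vc.sigma2_line == 0.0 and vc.sigma2_error == 0.0

    def test_zero_within_noise(self):
        vc = variance_components_mom({"A": (0, 0), "B": (0, 0), "C": (10, 10)})
        assert vc.sigma2_error == 0.0
        assert vc.sigma2_line == pytest.approx(np.var([0, 0, 10], ddof=1))

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            variance_components_mom({"A": (1, 2, 3)})

    def test_negative_component_truncated_but_recorded(self):
        # strong within-line spread, line means nearly equal
        vc = variance_components_mom({"A": (0, 10), "B": (1, 9), "C": (2, 8)})
        assert vc.sigma2_line == 0.0
        assert vc.negative_truncated
        assert vc.sigma2_line_untruncated < 0.0

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_mom_identity_on_balanced_data(self, seed):
        """var(line means) == sigma2_line_untruncated + sigma2_error/m exactly."""
        rng = np.random.default_rng(seed)
        k, m = rng.integers(3, 10), rng.integers(2, 6)
        data = {f"L{i}": rng.normal(rng.normal(0, 2), 1.0, size=m) for i in range(k)}
        vc = variance_components_mom(data)
        lm = np.array([np.mean(v) for v in data.values()])
        assert np.var(lm, ddof=1) == pytest.approx(
            vc.sigma2_line_untruncated + vc.sigma2_error / m, rel=1e-10
        )


class TestPredictionInterval:
    def test_hand_worked_t_interval(self):
        # means (2,6,10): s2_lm = 16, se = sqrt(16*4/3), t(.975, 2) = 4.3027
        pi = new_line_prediction_interval([2, 6, 10], alpha=0.05)
        assert pi.center == pytest.approx(6.0)
        assert pi.lower == pytest.approx(-13.8731, abs=1e-4)
        assert pi.upper == pytest.approx(25.8731, abs=1e-4)
        assert pi.df == 2

    def test_degenerate_interval_flagged(self):
        pi = new_line_prediction_interval([3, 3, 3], alpha=0.05)
        assert (pi.lower, pi.center, pi.upper) == (3.0, 3.0, 3.0)
        assert pi.degenerate

    @pytest.mark.parametrize("alphas", [(0.05, 0.5), (0.01, 0.1)])
    def test_wider_alpha_nested_inside(self, alphas):
        tight, loose = alphas
        rng = np.random.default_rng(0)
        means = rng.normal(0, 3, size=8)
        wide = new_line_prediction_interval(means, alpha=tight)
        narrow = new_line_prediction_interval(means, alpha=loose)
        assert wide.lower < narrow.lower < narrow.upper < wide.upper

    def test_component_substitution_for_different_m(self):
        data = {f"L{i}": np.random.default_rng(i).normal(i, 1, 8) for i in range(6)}
        vc = variance_components_mom(data)
        lm = [np.mean(v) for v in data.values()]
        pi8 = new_line_prediction_interval(lm, vc, new_line_m=8)
        pi1 = new_line_prediction_interval(lm, vc, new_line_m=1)
        # fewer seeds in the new line -> more predictive variance -> wider PI
        assert (pi1.upper - pi1.lower) > (pi8.upper - pi8.lower)
        # matching m reduces to the plain line-means variance
        assert pi8.upper == pytest.approx(
            new_line_prediction_interval(lm, alpha=0.05).upper
        )


class TestEquivalencePValue:
    def test_new_mean_at_center_gives_p_one(self):
        assert equivalence_p_value([0, 1, 2], 1.0) == pytest.approx(1.0)

    def test_hand_worked_t_cdf(self):
        # t = 2/sqrt(4/3) = 1.732, df 2: closed form F(t) = 1/2 + t/(2 sqrt(2+t^2))
        assert equivalence_p_value([0, 1, 2], 3.0) == pytest.approx(0.2254, abs=1e-4)

    def test_duality_p_at_interval_bound_equals_alpha(self):
        rng = np.random.default_rng(3)
        means = rng.normal(5, 2, size=12)
        for alpha in (0.05, 0.2):
            pi = new_line_prediction_interval(means, alpha=alpha)
            assert equivalence_p_value(means, pi.upper) == pytest.approx(alpha, abs=1e-12)
            assert equivalence_p_value(means, pi.lower) == pytest.approx(alpha, abs=1e-12)

    def test_degenerate_variance(self):
        assert equivalence_p_value([2, 2, 2], 2.0) == 1.0
        assert equivalence_p_value([2, 2, 2], 3.0) == 0.0

    def test_oracle_brute_force_t_test(self):
        """Interval inversion agrees with the direct t statistic to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = int(rng.integers(3, 60))
            means = rng.normal(rng.normal(0, 5), rng.uniform(0.1, 4), size=k)
            new = rng.normal(0, 10)
            t = (new - means.mean()) / np.sqrt(np.var(means, ddof=1) * (1 + 1 / k))
            expected = 2 * stats.t.sf(abs(t), k - 1)
            assert equivalence_p_value(means, new) == pytest.approx(expected, abs=1e-10)


class TestStoreyQValues:
    def test_bh_reduction_hand_example(self):
        q, pi0 = storey_qvalues([0.01, 0.04, 0.9], pi0=1.0)
        np.testing.assert_allclose(q, [0.03, 0.06, 0.9])

    def test_equal_ps_share_q(self):
        q, _ = storey_qvalues([0.5] * 4, pi0=1.0)
        np.testing.assert_allclose(q, 0.5)

    def test_single_p(self):
        q, pi0 = storey_qvalues([0.2])
        assert pi0 == 1.0  # m < 100 falls back
        assert q[0] == pytest.approx(0.2)

    def test_small_m_uses_pi0_one(self, caplog):
        with caplog.at_level("INFO", logger="metabeq.univariate"):
            _, pi0 = storey_qvalues(np.linspace(0.01, 0.99, 50))
        assert pi0 == 1.0

    def test_spline_pi0_near_one_for_uniform_ps(self):
        rng = np.random.default_rng(11)
        _, pi0 = storey_qvalues(rng.uniform(size=2000))
        assert 0.8 <= pi0 <= 1.0

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=200))
    def test_monotone_in_p_and_bounded_by_pi0(self, ps):
        q, pi0 = storey_qvalues(ps)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert (q <= pi0 + 1e-12).all()


class TestPValueHistogram:
    def test_evenly_spread_ps_one_per_bin(self):
        counts, edges = pvalue_histogram(np.arange(0.05, 1.0, 0.1), n_bins=10)
        assert (counts == 1).all()
        assert edges[0] == 0.0 and edges[-1] == 1.0

    def test_p_equal_one_lands_in_last_bin(self):
        counts, _ = pvalue_histogram([1.0], n_bins=5)
        assert counts[-1] == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=137)
        counts, _ = pvalue_histogram(p, n_bins=7)
        assert counts.sum() == 137


class TestScreenAllMetabolites:
    def test_shape_and_finiteness(self, small_panel):
        matrix, _ = small_panel
        res = screen_metabolites(matrix, RunConfig(test_line="L10", new_line_m=4))
        assert len(res) == 20
        assert np.isfinite(res["p_value"]).all()
        assert np.isfinite(res["q_value"]).all()
        assert ((res["p_value"] >= 0) & (res["p_value"] <= 1)).all()

    def test_inside_flag_dual_to_p(self, small_panel):
        matrix, _ = small_panel
        cfg = RunConfig(test_line="L10", new_line_m=4, alpha=0.2)
        res = screen_metabolites(matrix, cfg)
        assert (res["inside_interval"] == (res["p_value"] > 0.2)).all()
        within = (res["new_line_mean"] >= res["pi_lower"]) & (
            res["new_line_mean"] <= res["pi_upper"]
        )
        assert (res["inside_interval"] == within).all()

    def test_spiked_metabolite_attains_smallest_p(self, small_panel):
        matrix, truth = small_panel
        matrix, _ = apply_perturbations(matrix, truth, [("L10", "M005", 6.0)])
        res = screen_metabolites(matrix, RunConfig(test_line="L10", new_line_m=4))
        assert res["p_value"].idxmin() == "M005"

    def test_all_null_test_line_flagged(self):
        cfg = SyntheticConfig(n_lines=6, n_seeds_per_line=3, n_metabolites=4,
                              detection_quantile=0.0, rng_seed=1)
        matrix, _ = simulate_panel(cfg)
        vals = matrix.values.copy()
        vals.loc[matrix.samples_of("L06"), "M002"] = np.nan
        matrix = matrix.with_values(vals)
        res = screen_metabolites(matrix, RunConfig(test_line="L06", new_line_m=3))
        assert bool(res.loc["M002", "all_null_in_test_line"])
        assert not res["all_null_in_test_line"].drop("M002").any()

    def test_absent_test_line_rejected(self, small_panel):
        matrix, _ = small_panel
        with pytest.raises(ConfigError):
            screen_metabolites(matrix, RunConfig(test_line="L99"))
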