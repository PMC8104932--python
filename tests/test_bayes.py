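"""Bayesian core: transforms, conjugate oracle, ev statistic, sampler."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bayesase.bayes import (
    ConditionData,
    ModelInput,
    SamplerConfig,
    compute_ev,
    conjugate_posterior,
    fit_batch,
    fit_comparison,
    fit_table,
    pi_from_theta,
    theta_from_pi,
)

probs = st.floats(0.01, 0.99)


class TestTransforms:
    def test_balanced_theta_equal_bias_gives_half(self):
        assert pi_from_theta(0.5, 0.7, 0.7) == pytest.approx(0.5)

    def test_asymmetric_bias(self):
        # 0.45 / (0.45 + 0.05)
        assert pi_from_theta(0.5, 0.9, 0.1) == pytest.approx(0.9)

    def test_boundary_limit(self):
        assert pi_from_theta(1 - 1e-12, 0.8, 0.6) == pytest.approx(1.0)

    def test_inverse_example(self):
        assert theta_from_pi(0.9, 0.9, 0.1) == pytest.approx(0.5)

    def test_no_bias_identity(self):
        assert theta_from_pi(0.37, 0.6, 0.6) == pytest.approx(0.37)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(theta=probs, q1=probs, q2=probs)
    def test_roundtrip(self, theta, q1, q2):
        pi = pi_from_theta(theta, q1, q2)
        assert theta_from_pi(pi, q1, q2) == pytest.approx(theta, abs=1e-12)


class TestConjugatePosterior:
    def test_symmetric_counts_symmetric_posterior(self):
        o = conjugate_posterior(50, 50, 0.8, 0.8)
        assert (o.alpha, o.beta) == (51, 51)
        assert o.theta_mean() == pytest.approx(0.5, abs=1e-6)

    def test_beta_mean_formula(self):
        o = conjugate_posterior(400, 100, 0.7, 0.7)
        assert o.theta_mean() == pytest.approx(401 / 502, abs=1e-4)

    def test_no_data_returns_prior(self):
        o = conjugate_posterior(0, 0, 0.5, 0.5, a=2.0, b=3.0)
        assert (o.alpha, o.beta) == (2.0, 3.0)

    def test_quantiles_monotone(self):
        o = conjugate_posterior(30, 10, 0.9, 0.6)
        qs = o.theta_quantile(np.array([0.025, 0.5, 0.975]))
        assert qs[0] < qs[1] < qs[2]


class TestComputeEv:
    def test_median_at_null_gives_one(self):
        assert compute_ev([0.4, 0.45, 0.55, 0.6], 0.5) == 1.0

    def test_all_draws_above_null_gives_zero(self):
        assert compute_ev([0.6, 0.7, 0.8], 0.5) == 0.0

    def test_fixed_convention_example(self):
        draws = [0.3, 0.45, 0.55, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95]
        assert compute_ev(draws, 0.5) == pytest.approx(0.4)

    def test_empty_draws_error(self):
        with pytest.raises(ValueError):
            compute_ev([], 0.5)

    def test_matches_bruteforce_interval_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            draws = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2), rng.integers(5, 200))
            null = rng.uniform(-1.5, 1.5)
            assert abs(compute_ev(draws, null) - ev_bruteforce(draws, null)) <= 1e-3 + 1e-12


def ev_bruteforce(draws, null, step=1e-3):
    """Smallest ev on a grid whose 1-ev equal-tailed interval excludes the null."""
    draws = np.sort(np.asarray(draws, float))
    n = draws.size

    def quantile(p):
        k = min(max(int(np.ceil(p * n)), 1), n)
        return draws[k - 1]

    for ev in np.arange(1, int(round(1 / step)) + 1) * step:
        lo, hi = quantile(ev / 2), quantile(1 - ev / 2)
        if null < lo or null > hi:
            return ev
    return 1.0


def model(x1, y1, q1=0.5, q2=0.5, x2=None, y2=None, q1b=None, q2b=None, a=1.0, b=1.0):
    cond2 = None
    if x2 is not None:
        cond2 = ConditionData(x2, y2, q1b or q1, q2b or q2)
    return ModelInput("f", "cmp", ConditionData(x1, y1, q1, q2), cond2, a=a, b=b)


class TestFitComparison:
    def test_symmetric_conditions_no_difference(self, fast_config):
        s = fit_comparison(model(500, 500, x2=500, y2=500), fast_config)
        assert abs(s.delta_mean) < 0.05
        assert s.ev_h3 > 0.5

    def test_matches_conjugate_oracle(self):
        cfg = SamplerConfig(seed=3)
        s = fit_comparison(model(400, 100, x2=100, y2=400), cfg)
        assert s.theta1_mean == pytest.approx(401 / 502, abs=0.01)
        assert s.theta2_mean == pytest.approx(101 / 502, abs=0.01)
        assert s.ev_h3 == 0.0
        o = conjugate_posterior(400, 100, 0.5, 0.5)
        assert s.theta1_ci_low == pytest.approx(o.theta_quantile(0.025), abs=0.01)
        assert s.theta1_ci_high == pytest.approx(o.theta_quantile(0.975), abs=0.01)

    def test_bias_corrected_counts_show_no_imbalance(self):
        # 90:10 counts are fully explained by q1=0.9, q2=0.1 mapping bias
        s = fit_comparison(model(90, 10, q1=0.9, q2=0.1), SamplerConfig(seed=4))
        assert s.theta1_mean == pytest.approx(0.5, abs=0.05)
        assert s.ev_h1 > 0.5

    def test_single_condition_mode_fills_only_h1(self, fast_config):
        s = fit_comparison(model(40, 20), fast_config)
        assert s.ev_h1 is not None and s.ev_h2 is None and s.ev_h3 is None
        assert s.theta2_mean is None

    def test_determinism(self, fast_config):
        a = fit_comparison(model(30, 70, x2=50, y2=50), fast_config)
        b = fit_comparison(model(30, 70, x2=50, y2=50), fast_config)
        assert a == b

    def test_interval_brackets_mean(self, fast_config):
        s = fit_comparison(model(33, 11), fast_config)
        assert s.theta1_ci_low <= s.theta1_mean <= s.theta1_ci_high

    def test_no_informative_reads_anywhere_rejected(self):
        with pytest.raises(ValueError):
            model(0, 0)


class TestSymmetries:
    def test_label_symmetry(self):
        """Swapping (x<->y, q1<->q2) in both conditions maps theta to 1-theta."""
        cfg = SamplerConfig(seed=9)
        s = fit_comparison(model(80, 20, q1=0.9, q2=0.6, x2=30, y2=60), cfg)
        t = fit_comparison(model(20, 80, q1=0.6, q2=0.9, x2=60, y2=30), cfg)
        assert s.theta1_mean == pytest.approx(1 - t.theta1_mean, abs=0.02)
        assert s.delta_mean == pytest.approx(-t.delta_mean, abs=0.03)
        assert s.ev_h1 == pytest.approx(t.ev_h1, abs=0.05)
        assert s.ev_h3 == pytest.approx(t.ev_h3, abs=0.05)

    def test_condition_symmetry_negates_delta(self):
        cfg = SamplerConfig(seed=10)
        s = fit_comparison(model(80, 20, x2=40, y2=60), cfg)
        t = fit_comparison(model(40, 60, x2=80, y2=20), cfg)
        assert s.delta_mean == pytest.approx(-t.delta_mean, abs=0.02)
        assert s.ev_h3 == pytest.approx(t.ev_h3, abs=0.05)


class TestFitTable:
    def _counts(self):
        rows = []
        for cross, cond in (("c1", "m"), ("c2", "m")):
            rows += [
                ("g1", cross, cond, "1", 60, 40, 5, 0),
                ("g1", cross, cond, "2", 55, 45, 5, 0),
                ("g2", cross, cond, "1", 10, 90, 5, 0),
            ]
        return pd.DataFrame(
            rows,
            columns=[
                "FEATURE_ID", "CROSS", "CONDITION", "REP",
                "COUNT_G1", "COUNT_G2", "COUNT_AMBIG", "FLAG_LOW_COVERAGE",
            ],
        )

    def _design(self, cross2="c2"):
        return pd.DataFrame(
            [("cmp1", "c1", "m", cross2, "m")],
            columns=[
                "COMPARISON_ID", "COND1_CROSS", "COND1_CONDITION",
                "COND2_CROSS", "COND2_CONDITION",
            ],
        )

    def test_output_contract(self, fast_config):
        out = fit_table(self._counts(), self._design(), config=fast_config)
        assert list(out.columns)[:2] == ["FEATURE_ID", "COMPARISON"]
        assert set(out.FEATURE_ID) == {"g1", "g2"}
        assert out.EV_H3.between(0, 1).all()
        assert (out.CONVERGED == 1).all()

    def test_replicates_summed_before_fitting(self, fast_config):
        out = fit_table(self._counts(), self._design(), config=fast_config)
        # g1 condition 1 pools 115:85; the posterior mean must sit near 0.575
        g1 = out[out.FEATURE_ID == "g1"].iloc[0]
        assert g1.THETA1_MEAN == pytest.approx(115 / 200, abs=0.03)

    def test_orphan_identifiers_fatal(self, fast_config):
        with pytest.raises(ValueError, match="cross=c9"):
            fit_table(self._counts(), self._design(cross2="c9"), config=fast_config)
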