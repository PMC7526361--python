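"""Trial simulator: covariate distributions, Weibull inversion, censoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import truncnorm

import umaic
from umaic.errors import ConfigurationError
from umaic.simulate import (
    apply_censoring,
    linear_predictor,
    simulate_arm,
    simulate_covariates,
    simulate_event_time,
)
from umaic.specs import default_arm_a, default_arm_b, with_overrides


class TestCovariates:
    def test_distributions_match_targets(self, scenario1):
        spec = with_overrides(scenario1.arm_a, n=20000)
        cov = simulate_covariates(spec, np.random.default_rng(3))
        a = (21 - 53) / 11
        b = (80 - 53) / 11
        mu, var = truncnorm.stats(a, b, loc=53, scale=11, moments="mv")
        assert cov["age"].mean() == pytest.approx(float(mu), abs=4 * np.sqrt(var / 20000))
        assert cov["age"].std() == pytest.approx(float(np.sqrt(var)), rel=0.03)
        assert cov["age"].min() >= 21 and cov["age"].max() <= 80
        for col, p in [("postmenopausal", 0.40), ("grade2", 0.65), ("grade3", 0.15)]:
            se = np.sqrt(p * (1 - p) / 20000)
            assert cov[col].mean() == pytest.approx(p, abs=4 * se)
        # exactly one grade per subject (grade 1 = neither indicator)
        assert ((cov["grade2"] + cov["grade3"]) <= 1).all()

    def test_empty_arm(self, scenario1):
        spec = with_overrides(scenario1.arm_a, n=0)
        assert len(simulate_covariates(spec, np.random.default_rng(0))) == 0

    def test_degenerate_bernoulli(self, scenario1):
        spec = with_overrides(scenario1.arm_a, n=50, p_postmenopausal=1.0)
        cov = simulate_covariates(spec, np.random.default_rng(0))
        assert (cov["postmenopausal"] == 1).all()

    @pytest.mark.parametrize(
        "overrides, field",
        [
            ({"n": -1}, "n"),
            ({"age_sd": 0.0}, "age_sd"),
            ({"age_range": (80.0, 21.0)}, "age_range"),
            ({"p_postmenopausal": 1.4}, "p_postmenopausal"),
            ({"p_grade1": 0.5}, "grade"),
            ({"weibull_scale": -1e-8}, "weibull_scale"),
        ],
    )
    def test_invalid_spec_names_field(self, overrides, field):
        with pytest.raises(ConfigurationError, match=field):
            default_arm_a(**overrides)


class TestLinearPredictor:
    def test_single_term(self, scenario1):
        prof = pd.DataFrame(
            {"age": [50.0], "postmenopausal": [0], "grade2": [0], "grade3": [0]}
        )
        xb = linear_predictor(prof, scenario1.arm_a, treated=False)
        assert xb[0] == pytest.approx(1.0)

    def test_scenario2_treated_sum(self, scenario2):
        prof = pd.DataFrame(
            {"age": [50.0], "postmenopausal": [1], "grade2": [0], "grade3": [1]}
        )
        xb = linear_predictor(prof, scenario2.arm_b, treated=True)
        # 0.02*50 + 0.5 + 0.6 - 0.4 - 0.2
        assert xb[0] == pytest.approx(1.5)

    def test_zero_covariates(self, scenario1):
        prof = pd.DataFrame(
            {"age": [0.0], "postmenopausal": [0], "grade2": [0], "grade3": [0]}
        )
        assert linear_predictor(prof, scenario1.arm_a, treated=False)[0] == 0.0

    def test_treated_requires_coefficient(self, scenario1):
        prof = pd.DataFrame(
            {"age": [50.0], "postmenopausal": [0], "grade2": [0], "grade3": [0]}
        )
        with pytest.raises(ConfigurationError):
            linear_predictor(prof, scenario1.arm_a, treated=True)


class TestEventTimes:
    def test_boundary_u_one(self, scenario1):
        assert simulate_event_time(0.0, scenario1.arm_a, 1.0) == 0.0

    def test_u_zero_invalid(self, scenario1):
        with pytest.raises(ValueError):
            simulate_event_time(0.0, scenario1.arm_a, 0.0)

    def test_analytic_inversion_against_root_finding(self, scenario1):
        spec = scenario1.arm_a  # lambda = 4e-8, gamma = 2.2
        t = simulate_event_time(0.0, spec, np.exp(-1.0))
        assert t == pytest.approx((2.5e7) ** (1 / 2.2), rel=1e-12)
        # independent oracle: numerically solve S(T) = e^{-1}
        surv = lambda x: np.exp(-spec.weibull_scale * x**spec.weibull_shape)
        t_root = brentq(lambda x: surv(x) - np.exp(-1.0), 1.0, 1e5)
        assert t == pytest.approx(t_root, rel=1e-9)

    def test_empirical_survival_matches_closed_form(self, scenario1):
        spec = scenario1.arm_b
        xb = 1.0
        rng = np.random.default_rng(5)
        u = 1.0 - rng.random(100_000)
        t = simulate_event_time(xb, spec, u)
        for t0 in (500.0, 1000.0, 2000.0):
            s_true = np.exp(-spec.weibull_scale * t0**spec.weibull_shape * np.exp(xb))
            s_emp = np.mean(t > t0)
            mc_se = np.sqrt(s_true * (1 - s_true) / 100_000)
            assert s_emp == pytest.approx(s_true, abs=4 * mc_se)

    @given(
        xb1=st.floats(-2, 2),
        delta=st.floats(0.1, 2),
        u=st.floats(1e-6, 1.0, exclude_max=True),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_monotone_decreasing_in_xb_and_u(self, xb1, delta, u):
        spec = default_arm_a()
        t1 = simulate_event_time(xb1, spec, u)
        t2 = simulate_event_time(xb1 + delta, spec, u)
        assert t2 < t1
        assert simulate_event_time(xb1, spec, min(u + 1e-3, 1.0)) <= t1


class TestCensoring:
    def test_event_iff_latent_time_reached(self, scenario1):
        spec = scenario1.arm_a
        latent = np.full(500, 100.0)
        time, event = apply_censoring(latent, spec, np.random.default_rng(0))
        assert np.array_equal(event == 1, time == 100.0)
        assert (time <= 100.0).all()
        # a latent time beyond the horizon can never be an event
        time, event = apply_censoring(np.full(200, 3000.0), spec, np.random.default_rng(1))
        assert (event == 0).all() and (time < 2500.0).all()

    def test_marginal_censoring_matches_numerical_integration(self, scenario1):
        spec = scenario1.arm_a
        xb = 1.0  # age 50, no other covariates
        lam, gam, tau = spec.weibull_scale, spec.weibull_shape, spec.max_followup

        def density(t):
            h = lam * gam * t ** (gam - 1) * np.exp(xb)
            return h * np.exp(-lam * t**gam * np.exp(xb))

        # P(event) = P(T <= C) with C ~ U(0, tau)
        p_event, _ = integrate.quad(lambda t: density(t) * (1 - t / tau), 0, tau)
        rng = np.random.default_rng(9)
        n = 40_000
        latent = simulate_event_time(xb, spec, 1.0 - rng.random(n))
        _, event = apply_censoring(latent, spec, rng)
        mc_se = np.sqrt(p_event * (1 - p_event) / n)
        assert event.mean() == pytest.approx(p_event, abs=4 * mc_se)


class TestSimulateArm:
    def test_determinism(self, scenario1):
        a1 = simulate_arm(scenario1.arm_b, True, np.random.default_rng(123))
        a2 = simulate_arm(scenario1.arm_b, True, np.random.default_rng(123))
        pd.testing.assert_frame_equal(a1, a2)

    def test_record_invariants(self, b_arm_default, scenario1):
        df = b_arm_default
        assert len(df) == scenario1.arm_b.n
        assert (df["time"] <= np.minimum(df["latent_time"], 2500.0) + 1e-9).all()
        on_event = df["event"] == 1
        assert np.allclose(df.loc[on_event, "time"], df.loc[on_event, "latent_time"])
        assert (df["time"] >= 0).all()

    def test_no_censoring_mode(self, scenario1):
        spec = with_overrides(scenario1.arm_a, n=100)
        df = simulate_arm(spec, False, np.random.default_rng(2), censor=False)
        assert (df["event"] == 1).all()
        assert np.allclose(df["time"], df["latent_time"])
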