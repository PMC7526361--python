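"""Entropy balancing, ESS, and the pooled weighted Cox estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import CoxPHFitter

import umaic
from umaic.errors import InfeasibleTargetError
from umaic.maic import (
    BALANCE_ALL,
    OMIT_EM,
    OMIT_EM_GRADES,
    UNWEIGHTED,
    balance_target,
    entropy_balance,
    ess,
    pooled_weighted_cox,
    run_strategies,
)
from umaic.publication import publish, summarize_covariates
from umaic.specs import with_overrides


@pytest.fixture(scope="module")
def b_publication(b_arm_default):
    return publish(b_arm_default)


class TestEntropyBalance:
    def test_identity_tilt_gives_uniform_weights(self, arm_a_small):
        own = summarize_covariates(arm_a_small)
        # targets equal the arm's own raw moments (population variance, since
        # the age constraint balances the raw second moment)
        own = type(own)(
            mean_age=own.mean_age,
            var_age=float(arm_a_small["age"].var(ddof=0)),
            p_postmenopausal=own.p_postmenopausal,
            p_grade2=own.p_grade2,
            p_grade3=own.p_grade3,
            n_total=own.n_total,
        )
        ws = entropy_balance(arm_a_small, balance_target(own, BALANCE_ALL))
        assert np.allclose(ws.weights, ws.weights[0], rtol=1e-6)
        assert ws.ess == pytest.approx(len(arm_a_small), rel=1e-9)

    @pytest.mark.parametrize("strategy", [BALANCE_ALL, OMIT_EM, OMIT_EM_GRADES])
    def test_achieved_moments_hit_targets(self, arm_a_small, b_publication, strategy):
        target = balance_target(b_publication.aggregates, strategy)
        ws = entropy_balance(arm_a_small, target)
        for name, tv in ws.targets.items():
            assert ws.achieved[name] == pytest.approx(tv, rel=1e-8, abs=1e-10)
        assert ws.ess <= len(arm_a_small) + 1e-9
        # weights rescaled so the two arms carry equal weighted n
        assert ws.weights.sum() == pytest.approx(b_publication.aggregates.n_total)
        assert (ws.weights > 0).all()

    def test_ess_shrinks_as_more_moments_are_balanced(
        self, arm_a_small, b_publication
    ):
        esses = {
            s: entropy_balance(arm_a_small, balance_target(b_publication.aggregates, s)).ess
            for s in (BALANCE_ALL, OMIT_EM, OMIT_EM_GRADES)
        }
        assert esses[BALANCE_ALL] <= esses[OMIT_EM] + 1e-9
        assert esses[OMIT_EM] <= esses[OMIT_EM_GRADES] + 1e-9

    def test_infeasible_proportion_errors(self, arm_a_small, b_publication):
        agg = b_publication.aggregates
        bad = type(agg)(
            mean_age=agg.mean_age,
            var_age=agg.var_age,
            p_postmenopausal=1.0,
            p_grade2=agg.p_grade2,
            p_grade3=agg.p_grade3,
            n_total=agg.n_total,
        )
        with pytest.raises(InfeasibleTargetError, match="postmenopausal"):
            entropy_balance(arm_a_small, balance_target(bad, BALANCE_ALL))

    def test_infeasible_age_errors(self, arm_a_small, b_publication):
        agg = b_publication.aggregates
        bad = type(agg)(
            mean_age=150.0,
            var_age=agg.var_age,
            p_postmenopausal=agg.p_postmenopausal,
            p_grade2=agg.p_grade2,
            p_grade3=agg.p_grade3,
            n_total=agg.n_total,
        )
        with pytest.raises(InfeasibleTargetError, match="age"):
            entropy_balance(arm_a_small, balance_target(bad, BALANCE_ALL))


class TestESS:
    def test_uniform_and_point_mass(self):
        assert ess(np.ones(17)) == pytest.approx(17.0)
        w = np.zeros(10)
        w[3] = 1.0
        assert ess(w) == pytest.approx(1.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            ess(np.zeros(5))
        with pytest.raises(ValueError):
            ess(np.array([1.0, -0.5]))

    @given(st.integers(2, 40), st.floats(0.1, 100))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_scale_invariance_and_bound(self, n, c):
        rng = np.random.default_rng(n)
        w = rng.random(n) + 1e-6
        assert ess(c * w) == pytest.approx(ess(w), rel=1e-9)
        assert ess(w) <= n + 1e-9


class TestPooledWeightedCox:
    def test_pooled_weight_scale_invariance(self, arm_a_small, b_arm_default):
        # scaling every subject's weight by the same constant changes nothing
        recon = umaic.ReconstructedIPD(
            data=b_arm_default[["time", "event"]].reset_index(drop=True)
        )
        e1 = pooled_weighted_cox(arm_a_small, recon, None)
        c = 3.7
        e2 = pooled_weighted_cox(
            arm_a_small,
            recon,
            np.full(len(arm_a_small), c),
            arm_b_weights=np.full(len(b_arm_default), c),
        )
        assert e2.log_hr == pytest.approx(e1.log_hr, abs=1e-8)
        assert e2.se == pytest.approx(e1.se, rel=1e-6)

    def test_null_effect_recovered(self, scenario1):
        # two arms simulated from the same distribution, no treatment effect
        spec = with_overrides(scenario1.arm_a, n=1500)
        a = umaic.simulate_arm(spec, False, np.random.default_rng(31), "A")
        b = umaic.simulate_arm(spec, False, np.random.default_rng(32), "B")
        est = pooled_weighted_cox(a, b[["time", "event"]], None)
        assert est.converged
        assert est.log_hr == pytest.approx(0.0, abs=3 * est.se)

    def test_robust_se_close_to_model_se_with_unit_weights(self, scenario1):
        spec = with_overrides(scenario1.arm_a, n=2000)
        a = umaic.simulate_arm(spec, False, np.random.default_rng(41), "A")
        b = umaic.simulate_arm(spec, False, np.random.default_rng(42), "B")
        est = pooled_weighted_cox(a, b[["time", "event"]], None)
        df = pd.concat(
            [
                a[["time", "event"]].assign(treated_b=0.0),
                b[["time", "event"]].assign(treated_b=1.0),
            ]
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        assert est.se == pytest.approx(float(cph.standard_errors_["treated_b"]), rel=0.10)

    def test_zero_events_flagged(self, arm_a_small):
        dead_arm = pd.DataFrame({"time": [10.0, 20.0], "event": [0, 0]})
        est = pooled_weighted_cox(arm_a_small, dead_arm, None)
        assert not est.converged


class TestRunStrategies:
    def test_scenario1_strategy_set(self, arm_a_small, b_publication, b_arm_default):
        recon = umaic.reconstruct(b_publication)
        ests = run_strategies(arm_a_small, b_publication, recon, scenario_id=1)
        assert [e.strategy for e in ests] == [UNWEIGHTED, BALANCE_ALL, OMIT_EM_GRADES]
        ests = run_strategies(
            arm_a_small, b_publication, recon, 1, include_omit_em_scenario1=True
        )
        assert [e.strategy for e in ests] == [
            UNWEIGHTED,
            BALANCE_ALL,
            OMIT_EM_GRADES,
            OMIT_EM,
        ]

    def test_scenario2_strategy_set(self, arm_a_small, b_publication):
        recon = umaic.reconstruct(b_publication)
        ests = run_strategies(arm_a_small, b_publication, recon, scenario_id=2)
        assert [e.strategy for e in ests] == [
            UNWEIGHTED,
            BALANCE_ALL,
            OMIT_EM,
            OMIT_EM_GRADES,
        ]

    def test_unweighted_ignores_balance_targets(
        self, arm_a_small, b_publication
    ):
        recon = umaic.reconstruct(b_publication)
        ests = run_strategies(arm_a_small, b_publication, recon, 1)
        direct = pooled_weighted_cox(arm_a_small, recon, None)
        unw = next(e for e in ests if e.strategy == UNWEIGHTED)
        assert unw.log_hr == pytest.approx(direct.log_hr, abs=1e-12)
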