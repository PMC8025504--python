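"""Two-state HMM: emissions, forward likelihood, fitting and decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import beta as beta_dist, lognorm

import restsites as rs
from restsites.collar import ObservationSeries
from restsites.hmm import PARAM_NAMES, ffbs_decode
from restsites.synthetic import simulate_hmm_observations

from _oracles import (enumerate_log_marginal, enumerate_smoothed_marginals,
                      stationary_by_linear_solve)

AVG = rs.HmmParams(mu1=0.03, mu2=0.65, phi1=50.0, phi2=5.0,
                   m1=float(np.log(13)), m2=float(np.log(149)),
                   sigma1=0.9, sigma2=1.4, psi1=0.93, psi2=0.88)


def _obs(activity, steps):
    sl = np.asarray(steps, float)
    return ObservationSeries(
        activity=np.asarray(activity, float), step_length=sl,
        step_missing=np.isnan(sl),
        zero_substituted=np.zeros(len(sl), bool),
    )


class TestBuildingBlocks:
    @pytest.mark.parametrize("mean,prec,a,b", [
        (0.5, 2, 1.0, 1.0),
        (0.03, 50, 1.5, 48.5),
        (0.65, 5, 3.25, 1.75),
    ])
    def test_beta_shapes(self, mean, prec, a, b):
        assert rs.beta_shapes(mean, prec) == pytest.approx((a, b))

    def test_beta_shapes_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rs.beta_shapes(1.5, 2)
        with pytest.raises(ValueError):
            rs.beta_shapes(0.5, -1)

    def test_transition_matrix_definition(self):
        g = rs.transition_matrix(0.93, 0.88)
        np.testing.assert_allclose(g, [[0.93, 0.07], [0.12, 0.88]])
        np.testing.assert_allclose(rs.transition_matrix(0.5, 0.5),
                                   [[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValueError):
            rs.transition_matrix(1.0, 0.5)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one_and_stationarity(self, p1, p2):
        g = rs.transition_matrix(p1, p2)
        np.testing.assert_allclose(g.sum(axis=1), [1, 1])
        d = rs.stationary_distribution(g)
        np.testing.assert_allclose(d @ g, d, atol=1e-12)
        np.testing.assert_allclose(d, stationary_by_linear_solve(g), atol=1e-9)

    def test_stationary_at_study_averages(self):
        d = rs.stationary_distribution(rs.transition_matrix(0.93, 0.88))
        assert d[0] == pytest.approx(0.6316, abs=5e-5)
        sym = rs.stationary_distribution(rs.transition_matrix(0.7, 0.7))
        np.testing.assert_allclose(sym, [0.5, 0.5])

    @pytest.mark.parametrize("psi,interval,hours", [
        (0.89, 15, 2.3), (0.96, 15, 6.3), (0.5, 30, 1.0),
    ])
    def test_expected_sojourn(self, psi, interval, hours):
        assert rs.expected_sojourn(psi, interval) == pytest.approx(hours, abs=0.0501)


class TestEmissions:
    def test_uniform_beta_activity_only_gives_zero(self):
        p = rs.HmmParams(mu1=0.5, mu2=0.6, phi1=2.0, phi2=5.0, m1=1, m2=2,
                         sigma1=1, sigma2=1, psi1=0.5, psi2=0.5)
        assert rs.emission_logdensity(0.3, None, p, 1) == pytest.approx(0.0)

    def test_matches_textbook_density_product(self):
        a, b = rs.beta_shapes(AVG.mu1, AVG.phi1)
        expect = (beta_dist.logpdf(0.005, a, b)
                  + lognorm.logpdf(10.0, s=AVG.sigma1, scale=np.exp(AVG.m1)))
        got = rs.emission_logdensity(0.005, 10.0, AVG, 1)
        assert got == pytest.approx(expect, rel=1e-10)

    def test_resting_observation_less_likely_under_moving_state(self):
        rest = rs.emission_logdensity(0.005, 10.0, AVG, 1)
        move = rs.emission_logdensity(0.005, 10.0, AVG, 2)
        assert move < rest

    def test_boundary_activity_rejected(self):
        with pytest.raises(ValueError):
            rs.emission_logdensity(0.0, 10.0, AVG, 1)


class TestForward:
    def test_single_step_closed_form(self):
        obs = _obs([0.02], [np.nan])
        d = rs.stationary_distribution(rs.transition_matrix(AVG.psi1, AVG.psi2))
        f1 = np.exp(rs.emission_logdensity(0.02, None, AVG, 1))
        f2 = np.exp(rs.emission_logdensity(0.02, None, AVG, 2))
        assert rs.forward_log_marginal(obs, AVG) == pytest.approx(
            np.log(d[0] * f1 + d[1] * f2)
        )

    def test_equals_enumeration_over_paths(self):
        obs, _ = simulate_hmm_observations(AVG, 6, missing_prob=0.3, seed=3)
        assert rs.forward_log_marginal(obs, AVG) == pytest.approx(
            enumerate_log_marginal(obs, AVG), abs=1e-8
        )

    def test_outlier_observation_costs_more_than_typical_one(self):
        base, _ = simulate_hmm_observations(AVG, 8, missing_prob=0.0, seed=4)
        ll_base = rs.forward_log_marginal(base, AVG)
        typical = _obs(np.r_[base.activity, 0.02], np.r_[base.step_length[:-1], 13.0, np.nan])
        weird = _obs(np.r_[base.activity, 0.02], np.r_[base.step_length[:-1], 5e5, np.nan])
        drop_typical = rs.forward_log_marginal(typical, AVG) - ll_base
        drop_weird = rs.forward_log_marginal(weird, AVG) - ll_base
        assert drop_weird < drop_typical - 10


class TestFitting:
    def test_recovery_within_three_posterior_sd(self, recovery_run):
        fit = recovery_run["hmm_fit"]
        truth = recovery_run["params"].hmm.to_array()
        mean = fit.draws[PARAM_NAMES].mean().to_numpy()
        sd = fit.draws[PARAM_NAMES].std(ddof=1).to_numpy()
        z = (mean - truth) / sd
        assert np.all(np.abs(z) < 3), dict(zip(PARAM_NAMES, z))

    def test_every_draw_respects_label_ordering(self, recovery_run):
        d = recovery_run["hmm_fit"].draws
        assert (d["mu1"] < d["mu2"]).all()

    def test_emcee_chains_converge_rhat(self):
        obs, _ = simulate_hmm_observations(AVG, 150, missing_prob=0.2, seed=5)
        est = rs.ActivityStepHMM(backend="emcee", chains=2, warmup=1000,
                                 samples=1000, n_draws=400, random_state=3).fit(obs)
        assert est.fit_.rhat is not None
        assert max(est.fit_.rhat.values()) < 1.01
        assert min(est.fit_.ess.values()) > 100

    def test_constant_activity_reports_identifiability_failure(self):
        obs = _obs(np.full(50, 0.4), np.full(50, np.nan))
        with pytest.warns(UserWarning, match="identifiability"):
            est = rs.ActivityStepHMM(random_state=0).fit(obs)
        assert not est.fit_.converged


class TestDecoding:
    def test_ffbs_matches_exact_forward_backward(self):
        obs, _ = simulate_hmm_observations(AVG, 5, missing_prob=0.2, seed=9)
        exact = enumerate_smoothed_marginals(obs, AVG)
        fit = _fixed_fit(AVG)
        seq = ffbs_decode(obs, fit, n_draws=5000, seed=2, integrate_draws=False)
        se = np.sqrt(exact * (1 - exact) / 5000)
        assert np.all(np.abs(seq.p_rest - exact) <= 3 * se + 1e-9)

    def test_pure_resting_series_decodes_confidently(self):
        rng = np.random.default_rng(6)
        a, b = rs.beta_shapes(AVG.mu1, AVG.phi1)
        act = np.clip(rng.beta(a, b, 120), 0.005, 0.995)
        steps = np.r_[rng.lognormal(AVG.m1, AVG.sigma1, 119), np.nan]
        obs = _obs(act, steps)
        seq = ffbs_decode(obs, _fixed_fit(AVG), n_draws=600, seed=1,
                          integrate_draws=False)
        assert np.all(seq.p_rest > 0.95)

    def test_fixed_seed_reproducible(self):
        obs, _ = simulate_hmm_observations(AVG, 60, missing_prob=0.2, seed=7)
        fit = _fixed_fit(AVG)
        a = ffbs_decode(obs, fit, n_draws=300, seed=42)
        b = ffbs_decode(obs, fit, n_draws=300, seed=42)
        np.testing.assert_array_equal(a.p_rest, b.p_rest)

    def test_low_draw_count_warns(self):
        obs, _ = simulate_hmm_observations(AVG, 10, seed=8)
        with pytest.warns(UserWarning, match="n_draws"):
            ffbs_decode(obs, _fixed_fit(AVG), n_draws=50, seed=0)


class TestAssignment:
    @pytest.mark.parametrize("p,star,unc", [
        (0.96, 0, False),
        (0.50, 1, True),
        (0.95, 1, True),     # strict inequality at the threshold
        (0.04, 1, False),
    ])
    def test_threshold_rule(self, p, star, unc):
        seq = rs.assign_states(np.array([p]), 0.95)
        assert seq.s_star[0] == star
        assert bool(seq.uncertain[0]) is unc

    def test_threshold_must_exceed_half(self):
        with pytest.raises(ValueError):
            rs.assign_states(np.array([0.9]), 0.4)


class TestRestEvents:
    def test_single_event_duration(self, make_series):
        dep = make_series(np.arange(5.0), np.arange(5.0))
        seq = rs.assign_states(np.array([0.0, 0.99, 0.99, 0.99, 0.0]))
        evs = rs.extract_rest_events(seq, dep)
        assert len(evs) == 1
        assert evs[0].duration_h == pytest.approx(0.75)
        assert evs[0].n_fixes == 3

    def test_all_moving_gives_no_events(self, make_series):
        dep = make_series(np.arange(4.0), np.arange(4.0))
        evs = rs.extract_rest_events(rs.assign_states(np.zeros(4)), dep)
        assert evs == []

    def test_maximal_runs_split_correctly(self, make_series):
        dep = make_series(np.arange(4.0), np.arange(4.0))
        seq = rs.assign_states(np.array([0.99, 0.99, 0.0, 0.99]))
        evs = rs.extract_rest_events(seq, dep)
        assert [(e.start_index, e.end_index) for e in evs] == [(0, 1), (3, 3)]


def _fixed_fit(params):
    import pandas as pd
    draws = pd.DataFrame([params.to_array()], columns=PARAM_NAMES)
    return rs.HmmFit(draws=draws, params=params, map_params=params,
                     converged=True)
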