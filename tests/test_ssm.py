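"""Switching state-space model: matrices, likelihood, smoothing, summaries."""

import numpy as np
import pandas as pd
import pytest

import restsites as rs
from restsites.ssm import build_system_matrices

from _oracles import joint_gaussian_loglik

P_AVG = rs.SsmParams(h=20.0, q=165.0, rho=0.437)


def _random_instance(rng, T=7, p_miss=0.3):
    s = rng.integers(0, 2, T)
    x = rng.normal(0, 200, (T, 2))
    miss = rng.random(T) < p_miss
    miss[rng.integers(0, T)] = False     # keep at least one fix
    x[miss] = np.nan
    return x, s


class TestSystemMatrices:
    def test_resting_freezes_location_and_zeroes_selection(self):
        sm = build_system_matrices(0, 0.437)
        np.testing.assert_allclose(sm.U @ [3, 7, 1, 2], [3, 7, 3, 7])
        assert not sm.R.any()

    def test_moving_with_zero_rho_is_random_walk(self):
        sm = build_system_matrices(1, 0.0)
        np.testing.assert_allclose((sm.U @ [5, 6, 1, 2])[:2], [5, 6])

    def test_dcrw_velocity_contribution(self):
        sm = build_system_matrices(1, 0.437)
        nxt = sm.U @ [10, 0, 8, 0]
        assert nxt[0] == pytest.approx(10 + 0.437 * (10 - 8))
        assert nxt[2:].tolist() == [10, 0]

    def test_design_matrix_selects_current_location(self):
        sm = build_system_matrices(1, 0.2)
        np.testing.assert_allclose(sm.Z @ [1, 2, 3, 4], [1, 2])


class TestKalmanLikelihood:
    def test_matches_joint_gaussian_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            T = int(rng.integers(4, 9))
            x, s = _random_instance(rng, T)
            p = rs.SsmParams(
                h=float(rng.uniform(5, 50)), q=float(rng.uniform(50, 300)),
                rho=float(rng.uniform(0, 0.9)),
            )
            ll = rs.kalman_loglik(x, s, p, init_sd=1000.0)
            oracle = joint_gaussian_loglik(x, s, p, init_sd=1000.0)
            assert ll == pytest.approx(oracle, abs=1e-6)

    def test_all_resting_equals_iid_gaussian_about_common_point(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 15, (4, 2))
        s = np.zeros(4, int)
        p = rs.SsmParams(h=15.0, q=100.0, rho=0.3)
        ll = rs.kalman_loglik(x, s, p, init_sd=2000.0)
        oracle = joint_gaussian_loglik(x, s, p, init_sd=2000.0)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_h_change_moves_loglik_in_expected_direction(self, small_truth):
        s = np.where(small_truth.states == 1, 0, 1)
        base = rs.kalman_loglik(small_truth.series, s, P_AVG)
        # far-too-small error makes the observed scatter implausible
        tight = rs.kalman_loglik(small_truth.series, s,
                                 rs.SsmParams(h=1.0, q=165.0, rho=0.437))
        assert tight < base

    def test_misaligned_inputs_rejected(self, small_truth):
        with pytest.raises(ValueError):
            rs.kalman_loglik(small_truth.series, np.zeros(10, int), P_AVG)


class TestFitting:
    def test_recovery_within_three_posterior_sd(self, recovery_run):
        fit = recovery_run["ssm_fit"]
        truth = recovery_run["params"].ssm
        for name, tv in (("h", truth.h), ("q", truth.q), ("rho", truth.rho)):
            m = fit.draws[name].mean()
            sd = fit.draws[name].std(ddof=1)
            assert abs(m - tv) < 3 * sd, (name, m, tv, sd)

    def test_observation_error_an_order_below_process_error(self, recovery_run):
        p = recovery_run["ssm_fit"].params
        assert p.h * 5 < p.q

    def test_resting_only_series_reports_unidentifiable(self, make_series):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 20, (30, 2))
        dep = make_series(x[:, 0], x[:, 1])
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = rs.fit_ssm(dep, np.zeros(30, int), random_state=0, n_draws=100)
        assert not fit.converged

    def test_emcee_chains_converge_rhat(self, small_truth):
        s = np.where(small_truth.states == 1, 0, 1)[:120]
        x = np.column_stack([small_truth.series.easting,
                             small_truth.series.northing])[:120]
        fit = rs.fit_ssm(x, s, backend="emcee", chains=2, warmup=400,
                         samples=800, n_draws=300, random_state=4)
        assert max(fit.rhat.values()) < 1.01


class TestSimulationSmoother:
    def test_mean_matches_analytic_smoother(self, small_truth):
        T = 150
        s = np.where(small_truth.states == 1, 0, 1)[:T]
        x = np.column_stack([small_truth.series.easting,
                             small_truth.series.northing])[:T]
        alpha, V = rs.kalman_smoother(x, s, P_AVG)
        draws = rs.simulation_smoother(x, s, P_AVG, n_draws=2000, seed=9)
        se = draws.sd_path() / np.sqrt(draws.n_draws)
        z = (draws.mean_path() - alpha[:, :2]) / np.maximum(se, 1e-9)
        assert np.abs(z).max() < 3.5   # 300 comparisons at 3 se each

    def test_variance_matches_analytic_smoother(self, small_truth):
        T = 150
        s = np.where(small_truth.states == 1, 0, 1)[:T]
        x = np.column_stack([small_truth.series.easting,
                             small_truth.series.northing])[:T]
        _, V = rs.kalman_smoother(x, s, P_AVG)
        draws = rs.simulation_smoother(x, s, P_AVG, n_draws=2000, seed=10)
        sd_emp = draws.sd_path()
        sd_an = np.sqrt(np.stack([V[:, 0, 0], V[:, 1, 1]], axis=1))
        ratio = sd_emp / np.maximum(sd_an, 1e-9)
        assert np.all((ratio > 0.85) & (ratio < 1.15))

    def test_draws_constant_within_rest_events(self, small_truth):
        s = np.where(small_truth.states == 1, 0, 1)
        draws = rs.simulation_smoother(small_truth.series, s, P_AVG,
                                       n_draws=50, seed=1)
        seq = rs.assign_states(np.where(s == 0, 0.99, 0.01))
        for e in rs.extract_rest_events(seq, small_truth.series):
            seg = draws.paths[:, e.start_index:e.end_index + 1, :]
            assert np.abs(seg - seg[:, :1, :]).max() < 1e-6

    def test_rest_event_spread_shrinks_with_fix_count(self, make_series):
        """Conjugate scaling: a 4-fix rest event's location posterior sd is
        about half a 1-fix event's (h / sqrt(k))."""
        h = 20.0
        rng = np.random.default_rng(3)
        # a 4-fix rest event (steps 0-3), one movement step, then a rest
        # event observed through a single fix (step 5)
        e = np.asarray(
            [0, 0, 0, 0, np.nan, 500, np.nan, np.nan, np.nan, np.nan]
        ) + rng.normal(0, h, 10)
        n = np.zeros(10) + rng.normal(0, h, 10)
        n[np.isnan(e)] = np.nan
        dep = make_series(e, n)
        s = np.array([0, 0, 0, 0, 1, 0, 0, 0, 0, 1])
        p = rs.SsmParams(h=h, q=200.0, rho=0.2)
        draws = rs.simulation_smoother(dep, s, p, n_draws=4000, seed=5)
        sd_four = draws.paths[:, 0, 0].std()
        sd_one = draws.paths[:, 5, 0].std()
        assert sd_four == pytest.approx(h / 2, rel=0.12)
        assert sd_one / sd_four == pytest.approx(2.0, rel=0.25)

    def test_fixed_seed_bit_identical(self, small_truth):
        s = np.where(small_truth.states == 1, 0, 1)
        a = rs.simulation_smoother(small_truth.series, s, P_AVG, 30, seed=7)
        b = rs.simulation_smoother(small_truth.series, s, P_AVG, 30, seed=7)
        np.testing.assert_array_equal(a.paths, b.paths)


class TestMovementSummaries:
    def _draws(self, paths):
        return rs.LatentPathDraws(paths=np.asarray(paths, float),
                                  params=P_AVG, seed=0)

    def test_constant_path_moves_zero(self):
        ts = pd.date_range("2020-01-01", periods=5, freq="15min", tz="UTC")
        d = self._draws(np.zeros((3, 5, 2)))
        out = rs.movement_summaries(d, np.ones(5, int), ts)
        assert (out["daily"]["mean_m"] == 0).all()

    def test_straight_line_bout_distance(self):
        ts = pd.date_range("2020-01-01", periods=4, freq="15min", tz="UTC")
        path = np.array([[[0, 0], [100, 0], [200, 0], [300, 0]]], float)
        out = rs.movement_summaries(self._draws(path), np.ones(4, int), ts)
        assert out["bouts"]["mean_m"].iloc[0] == pytest.approx(300.0)
        assert out["daily"]["mean_m"].iloc[0] == pytest.approx(300.0)

    def test_invariant_to_draw_order(self):
        rng = np.random.default_rng(4)
        paths = rng.normal(0, 50, (40, 6, 2))
        ts = pd.date_range("2020-01-01", periods=6, freq="15min", tz="UTC")
        s = np.array([1, 1, 0, 1, 1, 1])
        a = rs.movement_summaries(self._draws(paths), s, ts)
        b = rs.movement_summaries(self._draws(paths[::-1]), s, ts)
        pd.testing.assert_frame_equal(a["daily"], b["daily"])
        pd.testing.assert_frame_equal(a["bouts"], b["bouts"])
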