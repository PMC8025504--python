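"""Generative simulator of collar deployments with known ground truth.

The generator inverts the two-stage model's assumptions: a two-state Markov
chain (initialized at its stationary distribution) drives both the Beta
activity emissions and the path process — frozen while resting, DCRW while
moving — and GPS observations are the true path plus isotropic Gaussian
error, thinned by a fix-failure process.  Defaults are the across-deployment
average parameter estimates for the fisher collar study this package was
built around, so the simulator's study conditions match the real system's
scales (meters, 15-min fixes, ~63% of time resting).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .collar import (ACTIVITY_HI, ACTIVITY_LO, DeploymentSeries)
from .hmm import (HmmFit, HmmParams, StateSequence, beta_shapes,
                  stationary_distribution, transition_matrix)
from .ssm import SsmFit, SsmParams, build_system_matrices

__all__ = ["TruthParams", "SyntheticTruth", "default_truth_params",
           "simulate_deployment", "simulate_hmm_observations",
           "recovery_report", "write_truth_csv"]


@dataclass(frozen=True)
class TruthParams:
    """Full generative parameter set for one simulated deployment."""

    hmm: HmmParams
    ssm: SsmParams
    p_fail: float = 0.25
    failure_persistence: float | None = None   # optional run-structured misses
    rest_fail_multiplier: float = 1.0          # >1: resting fails more often
    T: int = 2000
    fix_interval: int = 15
    start_coord: tuple = (0.0, 0.0)
    start_time: str = "2016-10-01T00:00:00+00:00"
    ref_lat: float = 42.4
    ref_lon: float = -122.3
    zone: str = "America/Los_Angeles"

    def __post_init__(self):
        if not 0 <= self.p_fail < 1:
            raise ValueError("p_fail must lie in [0, 1)")
        if self.T < 4:
            raise ValueError("T must be at least 4")


@dataclass(frozen=True)
class SyntheticTruth:
    """Simulated deployment plus its generating truth."""

    series: DeploymentSeries
    states: np.ndarray          # true behavioral states in {1, 2}
    path: np.ndarray            # (T, 2) true easting/northing
    params: TruthParams
    seed: int | None


def default_truth_params(**overrides) -> TruthParams:
    """Across-deployment average parameters of the fisher study system.

    Activity: resting Beta(mean 0.03, precision 50), moving Beta(0.65, 5).
    Apparent steps: lognormal with median 13 m resting / 149 m moving and
    log-sd 0.9 / 1.4.  Persistence 0.93 resting, 0.88 moving (15-min fixes,
    expected rest bouts ~3.6 h, stationary resting fraction 0.632).  GPS
    error sd 20 m, movement process sd 165 m, DCRW correlation 0.437.
    """
    hmm = HmmParams(
        mu1=0.03, mu2=0.65, phi1=50.0, phi2=5.0,
        m1=float(np.log(13.0)), m2=float(np.log(149.0)),
        sigma1=0.9, sigma2=1.4, psi1=0.93, psi2=0.88,
    )
    ssm = SsmParams(h=20.0, q=165.0, rho=0.437)
    p = TruthParams(hmm=hmm, ssm=ssm)
    return replace(p, **overrides) if overrides else p


def simulate_deployment(params: TruthParams | None = None,
                        seed: int | None = None,
                        deployment_id: str = "sim",
                        animal_id: str = "sim-animal") -> SyntheticTruth:
    """Simulate one deployment: states, true path, noisy/thinned fixes,
    state-dependent activity."""
    if params is None:
        params = default_truth_params()
    rng = np.random.default_rng(seed)
    hp, sp = params.hmm, params.ssm
    T = params.T

    # behavioral states from the Markov chain, initial = stationary
    gamma = transition_matrix(hp.psi1, hp.psi2)
    delta = stationary_distribution(gamma)
    states = np.empty(T, dtype=np.int8)
    states[0] = 1 if rng.random() < delta[0] else 2
    u = rng.random(T)
    for t in range(1, T):
        stay = gamma[states[t - 1] - 1, states[t - 1] - 1]
        states[t] = states[t - 1] if u[t] < stay else 3 - states[t - 1]

    # true path through the 4-dim switching system
    e0, n0 = params.start_coord
    alpha = np.array([e0, n0, e0, n0], float)
    path = np.empty((T, 2))
    for t in range(T):
        path[t] = alpha[:2]
        if t == T - 1:
            break
        s_star = 0 if states[t] == 1 else 1
        U = build_system_matrices(s_star, sp.rho).U
        alpha = U @ alpha
        if s_star == 1:
            alpha[:2] += rng.normal(0.0, sp.q, size=2)

    # activity per true state, clamped to the collar's reporting range
    a1, b1 = beta_shapes(hp.mu1, hp.phi1)
    a2, b2 = beta_shapes(hp.mu2, hp.phi2)
    act = np.where(
        states == 1, rng.beta(a1, b1, size=T), rng.beta(a2, b2, size=T)
    )
    act = np.clip(act, ACTIVITY_LO, ACTIVITY_HI)

    # fix failures: iid Bernoulli by default, optionally run-structured
    # and/or more frequent while resting (denning cover)
    p_fail = np.full(T, params.p_fail)
    if params.rest_fail_multiplier != 1.0:
        p_fail = np.where(
            states == 1,
            np.clip(p_fail * params.rest_fail_multiplier, 0, 0.99),
            p_fail,
        )
    if params.failure_persistence is None:
        fail = rng.random(T) < p_fail
    else:
        c = params.failure_persistence
        fail = np.empty(T, bool)
        fail[0] = rng.random() < p_fail[0]
        v = rng.random(T)
        for t in range(1, T):
            p = c * fail[t - 1] + (1 - c) * p_fail[t]
            fail[t] = v[t] < p
    success = ~fail

    obs = np.full((T, 2), np.nan)
    noise = rng.normal(0.0, sp.h, size=(T, 2))
    obs[success] = path[success] + noise[success]

    ts = pd.date_range(
        start=pd.Timestamp(params.start_time),
        periods=T, freq=f"{params.fix_interval}min",
    )
    series = DeploymentSeries(
        deployment_id=deployment_id, animal_id=animal_id,
        fix_interval=params.fix_interval, timestamps=ts,
        easting=obs[:, 0], northing=obs[:, 1], activity=act,
    )
    return SyntheticTruth(series=series, states=states, path=path,
                          params=params, seed=seed)


def simulate_hmm_observations(params: HmmParams, T: int,
                              missing_prob: float = 0.25,
                              seed: int | None = None):
    """Simulate an observation series directly from the HMM emission model.

    Activity comes from the state's Beta and step lengths from the state's
    lognormal (thinned by ``missing_prob`` to mimic failed fixes).  This is
    the generative model the HMM itself assumes, so its ten parameters are
    recoverable from the output — unlike apparent steps derived from a
    simulated location path, which during rest reflect pure GPS measurement
    error rather than the fitted resting lognormal.  Returns
    (ObservationSeries, true states in {1, 2}).
    """
    from .collar import ObservationSeries

    rng = np.random.default_rng(seed)
    gamma = transition_matrix(params.psi1, params.psi2)
    delta = stationary_distribution(gamma)
    states = np.empty(T, dtype=np.int8)
    states[0] = 1 if rng.random() < delta[0] else 2
    u = rng.random(T)
    for t in range(1, T):
        stay = gamma[states[t - 1] - 1, states[t - 1] - 1]
        states[t] = states[t - 1] if u[t] < stay else 3 - states[t - 1]
    a1, b1 = beta_shapes(params.mu1, params.phi1)
    a2, b2 = beta_shapes(params.mu2, params.phi2)
    act = np.where(states == 1, rng.beta(a1, b1, T), rng.beta(a2, b2, T))
    act = np.clip(act, ACTIVITY_LO, ACTIVITY_HI)
    m = np.where(states == 1, params.m1, params.m2)
    s = np.where(states == 1, params.sigma1, params.sigma2)
    steps = rng.lognormal(m, s)
    miss = rng.random(T) < missing_prob
    miss[-1] = True   # no successor fix attempt after the last step
    steps[miss] = np.nan
    obs = ObservationSeries(
        activity=act, step_length=steps, step_missing=miss,
        zero_substituted=np.zeros(T, bool),
    )
    return obs, states


def recovery_report(truth: SyntheticTruth, hmm_fit: HmmFit | None = None,
                    ssm_fit: SsmFit | None = None,
                    states: StateSequence | None = None,
                    z_flag: float = 3.0) -> dict:
    """Compare pipeline estimates against the generating truth.

    Returns per-parameter z-scores (posterior mean minus truth, over
    posterior sd), the state-assignment confusion matrix against the true
    states, and flags for any |z| above ``z_flag``.
    """
    report: dict = {"z_scores": {}, "flags": []}
    if hmm_fit is not None and hmm_fit.params is not None:
        true_vec = truth.params.hmm.to_array()
        mean = hmm_fit.draws.mean().to_numpy()
        sd = hmm_fit.draws.std(ddof=1).to_numpy()
        for name, tv, mv, sv in zip(hmm_fit.draws.columns, true_vec, mean, sd):
            report["z_scores"][name] = float((mv - tv) / sv)
    if ssm_fit is not None and ssm_fit.params is not None:
        true_vec = [truth.params.ssm.h, truth.params.ssm.q, truth.params.ssm.rho]
        mean = ssm_fit.draws.mean().to_numpy()
        sd = ssm_fit.draws.std(ddof=1).to_numpy()
        for name, tv, mv, sv in zip(ssm_fit.draws.columns, true_vec, mean, sd):
            report["z_scores"][name] = float((mv - tv) / sv)
    report["flags"] = [
        k for k, z in report["z_scores"].items() if abs(z) > z_flag
    ]
    if states is not None:
        true_rest = truth.states == 1
        assigned_rest = np.asarray(states.s_star) == 0
        cm = np.array([
            [int(np.sum(true_rest & assigned_rest)),
             int(np.sum(true_rest & ~assigned_rest))],
            [int(np.sum(~true_rest & assigned_rest)),
             int(np.sum(~true_rest & ~assigned_rest))],
        ])
        report["confusion"] = cm
        report["state_accuracy"] = float((cm[0, 0] + cm[1, 1]) / cm.sum())
    return report


def write_truth_csv(truth: SyntheticTruth, series_path, truth_path) -> None:
    """Write the deployment in the collar CSV dialect plus a truth CSV."""
    truth.series.to_frame().drop(columns="fix_success").to_csv(
        series_path, index=False
    )
    pd.DataFrame(
        {
            "timestamp": truth.series.timestamps,
            "state": truth.states,
            "true_easting": truth.path[:, 0],
            "true_northing": truth.path[:, 1],
        }
    ).to_csv(truth_path, index=False)
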