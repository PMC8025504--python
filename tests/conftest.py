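import numpy as np
import pytest

import restsites as rs


@pytest.fixture(scope="session")
def truth_params():
    return rs.default_truth_params()


@pytest.fixture(scope="session")
def small_truth():
    """A short path-based synthetic deployment with known truth."""
    return rs.simulate_deployment(rs.default_truth_params(T=400), seed=101)


@pytest.fixture(scope="session")
def recovery_run():
    """The T=2000 recovery experiment shared across tests.

    HMM parameters are recovered from an emission-model simulation (the
    generative model the HMM assumes); h/q/rho from a path-based simulation
    with the true states given; state accuracy from decoding the path-based
    deployment.  Heavy, so computed once per session.
    """
    params = rs.default_truth_params(T=2000)
    obs, _ = rs.synthetic.simulate_hmm_observations(params.hmm, 2000, seed=11)
    hmm = rs.ActivityStepHMM(random_state=7, n_draws=1000).fit(obs)

    truth = rs.simulate_deployment(params, seed=12)
    s_true = np.where(truth.states == 1, 0, 1)
    ssm_fit = rs.fit_ssm(truth.series, s_true, random_state=8, n_draws=1000)

    obs_path = rs.apparent_step_lengths(truth.series)
    hmm_path = rs.ActivityStepHMM(random_state=9, n_draws=500).fit(obs_path)
    states = hmm_path.decode(obs_path, n_draws=500, seed=10)
    return {
        "params": params,
        "hmm_fit": hmm.fit_,
        "ssm_fit": ssm_fit,
        "truth": truth,
        "states": states,
    }


@pytest.fixture
def make_series():
    """Build a small DeploymentSeries from plain arrays."""
    import pandas as pd

    def _make(easting, northing, activity=None, interval=15, dep="d1", animal="a1"):
        T = len(easting)
        if activity is None:
            activity = np.full(T, 0.1)
        ts = pd.date_range("2020-01-01", periods=T, freq=f"{interval}min", tz="UTC")
        return rs.DeploymentSeries(
            deployment_id=dep, animal_id=animal, fix_interval=interval,
            timestamps=ts, easting=np.asarray(easting, float),
            northing=np.asarray(northing, float),
            activity=np.asarray(activity, float),
        )

    return _make
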