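"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the package's recursion code paths: likelihoods by
exhaustive path enumeration or explicit joint-Gaussian construction, and
smoothed marginals by direct normalization over all state sequences.
"""

import itertools

import numpy as np
from scipy.stats import multivariate_normal

from restsites.hmm import emission_logdensity, stationary_distribution, transition_matrix
from restsites.ssm import build_system_matrices


def enumerate_log_marginal(obs, params):
    """HMM marginal likelihood by summing over all 2^T state paths."""
    T = len(obs)
    gamma = transition_matrix(params.psi1, params.psi2)
    delta = stationary_distribution(gamma)
    total = -np.inf
    for path in itertools.product((1, 2), repeat=T):
        lp = np.log(delta[path[0] - 1])
        for t in range(1, T):
            lp += np.log(gamma[path[t - 1] - 1, path[t] - 1])
        for t in range(T):
            lp += emission_logdensity(
                obs.activity[t], obs.step_length[t], params, path[t]
            )
        total = np.logaddexp(total, lp)
    return total


def enumerate_smoothed_marginals(obs, params):
    """Exact P(s_t = 1 | y_1..T) by normalizing over all state paths."""
    T = len(obs)
    gamma = transition_matrix(params.psi1, params.psi2)
    delta = stationary_distribution(gamma)
    log_post = {}
    for path in itertools.product((1, 2), repeat=T):
        lp = np.log(delta[path[0] - 1])
        for t in range(1, T):
            lp += np.log(gamma[path[t - 1] - 1, path[t] - 1])
        for t in range(T):
            lp += emission_logdensity(
                obs.activity[t], obs.step_length[t], params, path[t]
            )
        log_post[path] = lp
    lps = np.array(list(log_post.values()))
    w = np.exp(lps - lps.max())
    w /= w.sum()
    p1 = np.zeros(T)
    for weight, path in zip(w, log_post):
        for t in range(T):
            if path[t] == 1:
                p1[t] += weight
    return p1


def joint_gaussian_loglik(x, s_star, params, init_sd):
    """SSM marginal likelihood by building the full joint covariance of all
    latent states, selecting observed rows, and evaluating the density."""
    T = len(s_star)
    obs_idx = np.nonzero(~np.isnan(x[:, 0]))[0]
    e0, n0 = x[obs_idx[0]]
    m = np.zeros(4 * T)
    m[:4] = [e0, n0, e0, n0]
    C = np.zeros((4 * T, 4 * T))
    C[:4, :4] = np.eye(4) * init_sd**2
    for t in range(T - 1):
        U = build_system_matrices(s_star[t], params.rho).U
        for u in range(t + 1):
            B = U @ C[4 * t:4 * t + 4, 4 * u:4 * u + 4]
            C[4 * (t + 1):4 * (t + 2), 4 * u:4 * u + 4] = B
            C[4 * u:4 * u + 4, 4 * (t + 1):4 * (t + 2)] = B.T
        P = U @ C[4 * t:4 * t + 4, 4 * t:4 * t + 4] @ U.T
        if s_star[t] == 1:
            P = P + np.diag([params.q**2, params.q**2, 0, 0])
        C[4 * (t + 1):4 * (t + 2), 4 * (t + 1):4 * (t + 2)] = P
        m[4 * (t + 1):4 * (t + 2)] = U @ m[4 * t:4 * t + 4]
    rows = [r for t in obs_idx for r in (4 * t, 4 * t + 1)]
    S = C[np.ix_(rows, rows)] + params.h**2 * np.eye(len(rows))
    return multivariate_normal.logpdf(x[obs_idx].ravel(), m[rows], S)


def stationary_by_linear_solve(gamma):
    """Stationary distribution by solving delta (I - Gamma + 1) = 1."""
    A = np.vstack([(np.eye(2) - gamma).T, np.ones(2)])
    b = np.array([0.0, 0.0, 1.0])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol
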