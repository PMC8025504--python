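"""Two-state hidden Markov model for resting/moving decoding.

Observations are the pair y_t = (activity a_t, apparent step length l_t):
activity is Beta-distributed with state-specific mean mu_i and precision
phi_i (Ferrari & Cribari-Neto parameterization, shapes a = mu*phi,
b = (1-mu)*phi); step lengths are lognormal with state-specific log-mean m_i
and log-sd sigma_i.  The two emissions are conditionally independent given
the state, and a missing step length simply drops its factor from the joint
emission.  Transitions use a single persistence probability per state,
gamma_ii = psi_i, so dwell times are geometric.  State 1 is resting
(low activity, identified by the ordering constraint mu1 < mu2); state 2 is
moving.

Decoding uses forward-filtering backward-sampling (FFBS): full state paths
are drawn from their joint posterior, one per posterior parameter draw, and
the per-step resting probability is the fraction of paths resting at that
step.  Assignment is deliberately conservative: a step counts as resting
(s* = 0) only when P(resting) exceeds a high threshold (default 0.95).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, expit, logit
from scipy.stats import norm

from .collar import DeploymentSeries, ObservationSeries

__all__ = [
    "HmmParams",
    "HmmPriors",
    "HmmFit",
    "StateSequence",
    "RestEvent",
    "ActivityStepHMM",
    "beta_shapes",
    "emission_logdensity",
    "transition_matrix",
    "stationary_distribution",
    "forward_log_marginal",
    "fit_hmm",
    "ffbs_decode",
    "assign_states",
    "extract_rest_events",
    "expected_sojourn",
]

PARAM_NAMES = ["mu1", "mu2", "phi1", "phi2", "m1", "m2",
               "sigma1", "sigma2", "psi1", "psi2"]


@dataclass(frozen=True)
class HmmParams:
    """Emission and transition parameters of the two-state model.

    State 1 is resting, state 2 moving; the label is pinned by requiring
    mu1 < mu2 (resting has the lower mean activity).
    """

    mu1: float
    mu2: float
    phi1: float
    phi2: float
    m1: float
    m2: float
    sigma1: float
    sigma2: float
    psi1: float
    psi2: float

    def __post_init__(self):
        if not (0 < self.mu1 < 1 and 0 < self.mu2 < 1):
            raise ValueError("Beta means must lie in (0, 1)")
        if self.mu1 >= self.mu2:
            raise ValueError("label constraint violated: need mu1 < mu2")
        if self.phi1 <= 0 or self.phi2 <= 0:
            raise ValueError("Beta precisions must be positive")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("lognormal log-sd must be positive")
        if not (0 < self.psi1 < 1 and 0 < self.psi2 < 1):
            raise ValueError("persistence probabilities must lie in (0, 1)")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES])

    @classmethod
    def from_array(cls, x) -> "HmmParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))


@dataclass(frozen=True)
class HmmPriors:
    """Semi-informative priors, each on its transformed scale.

    (location, scale) of a normal for logit(mu_i), log(phi_i) and m_i; a
    folded normal |N(loc, scale)| for sigma_i on its natural scale; psi_i is
    uniform on (0, 1).
    """

    logit_mu1: tuple = (-3.0, 0.5)
    logit_mu2: tuple = (0.0, 1.0)
    log_phi1: tuple = (1.0, 1.0)
    log_phi2: tuple = (0.0, 1.0)
    m1: tuple = (3.0, 1.0)
    m2: tuple = (5.0, 1.0)
    sigma1: tuple = (3.0, 1.0)
    sigma2: tuple = (3.0, 1.0)


@dataclass
class HmmFit:
    """Posterior (or Laplace-approximate) summary of an HMM fit."""

    draws: pd.DataFrame                    # n_draws x 10, natural scale
    params: HmmParams                      # posterior-mean point estimate
    map_params: HmmParams
    converged: bool
    message: str = ""
    rhat: dict | None = None
    ess: dict | None = None
    backend: str = "laplace"
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Per-parameter posterior mean, sd, 5/95% quantiles, diagnostics."""
        d = self.draws
        out = pd.DataFrame(
            {
                "mean": d.mean(),
                "sd": d.std(ddof=1),
                "q5": d.quantile(0.05),
                "q95": d.quantile(0.95),
            }
        )
        if self.rhat:
            out["rhat"] = pd.Series(self.rhat)
        if self.ess:
            out["ess"] = pd.Series(self.ess)
        return out


@dataclass(frozen=True)
class StateSequence:
    """Decoded per-step resting probabilities and thresholded assignments.

    s_star uses the collar convention: 0 = resting, 1 = moving.  A step is
    resting only when p_rest strictly exceeds the threshold; steps where
    neither state clears the threshold are flagged uncertain (and treated as
    moving, the conservative choice for rest-site mapping).
    """

    p_rest: np.ndarray
    s_star: np.ndarray
    threshold: float
    uncertain: np.ndarray

    def __len__(self) -> int:
        return len(self.p_rest)


@dataclass(frozen=True)
class RestEvent:
    """A maximal run of consecutive steps assigned to the resting state."""

    deployment_id: str
    animal_id: str
    event_id: int
    start_index: int
    end_index: int           # inclusive
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    duration_h: float
    n_fixes: int

    @property
    def n_steps(self) -> int:
        return self.end_index - self.start_index + 1


# ---------------------------------------------------------------------------
# elementary pieces

def beta_shapes(mean: float, precision: float) -> tuple[float, float]:
    """Mean/precision -> standard (a, b) Beta shapes: a = mu*phi, b = (1-mu)*phi."""
    if not 0 < mean < 1:
        raise ValueError("mean must lie in (0, 1)")
    if precision <= 0:
        raise ValueError("precision must be positive")
    return mean * precision, (1.0 - mean) * precision


def transition_matrix(psi1: float, psi2: float) -> np.ndarray:
    """2x2 transition matrix [[psi1, 1-psi1], [1-psi2, psi2]]."""
    for p in (psi1, psi2):
        if not 0 < p < 1:
            raise ValueError("persistence probabilities must lie strictly in (0, 1)")
    return np.array([[psi1, 1.0 - psi1], [1.0 - psi2, psi2]])


def stationary_distribution(gamma: np.ndarray) -> np.ndarray:
    """Stationary distribution delta with delta @ gamma = delta.

    Closed form for the two-state chain: delta1 = (1-psi2)/((1-psi1)+(1-psi2)).
    """
    gamma = np.asarray(gamma, float)
    a, b = 1.0 - gamma[0, 0], 1.0 - gamma[1, 1]
    if a + b <= 0:
        raise ValueError("reducible chain: both persistence probabilities are 1")
    return np.array([b / (a + b), a / (a + b)])


def expected_sojourn(psi: float, fix_interval: float) -> float:
    """Expected dwell time in hours for geometric sojourns: interval/(1-psi)."""
    if not 0 < psi < 1:
        raise ValueError("psi must lie in (0, 1)")
    return fix_interval / (1.0 - psi) / 60.0


def _state_fields(params: HmmParams, state: int):
    if state == 1:
        return params.mu1, params.phi1, params.m1, params.sigma1
    if state == 2:
        return params.mu2, params.phi2, params.m2, params.sigma2
    raise ValueError("state must be 1 or 2")


def emission_logdensity(
    activity: float, step_length: float | None, params: HmmParams, state: int
) -> float:
    """log f_i(y_t): Beta log-density of activity plus, when the step length
    is present, the lognormal log-density of the step."""
    if not 0 < activity < 1:
        raise ValueError("activity must lie strictly in (0, 1)")
    mu, phi, m, sigma = _state_fields(params, state)
    a, b = beta_shapes(mu, phi)
    out = (
        (a - 1.0) * np.log(activity)
        + (b - 1.0) * np.log1p(-activity)
        - betaln(a, b)
    )
    if step_length is not None and not np.isnan(step_length):
        if step_length <= 0:
            raise ValueError("step length must be positive")
        z = (np.log(step_length) - m) / sigma
        out += -np.log(step_length) - np.log(sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * z * z
    return float(out)


def _emission_logmatrix(obs: ObservationSeries, theta: np.ndarray) -> np.ndarray:
    """T x 2 matrix of log emission densities for a flat parameter vector.

    theta is natural-scale [mu1, mu2, phi1, phi2, m1, m2, s1, s2, psi1, psi2].
    Uses precomputable logs so repeated likelihood evaluations are cheap.
    """
    a = obs.activity
    log_a, log_1ma = np.log(a), np.log1p(-a)
    present = ~obs.step_missing
    log_l = np.log(obs.step_length[present])
    out = np.empty((len(a), 2))
    for j in range(2):
        mu, phi, m, sigma = theta[j], theta[2 + j], theta[4 + j], theta[6 + j]
        sa, sb = mu * phi, (1.0 - mu) * phi
        out[:, j] = (sa - 1.0) * log_a + (sb - 1.0) * log_1ma - betaln(sa, sb)
        z = (log_l - m) / sigma
        out[present, j] += (
            -log_l - np.log(sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * z * z
        )
    return out


def _forward_from_logB(logB: np.ndarray, psi1: float, psi2: float) -> float:
    """Scaled forward recursion for the marginal log-likelihood
    log(delta P(y1) Gamma P(y2) ... Gamma P(yT) 1')."""
    a, b = 1.0 - psi1, 1.0 - psi2
    d1 = b / (a + b)
    T = logB.shape[0]
    ll = 0.0
    mt = max(logB[0, 0], logB[0, 1])
    p1 = d1 * np.exp(logB[0, 0] - mt)
    p2 = (1.0 - d1) * np.exp(logB[0, 1] - mt)
    c = p1 + p2
    ll += np.log(c) + mt
    p1, p2 = p1 / c, p2 / c
    for t in range(1, T):
        mt = max(logB[t, 0], logB[t, 1])
        e1 = np.exp(logB[t, 0] - mt)
        e2 = np.exp(logB[t, 1] - mt)
        q1 = (p1 * psi1 + p2 * (1.0 - psi2)) * e1
        q2 = (p1 * (1.0 - psi1) + p2 * psi2) * e2
        c = q1 + q2
        if not np.isfinite(c) or c <= 0:
            raise FloatingPointError(
                f"non-finite forward variable at step {t} (impossible observation?)"
            )
        ll += np.log(c) + mt
        p1, p2 = q1 / c, q2 / c
    return ll


def forward_log_marginal(obs: ObservationSeries, params: HmmParams) -> float:
    """Marginal log-likelihood of the observation series under the HMM,
    initialized at the stationary distribution."""
    if len(obs) == 0:
        raise ValueError("empty observation series")
    logB = _emission_logmatrix(obs, params.to_array())
    bad = ~np.isfinite(logB).all(axis=1)
    if bad.any():
        raise FloatingPointError(
            f"non-finite emission density at step {int(np.nonzero(bad)[0][0])}"
        )
    return float(_forward_from_logB(logB, params.psi1, params.psi2))


# ---------------------------------------------------------------------------
# transformed-scale posterior

def _to_natural(z: np.ndarray) -> np.ndarray:
    """Unconstrained vector -> natural-scale parameter vector."""
    z = np.asarray(z, float)
    out = np.empty_like(z)
    out[..., 0:2] = expit(z[..., 0:2])          # mu
    out[..., 2:4] = np.exp(z[..., 2:4])         # phi
    out[..., 4:6] = z[..., 4:6]                 # m
    out[..., 6:8] = np.exp(z[..., 6:8])         # sigma
    out[..., 8:10] = expit(z[..., 8:10])        # psi
    return out


def _to_unconstrained(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, float)
    out = np.empty_like(theta)
    out[0:2] = logit(theta[0:2])
    out[2:4] = np.log(theta[2:4])
    out[4:6] = theta[4:6]
    out[6:8] = np.log(theta[6:8])
    out[8:10] = logit(theta[8:10])
    return out


def _log_prior_unconstrained(z: np.ndarray, priors: HmmPriors) -> float:
    """Log prior density over the unconstrained vector, Jacobians included."""
    lp = 0.0
    for i, (loc, scale) in enumerate(
        [priors.logit_mu1, priors.logit_mu2, priors.log_phi1, priors.log_phi2,
         priors.m1, priors.m2]
    ):
        lp += norm.logpdf(z[i], loc, scale)
    # sigma ~ |N(loc, scale)| on the natural scale; optimize over log sigma
    for i, (loc, scale) in ((6, priors.sigma1), (7, priors.sigma2)):
        s = np.exp(z[i])
        lp += np.logaddexp(
            norm.logpdf(s, loc, scale), norm.logpdf(-s, loc, scale)
        ) + z[i]  # + log|ds/dlogs|
    # psi ~ Uniform(0,1); logit transform Jacobian = psi(1-psi)
    for i in (8, 9):
        p = expit(z[i])
        lp += np.log(p) + np.log1p(-p)
    return float(lp)


def _neg_log_posterior(z, obs, priors) -> float:
    theta = _to_natural(z)
    try:
        logB = _emission_logmatrix(obs, theta)
        if not np.isfinite(logB).all():
            return 1e12
        ll = _forward_from_logB(logB, theta[8], theta[9])
    except FloatingPointError:
        return 1e12
    lp = _log_prior_unconstrained(z, priors)
    val = -(ll + lp)
    return val if np.isfinite(val) else 1e12


def _order_states(theta: np.ndarray) -> np.ndarray:
    """Swap the full state blocks wherever mu1 > mu2 (label switching)."""
    theta = np.array(theta, float, copy=True)
    flip = theta[..., 0] > theta[..., 1]
    if np.any(flip):
        for j in range(0, 10, 2):
            a = theta[..., j][flip].copy()
            theta[..., j][flip] = theta[..., j + 1][flip]
            theta[..., j + 1][flip] = a
    return theta


def _numerical_hessian(f, x0, eps=1e-4):
    n = len(x0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * eps * eps)
    return H


# ---------------------------------------------------------------------------
# estimator

class ActivityStepHMM:
    """Two-state activity/step-length HMM, scikit-learn style.

    Parameters
    ----------
    priors : HmmPriors, optional
        Semi-informative priors (defaults as documented on HmmPriors).
    backend : {"laplace", "emcee"}
        "laplace": MAP via L-BFGS plus a Gaussian (Laplace) approximation of
        the posterior on the unconstrained scale; fast and deterministic.
        "emcee": affine-invariant ensemble MCMC with walker groups treated
        as chains for split-R-hat / ESS diagnostics.
    n_draws : int
        Posterior draws retained (Laplace samples, or thinned MCMC draws).
    chains, warmup, samples : int
        MCMC schedule (ignored by the Laplace backend).
    threshold : float
        Resting-assignment probability threshold (strict inequality).
    random_state : int or None
        Seed for all stochastic steps of the fit.

    Attributes (after fit)
    ----------------------
    params_ : HmmParams            posterior-mean point estimate
    fit_ : HmmFit                  draws, diagnostics, metadata
    n_features_in_ : int
    """

    def __init__(self, priors=None, backend="laplace", n_draws=1000,
                 chains=4, warmup=1000, samples=1000, threshold=0.95,
                 integrate_draws=True, random_state=None):
        self.priors = priors
        self.backend = backend
        self.n_draws = n_draws
        self.chains = chains
        self.warmup = warmup
        self.samples = samples
        self.threshold = threshold
        self.integrate_draws = integrate_draws
        self.random_state = random_state

    # sklearn plumbing ---------------------------------------------------
    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in ("priors", "backend", "n_draws", "chains", "warmup",
                      "samples", "threshold", "integrate_draws", "random_state")
        }

    def set_params(self, **kw):
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_obs(X) -> ObservationSeries:
        if isinstance(X, ObservationSeries):
            return X
        df = pd.DataFrame(X)
        sl = df["step_length"].to_numpy(float) if "step_length" in df else np.full(len(df), np.nan)
        return ObservationSeries(
            activity=df["activity"].to_numpy(float),
            step_length=sl,
            step_missing=np.isnan(sl),
            zero_substituted=np.zeros(len(df), bool),
        )

    # fitting ------------------------------------------------------------
    def fit(self, X, y=None):
        obs = self._as_obs(X)
        priors = self.priors or HmmPriors()
        rng = np.random.default_rng(self.random_state)
        if np.ptp(obs.activity) < 1e-12:
            self.fit_ = HmmFit(
                draws=pd.DataFrame(columns=PARAM_NAMES), params=None,
                map_params=None, converged=False, backend=self.backend,
                message="identifiability failure: constant activity series "
                        "carries no information to separate states",
            )
            warnings.warn(self.fit_.message)
            return self
        z_map, H = self._map(obs, priors, rng)
        if self.backend == "laplace":
            fit = self._laplace_fit(obs, priors, z_map, H, rng)
        elif self.backend == "emcee":
            fit = self._emcee_fit(obs, priors, z_map, H, rng)
        else:
            raise ValueError(f"unknown backend {self.backend!r}")
        self.fit_ = fit
        self.params_ = fit.params
        self.n_features_in_ = 2
        return self

    def _map(self, obs, priors, rng):
        z0 = _to_unconstrained(np.array(
            [0.05, 0.6, 20.0, 4.0, 2.5, 5.0, 1.0, 1.3, 0.9, 0.85]
        ))
        best = None
        for attempt in range(3):
            res = minimize(
                _neg_log_posterior, z0, args=(obs, priors), method="L-BFGS-B",
                options={"maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success and res.fun < 1e11:
                break
            z0 = z0 + rng.normal(0, 0.3, size=10)
        z_map = _order_states_unconstrained(best.x)
        H = _numerical_hessian(lambda z: _neg_log_posterior(z, obs, priors), z_map)
        return z_map, H

    def _laplace_fit(self, obs, priors, z_map, H, rng) -> HmmFit:
        converged, msg = True, ""
        try:
            L = np.linalg.cholesky(H)
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            converged = False
            msg = ("posterior Hessian not positive definite; parameters may be "
                   "weakly identified")
            w, V = np.linalg.eigh((H + H.T) / 2)
            w = np.clip(w, 1e-6, None)
            cov = V @ np.diag(1.0 / w) @ V.T
        cov = (cov + cov.T) / 2
        zs = rng.multivariate_normal(z_map, cov, size=self.n_draws)
        draws = _order_states(_to_natural(zs))
        df = pd.DataFrame(draws, columns=PARAM_NAMES)
        params = HmmParams.from_array(_order_states(df.mean().to_numpy()))
        return HmmFit(
            draws=df, params=params,
            map_params=HmmParams.from_array(_order_states(_to_natural(z_map))),
            converged=converged, message=msg, backend="laplace",
            meta={"n_draws": self.n_draws, "seed": self.random_state},
        )

    def _emcee_fit(self, obs, priors, z_map, H, rng) -> HmmFit:
        import emcee
        import arviz as az

        ndim = 10
        nwalkers = 32
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        try:
            cov = np.linalg.inv((H + H.T) / 2)
        except np.linalg.LinAlgError:
            cov = np.eye(ndim) * 0.01
        cov = cov + 1e-8 * np.eye(ndim)

        def log_prob(z):
            return -_neg_log_posterior(z, obs, priors)

        # independent ensembles play the role of chains: walkers within one
        # ensemble are mutually dependent, so each ensemble is flattened into
        # a single chain for split-Rhat
        chains = []
        for _ in range(max(2, self.chains)):
            p0 = rng.multivariate_normal(z_map, cov, size=nwalkers)
            sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, moves=moves)
            sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
            state = sampler.run_mcmc(p0, self.warmup, progress=False)
            sampler.reset()
            sampler.run_mcmc(state, self.samples, progress=False)
            raw = sampler.get_chain()                    # (steps, walkers, ndim)
            chains.append(_order_states(_to_natural(raw)).reshape(-1, ndim))
        nat = np.stack(chains)                           # (chain, draw, ndim)
        data = {name: nat[:, :, i] for i, name in enumerate(PARAM_NAMES)}
        idata = az.convert_to_dataset(data)
        rhat = {k: float(az.rhat(idata)[k]) for k in PARAM_NAMES}
        ess = {k: float(az.ess(idata)[k]) for k in PARAM_NAMES}
        converged = all(r < 1.01 for r in rhat.values())
        msg = "" if converged else (
            "non-convergence: split-Rhat >= 1.01 for "
            + ", ".join(k for k, r in rhat.items() if r >= 1.01)
        )
        if not converged:
            warnings.warn(msg)
        flat = nat.reshape(-1, ndim)
        idx = rng.choice(len(flat), size=min(self.n_draws, len(flat)), replace=False)
        df = pd.DataFrame(flat[idx], columns=PARAM_NAMES)
        params = HmmParams.from_array(_order_states(df.mean().to_numpy()))
        return HmmFit(
            draws=df, params=params,
            map_params=HmmParams.from_array(_order_states(_to_natural(z_map))),
            converged=converged, message=msg, rhat=rhat, ess=ess,
            backend="emcee",
            meta={"walkers": nwalkers, "chains": max(2, self.chains),
                  "warmup": self.warmup, "samples": self.samples,
                  "seed": self.random_state},
        )

    # decoding -----------------------------------------------------------
    def predict_proba(self, X, n_draws=None, seed=None):
        """Per-step posterior resting probability via FFBS on X."""
        self._check_fitted()
        seq = ffbs_decode(
            self._as_obs(X), self.fit_,
            n_draws=n_draws or self.n_draws,
            seed=self.random_state if seed is None else seed,
            threshold=self.threshold,
            integrate_draws=self.integrate_draws,
        )
        return seq.p_rest

    def predict(self, X, n_draws=None, seed=None):
        """Thresholded state assignment s* (0 = resting, 1 = moving)."""
        p = self.predict_proba(X, n_draws=n_draws, seed=seed)
        return assign_states(p, self.threshold).s_star

    def decode(self, X, n_draws=None, seed=None) -> StateSequence:
        p = self.predict_proba(X, n_draws=n_draws, seed=seed)
        return assign_states(p, self.threshold)

    def _check_fitted(self):
        if not hasattr(self, "fit_") or self.fit_.params is None:
            raise RuntimeError("estimator is not fitted (or the fit failed)")


def _order_states_unconstrained(z):
    theta = _order_states(_to_natural(z))
    return _to_unconstrained(theta)


def fit_hmm(obs: ObservationSeries, priors: HmmPriors | None = None,
            **config) -> HmmFit:
    """Functional wrapper over ActivityStepHMM.fit."""
    est = ActivityStepHMM(priors=priors, **config).fit(obs)
    return est.fit_


# ---------------------------------------------------------------------------
# FFBS decoding

def _ffbs_paths(obs: ObservationSeries, thetas: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Sample one state path per parameter row; returns (n, T) of {1, 2}.

    Vectorized across draws: a scaled forward filter per draw, then joint
    backward sampling using the filtered probabilities.
    """
    n = thetas.shape[0]
    T = len(obs)
    logB = np.stack([_emission_logmatrix(obs, thetas[i]) for i in range(n)])
    psi1, psi2 = thetas[:, 8], thetas[:, 9]
    a, b = 1.0 - psi1, 1.0 - psi2
    d1 = b / (a + b)
    filt = np.empty((n, T, 2))
    mt = logB[:, 0, :].max(axis=1, keepdims=True)
    w = np.stack([d1, 1 - d1], axis=1) * np.exp(logB[:, 0, :] - mt)
    filt[:, 0, :] = w / w.sum(axis=1, keepdims=True)
    for t in range(1, T):
        prev = filt[:, t - 1, :]
        pred1 = prev[:, 0] * psi1 + prev[:, 1] * (1 - psi2)
        pred2 = prev[:, 0] * (1 - psi1) + prev[:, 1] * psi2
        mt = logB[:, t, :].max(axis=1)
        w1 = pred1 * np.exp(logB[:, t, 0] - mt)
        w2 = pred2 * np.exp(logB[:, t, 1] - mt)
        c = w1 + w2
        filt[:, t, 0] = w1 / c
        filt[:, t, 1] = w2 / c
    states = np.empty((n, T), dtype=np.int8)
    u = rng.random((n, T))
    states[:, T - 1] = np.where(u[:, T - 1] < filt[:, T - 1, 0], 1, 2)
    for t in range(T - 2, -1, -1):
        nxt = states[:, t + 1]
        # P(s_t = 1 | s_{t+1}, y_1..t) propto filt[t,1] * gamma[1, nxt]
        g1 = np.where(nxt == 1, psi1, 1 - psi1)
        g2 = np.where(nxt == 1, 1 - psi2, psi2)
        w1 = filt[:, t, 0] * g1
        w2 = filt[:, t, 1] * g2
        states[:, t] = np.where(u[:, t] < w1 / (w1 + w2), 1, 2)
    return states


def ffbs_decode(obs: ObservationSeries, fit: HmmFit, n_draws: int = 1000,
                seed: int | None = None, threshold: float = 0.95,
                integrate_draws: bool = True, return_paths: bool = False):
    """Forward-filtering backward-sampling decode of the resting probability.

    With ``integrate_draws`` the parameter posterior is integrated over: one
    state path is sampled per (resampled) parameter draw.  Otherwise all
    paths are drawn at the posterior-mean parameters.  ``p_rest[t]`` is the
    fraction of sampled paths resting at step t.
    """
    if fit.params is None:
        raise RuntimeError("cannot decode from a failed fit")
    if n_draws < 100:
        warnings.warn("n_draws < 100: Monte Carlo error in p_rest may be large")
    rng = np.random.default_rng(seed)
    if integrate_draws and len(fit.draws):
        pool = fit.draws.to_numpy()
        idx = rng.integers(0, len(pool), size=n_draws)
        thetas = pool[idx]
    else:
        thetas = np.repeat(fit.params.to_array()[None, :], n_draws, axis=0)
    paths = _ffbs_paths(obs, thetas, rng)
    p_rest = (paths == 1).mean(axis=0)
    seq = assign_states(p_rest, threshold)
    if return_paths:
        return seq, paths
    return seq


def assign_states(p_rest: np.ndarray, threshold: float = 0.95) -> StateSequence:
    """Threshold resting probabilities: s* = 0 iff p_rest > threshold.

    Steps where neither state's probability exceeds the threshold are
    flagged uncertain and assigned to moving (conservative).
    """
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must lie in (0.5, 1)")
    p = np.asarray(p_rest, float)
    s_star = np.where(p > threshold, 0, 1).astype(np.int8)
    uncertain = np.maximum(p, 1.0 - p) <= threshold
    return StateSequence(p_rest=p, s_star=s_star, threshold=threshold,
                         uncertain=uncertain)


def extract_rest_events(states: StateSequence,
                        series: DeploymentSeries) -> list[RestEvent]:
    """Maximal runs of s* = 0, with duration (run length x fix interval)
    and the count of successful GPS fixes inside each run."""
    s = states.s_star
    if len(s) != len(series):
        raise ValueError("state sequence and series are misaligned")
    events = []
    t = 0
    k = 0
    while t < len(s):
        if s[t] == 0:
            start = t
            while t + 1 < len(s) and s[t + 1] == 0:
                t += 1
            events.append(
                RestEvent(
                    deployment_id=series.deployment_id,
                    animal_id=series.animal_id,
                    event_id=k,
                    start_index=start,
                    end_index=t,
                    start_time=series.timestamps[start],
                    end_time=series.timestamps[t],
                    duration_h=(t - start + 1) * series.fix_interval / 60.0,
                    n_fixes=int(series.fix_success[start:t + 1].sum()),
                )
            )
            k += 1
        t += 1
    return events
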