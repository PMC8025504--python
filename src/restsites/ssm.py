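"""Switching linear-Gaussian state space model for true-location estimation.

Conditional on the decoded behavioral states, the animal's true planar
location is a latent state alpha_t = [e_t, n_t, e_{t-1}, n_{t-1}]' observed
through GPS with isotropic Gaussian error (sd ``h`` meters) and evolving as

* resting (s*_t = 0):  alpha_{t+1} = [e_t, n_t, e_t, n_t]'  (frozen, no noise)
* moving  (s*_t = 1):  first-difference correlated random walk (DCRW):
  e_{t+1} = e_t + rho (e_t - e_{t-1}) + eta, with process sd ``q`` meters.

Failed fixes contribute no measurement update; the Kalman filter still
propagates the latent state, so every scheduled timestep gets a location
estimate.  The resting transition is exactly degenerate, which makes
predicted covariances singular; the Durbin-Koopman backward recursion used
here never inverts them.  Posterior path draws come from the mean-correction
simulation smoother: simulate an unconditional path plus observations,
smooth both, and correct the smoothed record by the simulation residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .collar import DeploymentSeries

__all__ = [
    "SsmParams",
    "SsmFit",
    "SystemMatrices",
    "LatentPathDraws",
    "SwitchingSSM",
    "build_system_matrices",
    "kalman_loglik",
    "kalman_smoother",
    "fit_ssm",
    "simulation_smoother",
    "movement_summaries",
]

Z_DESIGN = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
SSM_NAMES = ["h", "q", "rho"]
DEFAULT_BOUNDS = {"h": (1e-3, 500.0), "q": (1e-3, 5000.0), "rho": (0.0, 0.999)}
DEFAULT_INIT_SD = 10_000.0   # diffuse prior sd on alpha_1, meters


@dataclass(frozen=True)
class SsmParams:
    """Observation error sd h (m), process sd q (m), DCRW correlation rho."""

    h: float
    q: float
    rho: float

    def __post_init__(self):
        if self.h <= 0 or self.q <= 0:
            raise ValueError("h and q must be positive")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")


@dataclass(frozen=True)
class SystemMatrices:
    """Per-step transition U (4x4), selection R (4x2) and design Z (2x4)."""

    U: np.ndarray
    R: np.ndarray
    Z: np.ndarray


@dataclass
class SsmFit:
    draws: pd.DataFrame
    params: SsmParams | None
    map_params: SsmParams | None
    converged: bool
    message: str = ""
    rhat: dict | None = None
    ess: dict | None = None
    backend: str = "laplace"
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        d = self.draws
        out = pd.DataFrame({
            "mean": d.mean(), "sd": d.std(ddof=1),
            "q5": d.quantile(0.05), "q95": d.quantile(0.95),
        })
        if self.rhat:
            out["rhat"] = pd.Series(self.rhat)
        if self.ess:
            out["ess"] = pd.Series(self.ess)
        return out


@dataclass(frozen=True)
class LatentPathDraws:
    """n_draws x T x 2 posterior draws of the latent easting/northing path."""

    paths: np.ndarray
    params: SsmParams
    seed: int | None

    @property
    def n_draws(self) -> int:
        return self.paths.shape[0]

    def __len__(self) -> int:
        return self.paths.shape[1]

    def mean_path(self) -> np.ndarray:
        return self.paths.mean(axis=0)

    def sd_path(self) -> np.ndarray:
        return self.paths.std(axis=0, ddof=1)


def build_system_matrices(s_star: int, rho: float) -> SystemMatrices:
    """System matrices for one step given the assigned state.

    Resting (s*=0) freezes the location into both current and lag slots and
    zeroes the selection matrix; moving (s*=1) applies the DCRW update with
    correlation rho.
    """
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    s = int(s_star)
    if s not in (0, 1):
        raise ValueError("s_star must be 0 or 1")
    U = np.array([
        [1 + rho * s, 0, -rho * s, 0],
        [0, 1 + rho * s, 0, -rho * s],
        [1, 0, 0, 0],
        [0, 1, 0, 0],
    ])
    R = np.array([[s, 0], [0, s], [0, 0], [0, 0]], dtype=float)
    return SystemMatrices(U=U, R=R, Z=Z_DESIGN.copy())


# ---------------------------------------------------------------------------
# filtering machinery (prediction form, gains shared across draw replicates)

def _coords(series) -> np.ndarray:
    if isinstance(series, DeploymentSeries):
        return np.column_stack([series.easting, series.northing])
    x = np.asarray(series, float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("coordinates must be a (T, 2) array")
    return x


def _init_state(x: np.ndarray, init_sd: float):
    obs = np.nonzero(~np.isnan(x[:, 0]))[0]
    if obs.size == 0:
        raise ValueError("no successful fixes in series; cannot initialize")
    e0, n0 = x[obs[0]]
    a1 = np.array([e0, n0, e0, n0])
    P1 = np.eye(4) * init_sd**2
    return a1, P1


def _gain_pass(x: np.ndarray, s_star: np.ndarray, params: SsmParams,
               init_sd: float):
    """One covariance pass: predicted covariances, innovation precisions and
    Kalman/DK gains, all independent of the realized observations."""
    T = len(s_star)
    rho, h2, q2 = params.rho, params.h**2, params.q**2
    observed = ~np.isnan(x[:, 0])
    Us = np.empty((T, 4, 4))
    for t in range(T):
        Us[t] = build_system_matrices(s_star[t], rho).U
    RQR = np.zeros((T, 4, 4))
    move = s_star.astype(bool)
    RQR[move, 0, 0] = q2
    RQR[move, 1, 1] = q2
    _, P = _init_state(x, init_sd)
    P_pred = np.empty((T, 4, 4))
    F_inv = np.zeros((T, 2, 2))
    K = np.zeros((T, 4, 2))          # prediction-form gain  U P Z' F^-1
    L = np.empty((T, 4, 4))
    logdetF = np.zeros(T)
    Z = Z_DESIGN
    for t in range(T):
        P_pred[t] = P
        U = Us[t]
        if observed[t]:
            F = P[:2, :2] + h2 * np.eye(2)
            Fi = np.linalg.inv(F)
            F_inv[t] = Fi
            sign, ld = np.linalg.slogdet(F)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    f"innovation covariance not positive definite at step {t}"
                )
            logdetF[t] = ld
            K[t] = U @ P[:, :2] @ Fi
            L[t] = U - K[t] @ Z
        else:
            L[t] = U
        P = L[t] @ P @ Us[t].T + RQR[t]
        P = (P + P.T) / 2
    return {
        "observed": observed, "U": Us, "RQR": RQR, "P_pred": P_pred,
        "F_inv": F_inv, "K": K, "L": L, "logdetF": logdetF,
    }


def _filter_mean(xs: np.ndarray, gains: dict, a1: np.ndarray):
    """Innovations and predicted state means for stacked replicates.

    xs : (n, T, 2) observations (NaN at missing steps, same pattern per
    replicate).  Returns a_pred (n, T, 4) and v (n, T, 2, zero at missing).
    """
    n, T, _ = xs.shape
    a_pred = np.empty((n, T, 4))
    v = np.zeros((n, T, 2))
    a = np.broadcast_to(a1, (n, 4)).copy()
    observed = gains["observed"]
    for t in range(T):
        a_pred[:, t, :] = a
        if observed[t]:
            v[:, t, :] = xs[:, t, :] - a[:, :2]
            a = a @ gains["U"][t].T + v[:, t, :] @ gains["K"][t].T
        else:
            a = a @ gains["U"][t].T
    return a_pred, v


def _smooth_mean(a_pred: np.ndarray, v: np.ndarray, gains: dict) -> np.ndarray:
    """Durbin-Koopman backward recursion for smoothed state means (no
    covariance inversion, so degenerate resting steps are handled exactly)."""
    n, T, _ = a_pred.shape
    observed = gains["observed"]
    r = np.zeros((n, 4))
    alpha = np.empty((n, T, 4))
    Z = Z_DESIGN
    for t in range(T - 1, -1, -1):
        if observed[t]:
            r = v[:, t, :] @ gains["F_inv"][t].T @ Z + r @ gains["L"][t]
        else:
            r = r @ gains["L"][t]
        alpha[:, t, :] = a_pred[:, t, :] + r @ gains["P_pred"][t].T
    return alpha


def _smooth_cov(gains: dict) -> np.ndarray:
    """Smoothed state covariances V_t = P_t - P_t N_{t-1} P_t."""
    T = gains["P_pred"].shape[0]
    observed = gains["observed"]
    N = np.zeros((4, 4))
    V = np.empty((T, 4, 4))
    Z = Z_DESIGN
    for t in range(T - 1, -1, -1):
        Lt = gains["L"][t]
        if observed[t]:
            N = Z.T @ gains["F_inv"][t] @ Z + Lt.T @ N @ Lt
        else:
            N = Lt.T @ N @ Lt
        P = gains["P_pred"][t]
        V[t] = P - P @ N @ P
        V[t] = (V[t] + V[t].T) / 2
    return V


def kalman_loglik(series, s_star, params: SsmParams,
                  init_sd: float = DEFAULT_INIT_SD) -> float:
    """Prediction-error-decomposition log-likelihood.

    Steps with failed fixes contribute nothing (prediction only).  The
    latent state is initialized diffusely at the first observed fix with sd
    ``init_sd`` per component.
    """
    x = _coords(series)
    s_star = np.asarray(s_star, int)
    if len(x) != len(s_star):
        raise ValueError("series and state assignment are misaligned")
    gains = _gain_pass(x, s_star, params, init_sd)
    a1, _ = _init_state(x, init_sd)
    _, v = _filter_mean(x[None, :, :], gains, a1)
    observed = gains["observed"]
    ll = 0.0
    for t in np.nonzero(observed)[0]:
        vt = v[0, t]
        ll += -0.5 * (2 * np.log(2 * np.pi) + gains["logdetF"][t]
                      + vt @ gains["F_inv"][t] @ vt)
    return float(ll)


def kalman_smoother(series, s_star, params: SsmParams,
                    init_sd: float = DEFAULT_INIT_SD):
    """Analytic smoothed means (T, 4) and covariances (T, 4, 4)."""
    x = _coords(series)
    s_star = np.asarray(s_star, int)
    gains = _gain_pass(x, s_star, params, init_sd)
    a1, _ = _init_state(x, init_sd)
    a_pred, v = _filter_mean(x[None, :, :], gains, a1)
    alpha = _smooth_mean(a_pred, v, gains)[0]
    V = _smooth_cov(gains)
    return alpha, V


# ---------------------------------------------------------------------------
# fitting

class SwitchingSSM:
    """Switching DCRW state-space model, scikit-learn style.

    fit(X, s_star) estimates (h, q, rho) by maximizing the Kalman-filter
    likelihood under uniform priors within finite bounds ("laplace" backend:
    bounded MAP plus Gaussian approximation; "emcee": ensemble MCMC).  After
    fitting, ``sample`` draws latent paths with the simulation smoother.
    """

    def __init__(self, bounds=None, backend="laplace", n_draws=1000,
                 chains=4, warmup=1000, samples=1000, allow_negative_rho=False,
                 init_sd=DEFAULT_INIT_SD, random_state=None):
        self.bounds = bounds
        self.backend = backend
        self.n_draws = n_draws
        self.chains = chains
        self.warmup = warmup
        self.samples = samples
        self.allow_negative_rho = allow_negative_rho
        self.init_sd = init_sd
        self.random_state = random_state

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "bounds", "backend", "n_draws", "chains", "warmup", "samples",
            "allow_negative_rho", "init_sd", "random_state")}

    def set_params(self, **kw):
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _bounds(self):
        b = dict(DEFAULT_BOUNDS)
        if self.allow_negative_rho:
            b["rho"] = (-0.999, 0.999)
        if self.bounds:
            b.update(self.bounds)
        return [b[k] for k in SSM_NAMES]

    def fit(self, X, s_star):
        x = _coords(X)
        s = np.asarray(s_star, int)
        rng = np.random.default_rng(self.random_state)
        moving = bool(s[:-1].any())
        bounds = self._bounds()

        def nll(theta):
            try:
                p = SsmParams(*theta)
                return -kalman_loglik(x, s, p, self.init_sd)
            except (ValueError, np.linalg.LinAlgError):
                return 1e12

        theta0 = np.array([30.0, 150.0, 0.3])
        res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
        theta = res.x
        converged, msg = bool(res.success), ""
        if not moving:
            converged = False
            msg = ("q and rho are unidentifiable: no moving steps in the "
                   "assignment; only h is estimated")
            warnings.warn(msg)
        if self.backend == "laplace":
            fit = self._laplace(nll, theta, bounds, rng, converged, msg)
        elif self.backend == "emcee":
            fit = self._emcee(nll, theta, bounds, rng, converged, msg)
        else:
            raise ValueError(f"unknown backend {self.backend!r}")
        for lo, hi, name, val in ((*bounds[2], "rho", theta[2]),):
            if converged and (val <= lo + 1e-4 or val >= hi - 1e-4):
                fit.message += f" {name} estimate at prior boundary ({val:.4g})."
        self.fit_ = fit
        self.params_ = fit.params
        self.h_, self.q_, self.rho_ = fit.params.h, fit.params.q, fit.params.rho
        self._X, self._s = x, s
        return self

    def _laplace(self, nll, theta, bounds, rng, converged, msg):
        eps = np.maximum(1e-4 * np.abs(theta), 1e-5)
        n = len(theta)
        H = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = eps[i]
                ej = np.zeros(n); ej[j] = eps[j]
                H[i, j] = H[j, i] = (
                    nll(theta + ei + ej) - nll(theta + ei - ej)
                    - nll(theta - ei + ej) + nll(theta - ei - ej)
                ) / (4 * eps[i] * eps[j])
        try:
            cov = np.linalg.inv((H + H.T) / 2)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh((H + H.T) / 2)
            cov = V @ np.diag(1.0 / np.clip(w, 1e-8, None)) @ V.T
            if converged:
                converged, msg = False, "non-positive-definite Hessian at optimum"
        cov = (cov + cov.T) / 2
        zs = rng.multivariate_normal(theta, cov, size=self.n_draws)
        lo = np.array([b[0] for b in bounds]) + 1e-9
        hi = np.array([b[1] for b in bounds]) - 1e-9
        zs = np.clip(zs, lo, hi)
        df = pd.DataFrame(zs, columns=SSM_NAMES)
        return SsmFit(
            draws=df, params=SsmParams(*df.mean()), map_params=SsmParams(*theta),
            converged=converged, message=msg, backend="laplace",
            meta={"n_draws": self.n_draws, "seed": self.random_state},
        )

    def _emcee(self, nll, theta, bounds, rng, converged, msg):
        import emcee
        import arviz as az

        ndim = 3
        nwalkers = 2 * ndim + 6
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        def log_prob(z):
            if np.any(z <= lo) or np.any(z >= hi):
                return -np.inf
            return -nll(z)

        scale = np.maximum(0.05 * np.abs(theta), 1e-3)
        chains = []
        for _ in range(max(2, self.chains)):
            p0 = np.clip(theta + rng.normal(0, 1, (nwalkers, ndim)) * scale,
                         lo + 1e-6, hi - 1e-6)
            sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, moves=moves)
            sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
            state = sampler.run_mcmc(p0, self.warmup, progress=False)
            sampler.reset()
            sampler.run_mcmc(state, self.samples, progress=False)
            chains.append(sampler.get_chain().reshape(-1, ndim))
        chain = np.stack(chains)
        data = {name: chain[:, :, i] for i, name in enumerate(SSM_NAMES)}
        ds = az.convert_to_dataset(data)
        rhat = {k: float(az.rhat(ds)[k]) for k in SSM_NAMES}
        ess = {k: float(az.ess(ds)[k]) for k in SSM_NAMES}
        if not all(r < 1.01 for r in rhat.values()):
            converged = False
            msg += " split-Rhat >= 1.01."
            warnings.warn(msg)
        flat = chain.reshape(-1, ndim)
        idx = rng.choice(len(flat), size=min(self.n_draws, len(flat)),
                         replace=False)
        df = pd.DataFrame(flat[idx], columns=SSM_NAMES)
        return SsmFit(
            draws=df, params=SsmParams(*df.mean()), map_params=SsmParams(*theta),
            converged=converged, message=msg, rhat=rhat, ess=ess,
            backend="emcee",
            meta={"walkers": nwalkers, "warmup": self.warmup,
                  "samples": self.samples, "seed": self.random_state},
        )

    def sample(self, n_draws=2000, seed=None, X=None, s_star=None) -> LatentPathDraws:
        """Draw latent paths from the smoothing distribution."""
        self._check_fitted()
        x = self._X if X is None else _coords(X)
        s = self._s if s_star is None else np.asarray(s_star, int)
        return simulation_smoother(
            x, s, self.params_, n_draws=n_draws,
            seed=self.random_state if seed is None else seed,
            init_sd=self.init_sd,
        )

    def _check_fitted(self):
        if not hasattr(self, "fit_"):
            raise RuntimeError("estimator is not fitted")


def fit_ssm(series, s_star, bounds=None, **config) -> SsmFit:
    """Functional wrapper over SwitchingSSM.fit."""
    est = SwitchingSSM(bounds=bounds, **config).fit(series, s_star)
    return est.fit_


# ---------------------------------------------------------------------------
# simulation smoother

def simulation_smoother(series, s_star, params: SsmParams, n_draws: int = 2000,
                        seed: int | None = None,
                        init_sd: float = DEFAULT_INIT_SD,
                        chunk: int = 500) -> LatentPathDraws:
    """Mean-correction draws from the joint smoothing distribution.

    For each draw an unconditional state/observation record (alpha+, x+) is
    simulated from the model (same missingness pattern), both records are
    smoothed, and the draw is alpha_hat + (alpha+ - alpha_hat+).  Because
    every pass uses the exact degenerate resting transition, each draw's
    location is constant within every rest event.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    x = _coords(series)
    s = np.asarray(s_star, int)
    T = len(s)
    rng = np.random.default_rng(seed)
    gains = _gain_pass(x, s, params, init_sd)
    a1, P1 = _init_state(x, init_sd)
    a_pred, v = _filter_mean(x[None, :, :], gains, a1)
    alpha_hat = _smooth_mean(a_pred, v, gains)[0]     # (T, 4)
    observed = gains["observed"]
    move = s.astype(bool)
    out = np.empty((n_draws, T, 2))
    for start in range(0, n_draws, chunk):
        n = min(chunk, n_draws - start)
        # unconditional simulation
        ap = a1 + rng.standard_normal((n, 4)) * init_sd
        alpha_p = np.empty((n, T, 4))
        for t in range(T):
            alpha_p[:, t, :] = ap
            ap = ap @ gains["U"][t].T
            if move[t]:
                ap[:, :2] += rng.standard_normal((n, 2)) * params.q
        xp = np.full((n, T, 2), np.nan)
        xp[:, observed, :] = (
            alpha_p[:, observed, :2]
            + rng.standard_normal((n, int(observed.sum()), 2)) * params.h
        )
        a_pred_p, v_p = _filter_mean(xp, gains, a1)
        alpha_hat_p = _smooth_mean(a_pred_p, v_p, gains)
        out[start:start + n] = (
            alpha_hat[None, :, :2] + alpha_p[:, :, :2] - alpha_hat_p[:, :, :2]
        )
    return LatentPathDraws(paths=out, params=params, seed=seed)


# ---------------------------------------------------------------------------
# movement summaries

def movement_summaries(draws: LatentPathDraws, s_star, timestamps):
    """Per-day and per-movement-bout cumulative distance summaries.

    The displacement between t and t+1 is attributed to step t (the interval
    it spans).  Resting steps contribute exactly zero.  Returns a dict with
    ``daily`` and ``bouts`` DataFrames carrying the posterior mean and 5th /
    95th percentiles of cumulative distance in meters.
    """
    s = np.asarray(s_star, int)
    ts = pd.DatetimeIndex(timestamps)
    d = np.linalg.norm(np.diff(draws.paths, axis=1), axis=2)  # (n, T-1)
    days = ts[:-1].floor("D")
    daily_rows = []
    for day in days.unique():
        mask = days == day
        totals = d[:, mask].sum(axis=1)
        daily_rows.append({
            "day": day, "n_steps": int(mask.sum()),
            "mean_m": totals.mean(),
            "q5_m": np.percentile(totals, 5),
            "q95_m": np.percentile(totals, 95),
        })
    bout_rows = []
    t = 0
    k = 0
    while t < len(s) - 1:
        if s[t] == 1:
            start = t
            while t + 1 < len(s) - 1 and s[t + 1] == 1:
                t += 1
            totals = d[:, start:t + 1].sum(axis=1)
            bout_rows.append({
                "bout_id": k, "start_index": start, "end_index": t,
                "start_time": ts[start], "n_steps": t - start + 1,
                "mean_m": totals.mean(),
                "q5_m": np.percentile(totals, 5),
                "q95_m": np.percentile(totals, 95),
            })
            k += 1
        t += 1
    return {
        "daily": pd.DataFrame(daily_rows),
        "bouts": pd.DataFrame(bout_rows),
    }
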