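# Methods

## The problem

GPS-collared animals produce location time series that mix two kinds of
hidden information: the behavioral state (a resting animal and a moving one
generate very different tracks) and the true location (every fix carries
measurement error, and many scheduled fixes fail outright — for den-using
forest carnivores, often *because* the animal is resting under cover).
`restsites` implements a two-stage decomposition of this joint problem for
collars that also record an accelerometer-derived **activity** fraction per
fix interval: first decode *when* the animal rested, then, treating those
assignments as known, estimate *where*.

## Stage 1 — behavioral HMM

Observations per step t are `y_t = (a_t, l_t)`: activity `a_t in
[0.005, 0.995]` (complete) and apparent step length `l_t > 0` in meters
(missing whenever either endpoint fix failed).  Conditional on the latent
state `s_t in {1 = resting, 2 = moving}` the two are independent:

* `a_t | s_t = i ~ Beta(mu_i * phi_i, (1 - mu_i) * phi_i)` — the
  mean/precision parameterization;
* `l_t | s_t = i ~ Lognormal(m_i, sigma_i)`; a missing `l_t` simply drops
  this factor.  Exact-zero steps (identical consecutive fixes) are replaced
  upstream by 1 m and flagged, since zero is inadmissible under the
  lognormal.

Transitions use one persistence probability per state, `gamma_ii = psi_i`,
so dwell times are geometric with mean `interval / (1 - psi_i)`.  The
initial distribution is fixed at the stationary distribution
`delta_1 = (1 - psi_2) / ((1 - psi_1) + (1 - psi_2))` — the chain is
time-homogeneous, so estimating it would add a parameter with almost no
information.  The marginal likelihood `delta P(y_1) Gamma P(y_2) ... 1'` is
computed by a scaled forward recursion.

Label switching is resolved by requiring `mu_1 < mu_2` (resting is the
low-activity state); draws violating the ordering have their state blocks
swapped.

**Priors** (semi-informative, on transformed scales):
`logit(mu_1) ~ N(-3, 0.5)`, `logit(mu_2) ~ N(0, 1)`, `log(phi_1) ~ N(1, 1)`,
`log(phi_2) ~ N(0, 1)`, `m_1 ~ N(3, 1)`, `m_2 ~ N(5, 1)`,
`sigma_i ~ |N(3, 1)|`, `psi_i ~ Uniform(0, 1)`.  These keep the two mixture
components from collapsing on weakly informative series.

**Fitting backends.**  The default is MAP on the unconstrained scale
(L-BFGS, with prior Jacobians included so the optimum matches the posterior
mode MCMC would target) plus a Laplace Gaussian approximation whose samples
serve as posterior draws.  The alternative `emcee` backend runs several
independently seeded affine-invariant ensembles with differential-evolution
moves; each ensemble is flattened into one chain for split-R-hat and ESS
(walkers within an ensemble are mutually dependent, so treating walkers as
chains would be invalid).  Convergence is declared at R-hat < 1.01.  Both
backends satisfy the parameter-recovery property; the Laplace backend is
deterministic and roughly two orders of magnitude faster, which is what the
test suite uses at scale.

**Decoding.**  Forward-filtering backward-sampling draws whole state paths
from their joint posterior — one path per (resampled) posterior parameter
draw by default, or all paths at the posterior mean via a flag, since it is
not obvious which convention a given study used; both are supported.
`p_rest[t]` is the fraction of paths resting at t.  Assignment is
deliberately conservative: `s*_t = 0` (resting) only when `p_rest > 0.95`
(strict), everything else is treated as moving; steps where neither state
exceeds the threshold are additionally flagged *uncertain* so downstream
consumers can report them.  Rest events are maximal runs of `s* = 0`.

## Stage 2 — switching linear-Gaussian SSM

Conditional on `s*`, the latent state is
`alpha_t = [e_t, n_t, e_{t-1}, n_{t-1}]'` with

* observation: `x_t = Z alpha_t + eps_t`, `eps_t ~ N(0, h^2 I_2)`,
  `Z = [[1,0,0,0],[0,1,0,0]]`; failed fixes skip the measurement update
  (equivalently, infinite observation variance);
* system: `alpha_{t+1} = U_t alpha_t + R_t eta_t`, `eta_t ~ N(0, q^2 I_2)`,
  where `s*_t = 0` freezes the location exactly
  (`alpha_{t+1} = [e_t, n_t, e_t, n_t]'`, `R_t = 0`) and `s*_t = 1` applies
  the first-difference correlated random walk
  `e_{t+1} = e_t + rho (e_t - e_{t-1}) + eta`.

`h` is the GPS error sd (m), `q` the per-step movement sd (m), `rho` the
velocity correlation.  Defaults restrict `rho` to [0, 1) (persistent
directed movement); negative correlation can be enabled by a flag.

**Initialization.**  `alpha_1` is diffuse-Gaussian centered on the first
observed fix with sd 10 km per component (configurable).  The animals are
territory-confined, so 10 km is far beyond any plausible displacement while
still numerically safe.

**Estimation.**  Uniform priors inside finite bounds — `h in (0, 500)` m,
`q in (0, 5000)` m, `rho in [0, 1)` — make bounded maximum likelihood the
MAP; the default backend adds a Laplace approximation (draws clipped to the
bounds), and an `emcee` backend is available as above.  A resting-only
assignment leaves `q` and `rho` without information; this is detected and
reported as non-convergence rather than silently returning the prior.

**Numerics.**  The resting transition is exactly degenerate, so predicted
covariances are singular by design.  Filtering uses the prediction form
(`a_{t+1} = U a_t + K v_t`, `K = U P Z' F^{-1}`) and smoothing the
Durbin–Koopman backward recursion (`r`/`N`), which never inverts a state
covariance — only the 2x2 innovation covariance `F`, which is positive
definite whenever `h > 0`.  Covariances are symmetrized each step.

**Simulation smoother** (mean-correction): simulate an unconditional
state/observation record from the model with the same missingness pattern,
smooth both the real and simulated records, and return
`alpha_hat + (alpha+ - alpha_hat+)`.  All gain matrices depend only on
`s*`, the parameters and the missingness pattern, so one covariance pass is
shared by all draws and the per-draw work is vectorized; draws are processed
in chunks of 500 to bound memory.  Because every pass uses the exact frozen
transition, each draw's location is constant within every rest event — the
resting constraint holds exactly, not approximately.

## Rest-site summaries

Within a rest event the smoothing distribution of the (single) location is
exactly Gaussian, so the credible region is computed parametrically: pool
one location per draw, take sample mean and covariance, scale the
eigen-axes by `sqrt(chi2_2(level))`, and report area `pi a b` in hectares.
A kernel-density contour backend was considered and rejected as the
default: under a linear-Gaussian model the Gaussian ellipse is the
model-consistent summary, has a closed-form area, and is directly testable
(coverage of the 95% ellipse over Gaussian draws is 95% +/- 1 point at
n = 10,000).  Boundary polygons use 64 vertices (< 0.3% area error).

Distinct rest locations are connected components of the pairwise-overlap
graph of 95% ellipses (transitive chaining; an STRtree prunes candidate
pairs).  Events with zero successful fixes still get ellipses but are
excluded from clustering — their ellipses are too large to make overlap
meaningful.  Reuse flags per cluster: a same-animal revisit requires >= 24 h
between the *end* of one event and the *start* of the next (the rule's
anchor timestamps are not standardized; end-to-start is the conservative
reading and is documented here), and multi-animal use requires events from
more than one animal id.

## Diel categories

Eight half-open intervals partition the nadir-anchored solar day: night
after nadir, morning astronomical twilight, morning (civil dawn to the
morning golden-hour end), day before noon, day after noon, evening
(golden-hour start to civil dusk), evening twilight, night before the next
nadir.  Event instants come from the NOAA solar-position series (equation
of time + declination + hour-angle inversion, iterated once for
self-consistency), accurate to well under the +/- 3 min contract at
mid-latitudes; latitudes beyond +/- 60 degrees are rejected rather than
special-cased.  "Golden hour" is operationalized as the sun-elevation
+6 degree crossing — a common convention, stated here because no exact
numeric definition is standard.  One reference coordinate per deployment is
used for all steps: across a single territory the solar-time difference is
seconds, while per-step coordinates would be missing exactly where fixes
failed.

## Synthetic data

`simulate_deployment` inverts the model: a two-state Markov chain (initial
= stationary) drives state-dependent Beta activity and the path process
(frozen / DCRW through the same `U_t`, `R_t` matrices the SSM uses), GPS
observations add isotropic `N(0, h^2)` noise, and fixes fail with
probability 0.25 by default (iid; optionally run-structured via a
persistence parameter, and optionally state-dependent to mimic denning
cover).  Defaults are the study-average parameters:
`mu = (0.03, 0.65)`, `phi = (50, 5)`, median steps `(13, 149)` m,
`sigma = (0.9, 1.4)`, `psi = (0.93, 0.88)`, `h = 20` m, `q = 165` m,
`rho = 0.437`, 15-min fixes.  At these defaults the long-run resting
fraction is 0.632 and the activity histogram is bimodal with a large spike
at the 0.005 floor.

One structural point matters for recovery testing.  Apparent step lengths
derived from a simulated *path* are, during true rest, pure measurement
error — Rayleigh with scale `h*sqrt(2)`, mean ~ 35 m for `h = 20` — not
draws from the resting lognormal (median 13 m).  The two stages assume
different generative models for the same numbers, exactly as they do on
real data.  The package therefore ships two simulators:
`simulate_hmm_observations` draws activity and steps from the HMM's own
emission model and is the basis for the 10-parameter HMM recovery check,
while the path-based `simulate_deployment` underlies SSM recovery (given
true states), state-assignment accuracy, and every end-to-end check.
Consequently, passing recovery tests show each stage recovers the model it
assumes; they do not certify the HMM's lognormal component as a correct
description of error-contaminated steps (on real data it is explicitly an
approximation, and the moving-state fit is known to be imperfect).

What the simulator does *not* emulate: terrain/canopy-driven error
inflation, battery-decay failure trends, correlated or biased GPS error,
turning-angle structure, and any behavior beyond two states.  Tests passing
on this generator say nothing about those failure modes.

## Problem sizes and numerical choices

Recovery experiments use T = 2000 steps (about three weeks of 15-min
fixes — the scale of a short real deployment) with the Laplace backend;
oracle comparisons use 5000 FFBS draws and 2000 smoother draws, with
agreement required within 3 Monte-Carlo standard errors; likelihood oracles
are exact-arithmetic comparisons at 1e-8 (HMM, log scale) and 1e-6 (SSM).
Ensemble-MCMC convergence checks run two independently seeded chains of
1000 warmup + 1000 sampling iterations on shorter series.  Ties and
boundaries: the resting threshold uses strict `>`; `p_rest` exactly at the
threshold is moving and flagged uncertain.  Activity values inside [0, 1]
but outside the collar's [0.005, 0.995] reporting range are clamped with a
warning; values outside [0, 1] and missing activity are rejected.
Deployments are truncated after the last run of >= 3 consecutive successful
fixes (battery-fade tails), and a deployment with no such run, or whose
truncation leaves fewer than 4 steps, is rejected as unusable.

## Known limitations

* The two-stage design conditions stage 2 on hard state assignments;
  uncertainty in `s*` does not propagate into the ellipses (uncertain steps
  are flagged so consumers can at least see where).
* Lognormal step emissions cannot represent the negative skew real moving
  steps show; a three-state or time-inhomogeneous HMM is out of scope.
* Laplace posteriors are Gaussian on the unconstrained scale; for short
  series with boundary-adjacent parameters the MCMC backend is the honest
  option.
* GPS error is isotropic and homoscedastic; no HDOP covariates.
* Solar events assume an unobstructed horizon and standard refraction.
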