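# restsites

Locate the resting sites of GPS + accelerometer-collared animals with a
two-stage model that handles both hidden behavioral states and GPS
measurement error (including failed fixes).  Built for wildlife
biologists working with regular fix-attempt schedules on territorial,
den-using species — the motivating system is forest carnivores whose fixes
fail *because* they rest under cover — but the models are generic
hidden-Markov and state-space biostatistics.

## The model

**Stage 1 (when).**  A two-state HMM on each deployment's activity fraction
`a_t` and apparent step length `l_t` (Euclidean distance between
consecutive successful fixes — movement confounded with GPS error):

    a_t | s_t = i  ~  Beta(mu_i phi_i, (1 - mu_i) phi_i)
    l_t | s_t = i  ~  Lognormal(m_i, sigma_i)        (dropped when missing)
    P(s_t = i | s_{t-1} = i) = psi_i,   delta = delta Gamma

with the marginal likelihood `delta P(y_1) Gamma P(y_2) ... Gamma P(y_T) 1'`.
Forward-filtering backward-sampling yields a per-step resting probability;
a step is assigned resting (`s*_t = 0`) only when that probability exceeds
0.95, and rest events are maximal runs of `s* = 0`.

**Stage 2 (where).**  Taking `s*` as given, a switching linear-Gaussian
state space model with latent `alpha_t = [e_t, n_t, e_{t-1}, n_{t-1}]'`:
exactly stationary while resting, a first-difference correlated random walk
(`e_{t+1} = e_t + rho (e_t - e_{t-1}) + eta_t`) while moving, observed
through isotropic `N(0, h^2)` GPS error with failed fixes skipping the
measurement update.  Kalman filtering gives the likelihood for `(h, q,
rho)`; a mean-correction simulation smoother draws latent paths, from which
each rest event gets 50/80/95% Gaussian credible ellipses.  Overlapping 95%
ellipses are chained into geographically distinct rest locations, with
same-animal (>= 24 h gap) and multi-animal reuse flags, plus diel resting
proportions over eight solar-geometry categories and per-day/per-bout
movement distances.

See `docs/methods.md` for assumptions, priors, numerics and limitations.

## Worked example

Simulate three weeks of 15-minute fixes at the package's default
parameters, then run both stages:

```python
import numpy as np
import restsites as rs

truth = rs.simulate_deployment(rs.default_truth_params(T=2000), seed=42)
dep   = rs.truncate_trailing_failures(truth.series)
obs   = rs.apparent_step_lengths(dep)

hmm    = rs.ActivityStepHMM(random_state=0).fit(obs)
states = hmm.decode(obs, seed=1)
events = rs.extract_rest_events(states, dep)

ssm   = rs.SwitchingSSM(random_state=2).fit(dep, states.s_star)
draws = ssm.sample(n_draws=2000, seed=3)
ells  = [rs.rest_event_ellipse(draws, e, 0.95) for e in events if e.n_fixes >= 1]
clusters = rs.detect_reuse(rs.cluster_rest_locations(ells))
```

Output (printed by the calls above plus a few summaries):

```
          mean     sd      q5     q95
mu1      0.031  0.001   0.030   0.032
mu2      0.658  0.007   0.647   0.669
psi1     0.923  0.008   0.911   0.935
psi2     0.872  0.013   0.850   0.892
...
rest events: 94 | mean duration (h): 3.33
percent resting: 62.9% | percent uncertain: 0.2%
h=19.0 m  q=163.2 m  rho=0.426
median 95% ellipse area: 0.0944 ha
distinct rest locations: 90 | revisited: 1
```

Reading this: the fitted Beta means separate a near-zero-activity resting
state from a high-activity moving state; the persistence probabilities
imply geometric rest bouts of a few hours; 62.9% of steps are resting
(the generating chain's stationary fraction is 63.2%); the SSM recovers
the generating GPS error (20 m), movement scale (165 m) and velocity
correlation (0.437) closely; and a typical rest event is localized to
about a tenth of a hectare at 95% credibility.

A command-line interface wraps the same pipeline:

```
restsites simulate --seed 1 --t 2000 --out dep.csv
restsites run --input dep.csv --out run/ --seed 5
restsites summarize run/
```

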