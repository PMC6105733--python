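# intervalbayes

Bayesian observer models of human interval reproduction under scalar
(signal-dependent) timing noise.

In the 1-2-Go / 1-2-3-Go task, an observer measures a sample interval
`t_s` (drawn from a discrete uniform prior on {600 … 1000} ms) once or
twice and reproduces it. Timing noise is scalar — measurement SD is
`w_m·t_s` and production SD is `w_p·t_e` — which makes the likelihood
skewed in `t_s` and, crucially, means no simple sufficient-statistic
update can propagate the posterior across sequential measurements. This
package implements, simulates, fits, and compares four observer models
of how the estimate `t_e` is formed:

| model | estimate for two measurements |
| --- | --- |
| **BLS** | posterior mean, `f_BLS2(t_m1, t_m2)` — optimal under quadratic loss |
| **BLS_mem** | posterior mean with a distinct Weber fraction `w_mem` on the first measurement |
| **LNE** | one-measurement BLS nonlinearity applied to the running average `0.5·(t_m1 + t_m2)` |
| **EKF** | sequential update `t_e ← t_e + k_n·f*(t_m − t_e)` with `f*(x) = f_BLS1(x + t_e0) − t_e0`, gain `k_n = w²_{n−1}/(w²_{n−1} + w²_m)` |

The response model is a lapse mixture,
`p(t_p|t_e) = (1−γ)·N(t_e + b, (w_p t_e)²) + γ·U(0, 2000 ms)`, and the
trial likelihood `p(t_p|t_s, Θ)` marginalizes the unobserved
measurement(s) by Simpson quadrature. Fitting is cross-validated
predictive maximum likelihood (held-out blocks of trials, fold-averaged
parameters); model comparison uses held-out log-likelihood ratios
against BLS; behaviour is summarized by
`BIAS² = mean_i (t̄_p,i − t_s,i)²`, `VAR = mean_i σ²_i`, and
`RMSE = √(BIAS² + VAR)` over the distinct sample intervals. A complete
task simulator (measurement → estimator → production → lapse, plus the
one-up/one-down correctness staircase and the standard trial-exclusion
rules) generates ground-truth data for every stage, so the whole
pipeline is testable end to end without any external data.

The package is aimed at researchers in time perception and computational
psychophysics who want to fit these observer models to interval-
reproduction data, or to use the simulator and recovery machinery to
vet an experimental design.

See `docs/methods.md` for the full model account, numerical choices, and
limitations.

## Worked example

Parameter recovery on synthetic data — simulate 2000 trials from a BLS
observer and fit it back:

```bash
$ intervalbayes recover --n-trials 2000 --seed 0 --restarts 2
truth:  w_m=0.1000 w_p=0.0800 gamma=0.020
fitted: w_m=0.0909 w_p=0.0813 gamma=0.018 (loglik -11695.1)
```

The fitted Weber fractions land within ~10% of the generating values
(sampling noise at 2000 trials); the log-likelihood is the summed log
predictive density of the data at the optimum.

The built-in oracle checks compare every quadrature-based quantity with
an independent Monte-Carlo route:

```bash
$ intervalbayes validate --n-draws 100000 --seed 2
bls1(700): quadrature 719.560, MC 719.543 +/- 0.214
bls2(650,950): quadrature 829.499, MC 829.690 +/- 0.204
EKF marginal density: max bin discrepancy 3.88 binomial SE
likelihood-product closure residual: scalar 1.017e-04, gaussian control 2.854e-16
BLS2 line-scan range along t_m1+t_m2=1600: 12.246 ms
```

Reading the output: the one- and two-measurement posterior means agree
with importance sampling within its standard error; the largest
histogram-bin discrepancy of the EKF marginal density is at the level
expected for the maximum over ~100 bins; the product of two scalar
likelihoods cannot be fit by any single scalar likelihood (relative
residual 1e-4, versus 3e-16 for the closed Gaussian family) — the
formal reason sequential updating is hard under scalar noise; and the
two-measurement BLS estimate varies by ~12 ms along a line of constant
`t_m1 + t_m2`, the curvature of its iso-estimate contours that the
linear LNE model lacks.

Library use mirrors the CLI:

```python
import numpy as np
from intervalbayes import (ObserverParams, PriorSpec, simulate_session,
                           fit_model_lnocv, FitConfig, FAST_QUAD)

prior = PriorSpec()
truth = ObserverParams("ekf", w_m=0.10, w_p=0.08, b=10.0, gamma=0.02)
trials, _ = simulate_session(4000, truth, prior, np.random.default_rng(7))
fit = fit_model_lnocv(trials, "ekf", prior, FAST_QUAD,
                      FitConfig(test_block_size=2000, optimizer_restarts=2))
print(fit.averaged_params)
```

Other commands: `simulate` (write a session CSV), `fit` / `compare` /
`stats` (fit one model, compare two fits, summarize a dataset), `run`
(the full simulate → exclude → fit-all-four → compare → stats pipeline
into one output directory).

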