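# Methods

## The task and the generative model

The package models behaviour in a two-condition interval reproduction
task. On each trial a sample interval `t_s` is drawn from a discrete
uniform distribution over {600, 700, 800, 900, 1000} ms and demarcated by
flashes: once in the 1-2-Go condition (one measurement) or twice in the
1-2-3-Go condition (two measurements of the same `t_s`). The observer
reproduces the interval by a keypress; the produced interval is `t_p`.

Timing noise is *scalar*: the SD of a noisy measurement grows in
proportion to the timed duration. A measurement is

    t_m ~ Normal(t_s, (w_m t_s)^2)

with `w_m` the measurement Weber fraction. Production adds its own scalar
noise around the internal estimate `t_e`, plus a constant offset:

    t_p ~ Normal(t_e + b, (w_p t_e)^2)

The offset `b` (ms) shifts the mean only. With probability `gamma` the
trial is a lapse and `t_p` is drawn uniformly on [0, 2000] ms regardless
of the stimulus. The response density is therefore the mixture

    p(t_p | t_e) = (1 - gamma) Normal(t_e + b, (w_p t_e)^2)
                 + gamma Uniform(0, 2000).

The scalar likelihood as a function of `t_s` at fixed `t_m`,

    lambda(t_m | t_s) = Normal(t_m; t_s, (w_m t_s)^2),

is skewed toward longer intervals because both the mean and the SD depend
on `t_s`. Two consequences drive the whole modelling problem:

* the product of two scalar likelihoods is not itself a scalar
  likelihood (numerically checked in `validation.scalar_product_fit_residual`),
  so no finite set of sufficient statistics propagates the posterior
  exactly across measurements — unlike the Gaussian case, where a Kalman
  filter is exact; and
* the uninformative limit `w -> inf` is *not* flat in `t_s`: the
  `1/(w t_s)` prefactor survives, leaving a `1/t_s`-tilted posterior. As
  a corollary the one-measurement estimator map is monotone only above
  roughly 350-400 ms for realistic Weber fractions and its
  large-noise limit is `width / log(t_max/t_min)` (about 783 ms for the
  default prior), slightly below the prior mean.

## The four estimators

All four share the continuous uniform prior on [600, 1000] ms used in
the estimator integrals (the discrete support is a property of the task,
the continuous range a property of the observer's prior belief).

**BLS** (Bayes least-squares) is the posterior mean, optimal under
quadratic loss. For one measurement

    f_BLS1(t_m1) = Int t_s lambda(t_m1|t_s) dt_s / Int lambda(t_m1|t_s) dt_s

over [t_min, t_max]; for two measurements the integrand carries the
product of the two likelihoods. Its iso-estimate contours in the
(t_m1, t_m2) plane are convex: the larger measurement dominates.

**BLS_mem** replaces the first measurement's Weber fraction with a free
parameter `w_mem` on two-measurement trials, modelling memory degradation
(or, for `w_mem < w_m`, attentional anticipation). With `w_mem = w_m` it
is exactly BLS. The synthetic generator draws the first 1-2-3-Go
measurement with SD `w_mem t_s` for this model, so that the fitted
likelihood and the generative process agree (model recovery would be
ill-posed otherwise).

**LNE** (linear-nonlinear estimator) tracks the running average of the
measurements with gains `k_n = 1/n` (so `k_1 = 1`, `k_2 = 0.5`) and
applies the one-measurement BLS nonlinearity to the final average. Its
iso-estimate contours are exactly linear, and the bias it produces is
identical across conditions — its signature failure mode.

**EKF** (extended-Kalman-filter-style updater) maintains a point estimate
`t_e` and its reliability expressed as a Weber fraction `w`. Starting
from the prior mean with `w_0 = inf` (handled symbolically: the first
gain is exactly 1), each measurement updates

    t_e <- t_e + k_n fstar(t_m - t_e),      fstar(x) = f_BLS1(x + t_e0) - t_e0,
    k_n = w_{n-1}^2 / (w_{n-1}^2 + w_m^2),
    w_n = w_{n-1} w_m / sqrt(w_{n-1}^2 + w_m^2),

with `t_e0` the prior mean. After one measurement EKF equals BLS exactly;
with two it is suboptimal but reproduces the qualitative convexity of the
BLS contours. The innovation argument `x + t_e0` is not clipped; for
extreme measurement pairs the two-measurement EKF estimate can leave
(t_min, t_max) by up to a quarter of the prior width, which the
likelihood machinery accommodates (estimate grid spans [500, 1100] ms
for the default prior).

## Trial likelihood

The fitted quantity is the predictive density `p(t_p | t_s, Theta)`
obtained by marginalizing the unobserved measurement(s):

    p(t_p|t_s) = Int lambda(t_m1|t_s) p(t_p | f(t_m1)) dt_m1            (one)
    p(t_p|t_s) = Int Int lambda lambda p(t_p | f(t_m1,t_m2)) dt_m1 dt_m2 (two)

with `f` the model's estimator and `p(t_p | t_e)` the lapse mixture. The
integrals use composite Simpson rules: 201 nodes over the prior range for
the estimator integrals, and measurement grids of 101 nodes (51 in the
fast configuration) centred on `t_s` with half-width 5 SD. Measurement
grids are not truncated at zero: the equations place no positivity
constraint on `t_m`, and the mass below zero is negligible at fitted
parameters. Doubling the 5-SD span changes a 100-trial log-likelihood by
less than 1e-3 nats (tested).

Because the response density depends on the measurements only through the
estimate, the engine collapses the (t_m1, t_m2) Simpson tensor onto a
dense estimate grid (0.5 ms spacing, 1 ms in the fast configuration) by
linear binning of the Simpson weights, then multiplies by one Gaussian
response matrix shared across all `t_s` and both conditions for a given
parameter vector. This is algebraically the same weighted sum with a
relative error below ~1e-4 from the binning, and it is what makes a full
log-likelihood evaluation cost ~30-60 ms so that cross-validated fitting
is practical on one CPU. The non-lapse density is tabulated on a 1 ms
`t_p` grid over [0, 2000] ms and interpolated with a cubic spline
(clipped at zero); the lapse floor `gamma/2000` per ms is added
analytically, so the mixture floor holds exactly. The one-measurement BLS
map is itself cached on a 1 ms grid with monotone (PCHIP) interpolation
sized to cover every innovation argument the measurement grids can
produce.

Numerical safeguards: all posterior-mean ratios are computed with
row-max log-domain stabilization (far outside the prior the raw
likelihoods underflow), and the symbolic `w_0 = inf` initial state avoids
inf/inf in the first EKF gain.

## Fitting and model comparison

Parameters Theta = (w_m, w_p, b, gamma) — plus `w_mem` for BLS_mem — are
fit by maximizing the summed log predictive density with Nelder-Mead in
a unit box over the bounds w_m, w_p in [1e-3, 0.5], b in [-300, 300] ms,
gamma in [0, 0.3], w_mem in [1e-3, 1]. Restarts (default 5) start from
field-typical values (w_m = 0.15, w_p = 0.1, b = 0, gamma = 0.02) and
Latin-hypercube draws. Both conditions share one parameter vector.

Cross-validation holds out contiguous blocks of trials (default 100) in
turn, fits on the complement, and evaluates the held-out log-likelihood;
the final parameter vector is the arithmetic mean of per-fold optima
(fold optima are near-identical because folds share most data — tested
against a single full-data fit at the 5% level). Later folds warm-start
from the previous fold's optimum with a single local search; the first
fold uses the full restart budget. Datasets smaller than two blocks fall
back to a single full-data fold with a warning. Model comparison reports
the per-fold held-out log-likelihood difference of each candidate
against BLS, with its standard error across folds.

Lapse trials are identified post hoc as those where
`gamma * p(t_p|lapse)` exceeds `(1-gamma) * p_nonlapse(t_p|t_s, Theta)`;
the non-lapse density is marginalized over measurements because the
estimate itself is latent.

## Summary statistics

With `mean_i` and `var_i` the mean and unbiased (n-1) variance of `t_p`
at the i-th distinct sample interval,

    BIAS^2 = (1/N) sum_i (mean_i - t_s_i)^2,
    VAR    = (1/N) sum_i var_i,
    RMSE   = sqrt(BIAS^2 + VAR).

Observed statistics exclude flagged lapse trials and subtract the fitted
offset first. Model-expected statistics average BIAS^2 and VAR over
repeated simulations (default 1000) with trial counts matched per `t_s`,
lapse and offset forced off; averaging finite-size replicates keeps the
small-sample inflation of the observed statistics in the prediction. The
RMSE difference between conditions is tested with a permutation test
stratified by `t_s` (labels shuffled within stratum, preserving each
condition's stimulus composition), two-sided, with the add-one p-value
`(1 + #{|null| >= |obs|}) / (1 + n_perm)` and 10,000 permutations by
default.

## Task simulator

The generator draws `t_s` i.i.d. from the discrete support, interleaves
conditions by a Bernoulli mix (default 0.5), and composes measurement
noise, the model estimator, production noise, the offset, and lapses.
For batches above 20,000 trials the estimator maps are tabulated over
the range of the drawn measurements and interpolated (monotone cubic in
one dimension, bicubic on a 4 ms grid for the two-measurement posterior
means); the interpolation error is below 1e-5 ms — some seven orders of
magnitude under the production noise — and the random stream is
identical on both paths.
Negative productions are redrawn rather than truncated (the response
density ignores the positivity constraint; redraw frequency is
negligible at fitted parameters). The one-up/one-down correctness
staircase on the relative error |t_p - t_s|/t_s starts at 0.15, steps by
0.001 (down after correct, up after incorrect, floored at one step), and
equilibrates near 50% correct; correctness is judged inclusively at the
threshold. The staircase only does feedback bookkeeping — the observer
models contain no feedback-dependent term, so it never alters the
generative process. Exclusion rules mirror the experimental protocol:
the first 99 trials of each session are dropped (adaptation to the
prior), as are anticipatory responses (t_p <= 0) and responses later
than `t_s + 1000` ms, the boundary being inclusive (a response at
exactly `t_s + 1000` survives).

What the simulator does *not* emulate: reaction-time structure of the
keypress, inter-trial delays, session-to-session drift in Weber
fractions, correlated noise between the two measurements of a 1-2-3-Go
trial (the two flashes share an event, so real measurements may be
correlated), and sequential effects of feedback on behaviour. Passing
tests therefore certify the inference machinery on data that obey the
model assumptions exactly; they do not certify those assumptions for any
particular empirical dataset.

## Validation suite

Every quadrature-based quantity has an independent check: posterior
means against self-normalized importance sampling from the raw Gaussian
formulas (1e6 draws, delta-method SE) and against `scipy.integrate.quad`;
marginal densities against forward-simulation histograms (20 ms bins,
binomial SEs, family-wise bound on the largest bin z-score); identities
(EKF/LNE with one measurement vs BLS, BLS_mem at `w_mem = w_m` vs BLS,
recursive vs batch posterior) at 1e-9. Parameter recovery (Weber
fractions within 20% from 2000 trials) and model recovery (the
generating model attains the highest held-out log-likelihood among the
four candidates on 4000-trial datasets from each generator) run as part
of the test suite with a reduced-cost configuration: 51-node measurement
grids, 1 ms estimate grid, two folds of 2000 trials, two restarts.
Problem sizes in the suite (trial counts, replicate counts, draw counts)
were chosen as the smallest at which each effect is comfortably resolved.

A note on the bias/variance character of EKF suboptimality: at matched
`w_m` the EKF's two-measurement BIAS statistic is *below* the optimal
BLS estimator's for Weber fractions up to about 0.1 — the interior
sample intervals show more central tendency, but the edge intervals,
which dominate the squared statistic, show less, and the lost accuracy
appears as excess VAR instead. Only for `w_m` of roughly 0.15 and above
does EKF suboptimality manifest as excess BIAS. The test suite computes
both regimes; analyses that expect an excess-bias signature from
EKF-like behaviour should keep this parameter dependence in mind.

## Known limitations

* The likelihood engine supports one or two measurements per trial; the
  estimators themselves accept longer sequences.
* Cross-validation SEs come from as few as two folds in the reduced
  configuration and are correspondingly coarse.
* Gradients are not available; fits rely on derivative-free search and
  can in principle terminate at local optima (mitigated by restarts).
* The subjective prior is assumed to match the experimental one, the
  cost function is quadratic, and measurement noises are independent —
  all structural assumptions inherited by every model in the set.
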