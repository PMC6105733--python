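"""Independent cross-checks of the quadrature pipeline.

Monte-Carlo oracles (plain numpy sampling, no Simpson machinery) for the
estimator maps and marginal densities, plus the two structural
diagnostics that motivate the modelling: the scalar-noise likelihood
family is not closed under multiplication, and constant-noise (Gaussian)
integration collapses the two-measurement estimator to a function of the
measurement sum. These back the ``validate`` CLI command and the test
suite's oracle-equivalence checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._quad import simpson_nodes
from .likelihood import PredictiveDensity, QuadratureConfig, DEFAULT_QUAD
from .models import ObserverParams
from .prior import PriorSpec

__all__ = [
    "mc_posterior_mean",
    "mc_density_check",
    "scalar_product_fit_residual",
    "line_scan_range",
]


def mc_posterior_mean(
    t_m1: float,
    w1: float,
    prior: PriorSpec,
    t_m2: float | None = None,
    w2: float | None = None,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo posterior mean E[t_s | measurements] and its standard error.

    Self-normalized importance sampling with the uniform prior as the
    proposal: draw ``t_s ~ U[t_min, t_max]``, weight by the likelihood(s)
    evaluated from the raw Gaussian formula. Independent of the Simpson
    quadrature used by the estimator maps.
    """
    rng = np.random.default_rng() if rng is None else rng
    ts = rng.uniform(prior.t_min, prior.t_max, n_draws)

    def raw_likelihood(t_m: float, w: float) -> np.ndarray:
        sd = w * ts
        return np.exp(-0.5 * ((t_m - ts) / sd) ** 2) / sd

    w = raw_likelihood(t_m1, w1)
    if t_m2 is not None:
        w = w * raw_likelihood(t_m2, w2 if w2 is not None else w1)
    total = w.sum()
    mean = float((w * ts).sum() / total)
    # delta-method SE of the ratio estimator
    se = float(np.sqrt(np.sum((w * (ts - mean)) ** 2)) / total)
    return mean, se


@dataclass(frozen=True)
class DensityCheck:
    bin_edges: np.ndarray
    mc_probs: np.ndarray
    model_probs: np.ndarray
    se: np.ndarray

    @property
    def max_discrepancy_se(self) -> float:
        """Largest |MC - model| bin discrepancy in units of binomial SE."""
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(self.mc_probs - self.model_probs) / self.se
        return float(np.nanmax(z[self.se > 0]))


def mc_density_check(
    t_s: float,
    n_meas: int,
    params: ObserverParams,
    prior: PriorSpec,
    quad: QuadratureConfig = DEFAULT_QUAD,
    n_draws: int = 1_000_000,
    bin_width: float = 20.0,
    rng: np.random.Generator | None = None,
) -> DensityCheck:
    """Compare the marginal density against a Monte-Carlo histogram of t_p.

    Simulates ``n_draws`` productions by forward sampling (measurement
    noise -> estimator -> production noise -> lapse mixture) and bins
    them; the model probabilities integrate the quadrature density over
    the same bins. Returns per-bin probabilities and binomial SEs.
    """
    from .simulate import _simulate_core  # forward sampler
    from .models import Condition

    rng = np.random.default_rng() if rng is None else rng
    cond = (
        Condition.ONE_TWO_GO if n_meas == 1 else Condition.ONE_TWO_THREE_GO
    )
    out = _simulate_core(
        np.full(n_draws, cond.value), np.full(n_draws, float(t_s)), params, prior, rng
    )
    tp = out["tp_ms"]
    lo, hi = params.lapse_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(tp, bins=edges)
    mc = counts / n_draws
    se = np.sqrt(np.clip(mc * (1 - mc), 0, None) / n_draws)

    engine = PredictiveDensity(params, prior, quad)
    fine = 5  # Simpson sub-nodes per bin for the model-bin mass
    probs = np.empty(mc.size)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        x, wq = simpson_nodes(a, b, fine)
        probs[i] = wq @ engine.density(x, t_s, n_meas)
    return DensityCheck(edges, mc, probs, se)


def scalar_product_fit_residual(
    t_m1: float,
    t_m2: float,
    w: float,
    prior: PriorSpec,
    n_grid: int = 401,
    gaussian: bool = False,
) -> float:
    """Relative residual of the best single-likelihood fit to a likelihood product.

    Fits ``a * L(t_s; m, v)`` (amplitude, location, width) by least
    squares to the product of the two measurement likelihoods over a
    ``t_s`` grid. With scalar noise the product leaves the family, so the
    residual stays well above zero for ``t_m1 != t_m2``; with
    duration-independent Gaussian noise (``gaussian=True``) the family is
    closed and the residual vanishes. Returns ||residual|| / ||product||.
    """
    ts = np.linspace(prior.t_min, prior.t_max, n_grid)

    if gaussian:
        def member(theta):
            m, v = theta
            return np.exp(-0.5 * ((m - ts) / v) ** 2)
    else:
        def member(theta):
            m, v = theta
            sd = v * ts
            return np.exp(-0.5 * ((m - ts) / sd) ** 2) / sd

    target = member((t_m1, w)) * member((t_m2, w))
    scale = np.linalg.norm(target)

    def residual(theta):
        a, m, v = theta
        return (a * member((m, abs(v))) - target) / scale

    x0 = np.array([np.max(target), 0.5 * (t_m1 + t_m2), w])
    fit = least_squares(residual, x0, method="lm", max_nfev=20_000)
    return float(np.linalg.norm(fit.fun))


def line_scan_range(
    estimator, total: float, half_span: float, n: int = 41
) -> float:
    """Range of a two-measurement estimator along the line t_m1 + t_m2 = total.

    ``estimator(t_m1, t_m2)`` is evaluated on symmetric pairs around
    ``total / 2``; returns max - min of the estimates. Zero (up to
    quadrature error) means linear iso-estimate contours.
    """
    d = np.linspace(-half_span, half_span, n)
    est = estimator(total / 2 + d, total / 2 - d)
    return float(np.max(est) - np.min(est))
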