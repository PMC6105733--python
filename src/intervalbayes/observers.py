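"""Scalar-noise likelihood, posteriors, estimator maps, and response densities.

All durations are milliseconds and all densities are per ms. The
measurement likelihood is Gaussian in ``t_m`` with SD proportional to the
*sample* interval (scalar variability): as a function of ``t_s`` at fixed
``t_m`` it is skewed toward longer intervals, which is what makes the
two-measurement posterior leave the single-likelihood family and forces
the estimators below apart.

Estimator maps
--------------
``bls1_map``      posterior mean after one measurement (all models share it)
``bls2_map``      posterior mean after two measurements (optimal)
``blsmem_map``    two-measurement posterior mean with a distinct Weber
                  fraction on the first measurement
``lne_estimate``  running average of the measurements passed through the
                  one-measurement BLS nonlinearity
``ekf_estimate``  sequential update: gain-scaled nonlinear function of the
                  prediction error added to the running estimate
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._quad import simpson_nodes
from .models import ObserverParams
from .prior import PriorSpec

__all__ = [
    "scalar_likelihood",
    "posterior_1meas",
    "posterior_2meas_batch",
    "posterior_2meas_recursive",
    "bls1_map",
    "bls2_map",
    "blsmem_map",
    "bls2_map_constant_noise",
    "Bls1Table",
    "EstimatorState",
    "ekf_update",
    "ekf_estimate",
    "lne_update",
    "lne_estimate",
    "production_density",
    "response_mixture_density",
    "N_TS_NODES",
]

#: default Simpson node count over the prior support [t_min, t_max]
N_TS_NODES = 201

#: evaluate vectorized estimator maps in chunks of this many arguments,
#: bounding the (n, n_ts) likelihood matrices to ~100 MB of temporaries
_CHUNK = 65536

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _check_positive(name: str, value) -> None:
    if np.any(np.asarray(value) <= 0):
        raise ValueError(f"{name} must be strictly positive")


def scalar_likelihood(t_m, t_s, w) -> np.ndarray:
    """Gaussian measurement density with scalar noise, lambda(t_m | t_s).

    Mean ``t_s``, SD ``w * t_s``. ``t_m`` may be any real number;
    ``t_s`` and ``w`` must be positive.
    """
    t_s = np.asarray(t_s, dtype=float)
    _check_positive("t_s", t_s)
    _check_positive("w", w)
    sd = w * t_s
    z = (np.asarray(t_m, dtype=float) - t_s) / sd
    return np.exp(-0.5 * z * z) / (_SQRT2PI * sd)


def production_density(t_p, t_e, w_p, b: float = 0.0) -> np.ndarray:
    """Density of the produced interval: Gaussian, mean ``t_e + b``, SD ``w_p * t_e``.

    The offset ``b`` shifts the mean only; the SD scales with the estimate.
    """
    t_e = np.asarray(t_e, dtype=float)
    _check_positive("t_e", t_e)
    _check_positive("w_p", w_p)
    sd = w_p * t_e
    z = (np.asarray(t_p, dtype=float) - t_e - b) / sd
    return np.exp(-0.5 * z * z) / (_SQRT2PI * sd)


def response_mixture_density(t_p, t_e, params: ObserverParams) -> np.ndarray:
    """Lapse-augmented response density.

    ``(1 - gamma) * production + gamma * Uniform(lapse_range)``; with
    ``gamma = 0`` this is exactly the production density.
    """
    t_p = np.asarray(t_p, dtype=float)
    core = production_density(t_p, t_e, params.w_p, params.b)
    if params.gamma == 0.0:
        return core
    lo, hi = params.lapse_range
    lapse = np.where((t_p >= lo) & (t_p <= hi), 1.0 / params.lapse_width, 0.0)
    return (1.0 - params.gamma) * core + params.gamma * lapse


# ---------------------------------------------------------------------------
# posteriors over t_s
# ---------------------------------------------------------------------------

def _check_grid(ts_grid: np.ndarray, prior: PriorSpec) -> np.ndarray:
    grid = np.asarray(ts_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 3:
        raise ValueError("ts_grid must be a 1-D grid with >= 3 nodes")
    if grid[0] > prior.t_min or grid[-1] < prior.t_max:
        raise ValueError(
            f"ts_grid [{grid[0]}, {grid[-1]}] does not cover the prior "
            f"support [{prior.t_min}, {prior.t_max}]"
        )
    return grid


def _normalize_on_grid(density: np.ndarray, grid: np.ndarray) -> np.ndarray:
    total = np.trapezoid(density, grid)
    if not total > 0:
        raise ValueError("posterior has zero mass on the grid")
    return density / total


def posterior_1meas(ts_grid, t_m1: float, w_m: float, prior: PriorSpec) -> np.ndarray:
    """Posterior density over ``ts_grid`` after one measurement, trapezoid-normalized."""
    grid = _check_grid(ts_grid, prior)
    dens = np.where(
        prior.pdf(grid) > 0, scalar_likelihood(t_m1, grid, w_m) * prior.pdf(grid), 0.0
    )
    return _normalize_on_grid(dens, grid)


def posterior_2meas_batch(
    ts_grid, t_m1: float, t_m2: float, w_m: float, prior: PriorSpec
) -> np.ndarray:
    """Two-measurement posterior computed in one step: lambda * lambda * prior, normalized."""
    grid = _check_grid(ts_grid, prior)
    dens = (
        scalar_likelihood(t_m1, grid, w_m)
        * scalar_likelihood(t_m2, grid, w_m)
        * prior.pdf(grid)
    )
    return _normalize_on_grid(dens, grid)


def posterior_2meas_recursive(
    ts_grid, t_m1: float, t_m2: float, w_m: float, prior: PriorSpec
) -> np.ndarray:
    """Two-measurement posterior via sequential updating.

    The one-measurement posterior serves as the prior for the second
    measurement; algebraically identical to the batch form.
    """
    grid = _check_grid(ts_grid, prior)
    stage1 = posterior_1meas(grid, t_m1, w_m, prior)
    dens = scalar_likelihood(t_m2, grid, w_m) * stage1
    return _normalize_on_grid(dens, grid)


# ---------------------------------------------------------------------------
# BLS estimator maps (posterior means under the continuous uniform prior)
# ---------------------------------------------------------------------------

def _likelihood_matrix(t_m: np.ndarray, ts: np.ndarray, w: float) -> np.ndarray:
    """lambda(t_m_i | ts_j) as an (n_m, n_ts) matrix."""
    sd = w * ts[None, :]
    z = (t_m[:, None] - ts[None, :]) / sd
    return np.exp(-0.5 * z * z) / (_SQRT2PI * sd)


def _log_likelihood_matrix(t_m: np.ndarray, ts: np.ndarray, w: float) -> np.ndarray:
    sd = w * ts  # the log-prefactor only depends on the ts grid
    z = (t_m[:, None] - ts[None, :]) * (1.0 / sd)[None, :]
    z *= z
    z *= -0.5
    z -= np.log(_SQRT2PI * sd)[None, :]
    return z


def _posterior_mean_rows(
    loglam: np.ndarray, ts: np.ndarray, wts: np.ndarray
) -> np.ndarray:
    """Row-wise E[ts] with weights exp(loglam)*wts, stabilized against underflow."""
    lam = np.exp(loglam - loglam.max(axis=1, keepdims=True))
    return (lam @ (wts * ts)) / (lam @ wts)


def bls1_map(t_m1, w_m: float, prior: PriorSpec, n_nodes: int = N_TS_NODES):
    """One-measurement BLS estimate E[t_s | t_m1] under the uniform prior.

    Defined for any real ``t_m1`` (including values outside the prior
    range); strictly increasing and bounded in (t_min, t_max).
    """
    _check_positive("w_m", w_m)
    t_m = np.atleast_1d(np.asarray(t_m1, dtype=float))
    ts, wts = simpson_nodes(prior.t_min, prior.t_max, n_nodes)
    flat = t_m.ravel()
    est = np.concatenate(
        [
            _posterior_mean_rows(_log_likelihood_matrix(chunk, ts, w_m), ts, wts)
            for chunk in np.array_split(flat, max(1, flat.size // _CHUNK))
        ]
    ).reshape(t_m.shape)
    return est if np.ndim(t_m1) else float(est[0])


def _bls2_core(
    t_m1, t_m2, w1: float, w2: float, prior: PriorSpec, n_nodes: int
):
    a1 = np.atleast_1d(np.asarray(t_m1, dtype=float))
    a2 = np.atleast_1d(np.asarray(t_m2, dtype=float))
    a1, a2 = np.broadcast_arrays(a1, a2)
    shape = a1.shape
    ts, wts = simpson_nodes(prior.t_min, prior.t_max, n_nodes)
    f1, f2 = a1.ravel(), a2.ravel()
    parts = []
    n_chunks = max(1, f1.size // _CHUNK)
    for c1, c2 in zip(np.array_split(f1, n_chunks), np.array_split(f2, n_chunks)):
        loglam = _log_likelihood_matrix(c1, ts, w1) + _log_likelihood_matrix(
            c2, ts, w2
        )
        parts.append(_posterior_mean_rows(loglam, ts, wts))
    est = np.concatenate(parts).reshape(shape)
    if np.ndim(t_m1) == 0 and np.ndim(t_m2) == 0:
        return float(est.ravel()[0])
    return est


def bls2_map(t_m1, t_m2, w_m: float, prior: PriorSpec, n_nodes: int = N_TS_NODES):
    """Two-measurement BLS estimate E[t_s | t_m1, t_m2]; symmetric in its arguments."""
    _check_positive("w_m", w_m)
    return _bls2_core(t_m1, t_m2, w_m, w_m, prior, n_nodes)


def blsmem_map(
    t_m1, t_m2, w_mem: float, w_m: float, prior: PriorSpec, n_nodes: int = N_TS_NODES
):
    """Two-measurement BLS estimate with Weber fraction ``w_mem`` on the first measurement.

    Reduces exactly to :func:`bls2_map` when ``w_mem == w_m``; as
    ``w_mem -> inf`` the first measurement becomes uninformative and the
    map approaches ``bls1_map(t_m2)``.
    """
    _check_positive("w_mem", w_mem)
    _check_positive("w_m", w_m)
    return _bls2_core(t_m1, t_m2, w_mem, w_m, prior, n_nodes)


def bls2_map_constant_noise(
    t_m1, t_m2, sigma: float, prior: PriorSpec, n_nodes: int = N_TS_NODES
):
    """Two-measurement posterior mean when both likelihoods have a *constant* SD.

    Control case: with duration-independent Gaussian noise the estimate
    depends on the measurements only through their sum, so iso-estimate
    contours in the (t_m1, t_m2) plane are straight lines. The contrast
    with :func:`bls2_map` isolates the effect of scalar noise.
    """
    _check_positive("sigma", sigma)
    a1 = np.atleast_1d(np.asarray(t_m1, dtype=float))
    a2 = np.atleast_1d(np.asarray(t_m2, dtype=float))
    a1, a2 = np.broadcast_arrays(a1, a2)
    ts, wts = simpson_nodes(prior.t_min, prior.t_max, n_nodes)
    z1 = (a1.ravel()[:, None] - ts[None, :]) / sigma
    z2 = (a2.ravel()[:, None] - ts[None, :]) / sigma
    est = _posterior_mean_rows(-0.5 * (z1 * z1 + z2 * z2), ts, wts).reshape(a1.shape)
    if np.ndim(t_m1) == 0 and np.ndim(t_m2) == 0:
        return float(est.ravel()[0])
    return est


class Bls1Table:
    """Cached one-measurement BLS map on a dense grid with monotone interpolation.

    The EKF and LNE estimators call ``bls1_map`` inside inner loops; this
    table evaluates the quadrature once on a uniform argument grid and
    interpolates with a shape-preserving (monotone) cubic. Arguments must
    lie inside ``[lo, hi]``.
    """

    def __init__(
        self,
        w_m: float,
        prior: PriorSpec,
        lo: float | None = None,
        hi: float | None = None,
        step: float = 1.0,
        n_nodes: int = N_TS_NODES,
    ) -> None:
        _check_positive("w_m", w_m)
        _check_positive("step", step)
        half = 3.0 * prior.width
        self.lo = float(prior.mean - half if lo is None else lo)
        self.hi = float(prior.mean + half if hi is None else hi)
        if not self.lo < self.hi:
            raise ValueError("table range is empty")
        self.w_m = float(w_m)
        self.prior = prior
        self.step = float(step)
        n = int(np.ceil((self.hi - self.lo) / self.step)) + 1
        self.args = self.lo + self.step * np.arange(n)
        self.hi = float(self.args[-1])
        self.values = bls1_map(self.args, w_m, prior, n_nodes)
        self._interp = PchipInterpolator(self.args, self.values, extrapolate=False)

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lo) or np.any(x > self.hi):
            raise ValueError(
                f"argument outside the cached range [{self.lo}, {self.hi}] ms"
            )
        return self._interp(x)

    def to_csv(self, path) -> None:
        """Export the lookup table as a two-column CSV (argument_ms, estimate_ms)."""
        arr = np.column_stack([self.args, self.values])
        np.savetxt(path, arr, delimiter=",", header="argument_ms,estimate_ms", comments="")


# ---------------------------------------------------------------------------
# sequential estimators (EKF and LNE)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EstimatorState:
    """State of a sequential estimator after ``n`` absorbed measurements.

    ``w is None`` encodes an infinitely unreliable initial estimate
    (the prior mean before any measurement), handled symbolically so the
    first gain is exactly 1 rather than inf/inf.
    """

    t_e: float
    n: int = 0
    w: float | None = None
    running_mean: float | None = None
    last_gain: float | None = None
    last_error: float | None = None

    @classmethod
    def initial(cls, prior: PriorSpec) -> "EstimatorState":
        return cls(t_e=prior.mean)


def _resolve_f1(
    f_bls1: Callable | None, w_m: float, prior: PriorSpec
) -> Callable:
    if f_bls1 is not None:
        return f_bls1
    return lambda x: bls1_map(x, w_m, prior)


def ekf_update(
    state: EstimatorState,
    t_m: float,
    w_m: float,
    prior: PriorSpec,
    f_bls1: Callable | None = None,
) -> EstimatorState:
    """One EKF step: ``t_e <- t_e + k * fstar(t_m - t_e)``.

    ``fstar(x) = bls1_map(x + t_e0) - t_e0`` with ``t_e0`` the prior mean;
    the gain is ``k = w_prev^2 / (w_prev^2 + w_m^2)`` and the estimate
    Weber fraction is propagated as in Gaussian cue combination,
    ``w <- w_prev * w_m / sqrt(w_prev^2 + w_m^2)`` (strictly decreasing).
    The initial state (``w = None``, i.e. infinite) gives ``k = 1`` exactly.
    """
    _check_positive("w_m", w_m)
    f1 = _resolve_f1(f_bls1, w_m, prior)
    t_e0 = prior.mean
    x = float(t_m) - state.t_e
    innovation = float(f1(x + t_e0)) - t_e0
    if state.w is None:  # w_prev = inf, exact limit
        k = 1.0
        w_new = float(w_m)
    else:
        w2, m2 = state.w**2, w_m**2
        k = w2 / (w2 + m2)
        w_new = state.w * w_m / np.sqrt(w2 + m2)
    return replace(
        state,
        t_e=state.t_e + k * innovation,
        n=state.n + 1,
        w=float(w_new),
        last_gain=float(k),
        last_error=x,
    )


def ekf_estimate(
    measurements: Sequence[float],
    w_m: float,
    prior: PriorSpec,
    f_bls1: Callable | None = None,
) -> float:
    """Chain EKF updates from the prior mean; identical to bls1_map for one measurement."""
    if len(measurements) == 0:
        raise ValueError("need at least one measurement")
    state = EstimatorState.initial(prior)
    f1 = _resolve_f1(f_bls1, w_m, prior)
    for t_m in measurements:
        state = ekf_update(state, t_m, w_m, prior, f_bls1=f1)
    return state.t_e


def lne_update(state: EstimatorState, t_m: float) -> EstimatorState:
    """One running-average step with gain ``k_n = 1/n``.

    The first measurement initialises the mean (gain 1); the second is
    weighted by 1/2, and so on. The estimate field is the raw running
    mean; the nonlinearity is applied only when reading out the estimate.
    """
    n = state.n + 1
    k = 1.0 / n
    prev = state.running_mean if state.running_mean is not None else 0.0
    mean = (1.0 - k) * prev + k * float(t_m)
    return replace(
        state,
        n=n,
        running_mean=mean,
        last_gain=k,
        last_error=float(t_m) - (state.running_mean if state.running_mean is not None else state.t_e),
    )


def lne_estimate(
    measurements: Sequence[float],
    w_m: float,
    prior: PriorSpec,
    f_bls1: Callable | None = None,
) -> float:
    """LNE estimate: one-measurement BLS nonlinearity applied to the running mean."""
    if len(measurements) == 0:
        raise ValueError("need at least one measurement")
    state = EstimatorState.initial(prior)
    for t_m in measurements:
        state = lne_update(state, t_m)
    f1 = _resolve_f1(f_bls1, w_m, prior)
    return float(f1(state.running_mean))
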