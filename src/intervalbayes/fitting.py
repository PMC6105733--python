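"""Predictive maximum-likelihood fitting with leave-N-out cross-validation.

Each model is fit by maximizing the trial-wise log predictive likelihood
with a bounded derivative-free search (Nelder-Mead in a unit box over the
parameter bounds), restarted from Latin-hypercube initial points.
Cross-validation holds out contiguous blocks of trials in turn
(``test_block_size`` per fold, 100 by default), refits on the complement,
and evaluates the held-out log-likelihood; the final parameter vector is
the arithmetic mean of the per-fold optima. Model comparison reports the
per-fold held-out log-likelihood ratio of a candidate against the BLS
reference, with its standard error across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .likelihood import DEFAULT_QUAD, PredictiveDensity, QuadratureConfig
from .models import Condition, Model, ObserverParams
from .prior import PriorSpec

__all__ = [
    "DEFAULT_BOUNDS",
    "FitConfig",
    "FitResult",
    "LoglikRatio",
    "optimize_params",
    "fit_model_lnocv",
    "classify_lapse_trials",
    "loglik_ratio_vs_bls",
]

#: per-parameter fitting bounds; Weber fractions below 1e-3 are outside
#: the fitted domain (limit behaviour is still available to direct calls)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "w_m": (1e-3, 0.5),
    "w_p": (1e-3, 0.5),
    "b": (-300.0, 300.0),
    "gamma": (0.0, 0.3),
    "w_mem": (1e-3, 1.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and cross-validation settings."""

    test_block_size: int = 100
    optimizer_restarts: int = 5
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    seed: int = 0
    fold_scheme: str = "contiguous"  # or "random"
    maxfev: int = 400
    xatol: float = 1e-3  # in unit-box coordinates
    fatol: float = 0.01  # nats
    warm_start: bool = True  # later folds start from the previous optimum

    def __post_init__(self) -> None:
        if self.test_block_size <= 0:
            raise ValueError("test_block_size must be positive")
        if self.optimizer_restarts < 1:
            raise ValueError("optimizer_restarts must be >= 1")
        if self.fold_scheme not in ("contiguous", "random"):
            raise ValueError("fold_scheme must be 'contiguous' or 'random'")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered")


@dataclass
class FitResult:
    """Per-fold and averaged outcome of one model fit."""

    model: Model
    per_fold_params: list[ObserverParams]
    averaged_params: ObserverParams
    per_fold_test_loglik: list[float]
    per_fold_train_loglik: list[float]
    fold_test_indices: list[np.ndarray]
    n_trials: int


@dataclass(frozen=True)
class LoglikRatio:
    """Held-out log-likelihood ratio of a candidate model vs the BLS reference."""

    model: Model
    per_fold: np.ndarray
    mean: float
    se: float


def _param_names(model: Model) -> list[str]:
    names = ["w_m", "w_p", "b", "gamma"]
    if model is Model.BLS_MEM:
        names.append("w_mem")
    return names


def _to_params(model: Model, values: np.ndarray, names: list[str]) -> ObserverParams:
    kw = dict(zip(names, (float(v) for v in values)))
    return ObserverParams(model=model, **kw)


def _default_init(model: Model, bounds: dict) -> np.ndarray:
    init = {"w_m": 0.15, "w_p": 0.1, "b": 0.0, "gamma": 0.02, "w_mem": 0.2}
    names = _param_names(model)
    x = np.array([init[n] for n in names])
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    return np.clip(x, lo, hi)


def optimize_params(
    trials: pd.DataFrame,
    model: Model,
    prior: PriorSpec,
    quad: QuadratureConfig = DEFAULT_QUAD,
    config: FitConfig = FitConfig(),
    init: ObserverParams | None = None,
) -> tuple[ObserverParams, float]:
    """Maximize the dataset log-likelihood over the bounded parameter box.

    Runs ``optimizer_restarts`` local searches: the first from ``init``
    (or field defaults), the rest from Latin-hypercube points. Returns
    the best parameters and their attained log-likelihood.
    """
    if len(trials) == 0:
        raise ValueError("cannot fit an empty trial table")
    model = Model(model)
    names = _param_names(model)
    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])

    def objective(u: np.ndarray) -> float:
        x = lo + np.clip(u, 0.0, 1.0) * (hi - lo)
        params = _to_params(model, x, names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll = PredictiveDensity(params, prior, quad).log_likelihood(trials)
        return -ll if np.isfinite(ll) else 1e12

    starts = []
    if init is not None:
        starts.append(np.array([getattr(init, n) for n in names], dtype=float))
    else:
        starts.append(_default_init(model, config.bounds))
    n_extra = config.optimizer_restarts - 1
    if n_extra > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
        starts.extend(lo + sampler.random(n_extra) * (hi - lo))

    best_u, best_f = None, np.inf
    diagnostics = []
    for x0 in starts:
        u0 = (np.clip(x0, lo, hi) - lo) / (hi - lo)
        res = minimize(
            objective, u0, method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * len(names),
            options={
                "maxfev": config.maxfev,
                "xatol": config.xatol,
                "fatol": config.fatol,
            },
        )
        diagnostics.append((x0, res))
        if res.fun < best_f:
            best_u, best_f = res.x, res.fun
    if best_u is None or not np.isfinite(best_f):
        raise RuntimeError(f"all optimizer restarts failed: {diagnostics}")
    x = lo + np.clip(best_u, 0.0, 1.0) * (hi - lo)
    return _to_params(model, x, names), -best_f


def _fold_indices(
    n: int, config: FitConfig
) -> list[np.ndarray]:
    block = config.test_block_size
    if n < 2 * block:
        warnings.warn(
            f"dataset of {n} trials is smaller than two test blocks of "
            f"{block}; fitting a single fold on the full data",
            stacklevel=3,
        )
        return [np.arange(n)]
    order = np.arange(n)
    if config.fold_scheme == "random":
        order = np.random.default_rng(config.seed).permutation(n)
    n_folds = n // block
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    return [np.sort(order[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]


def fit_model_lnocv(
    trials: pd.DataFrame,
    model: Model,
    prior: PriorSpec,
    quad: QuadratureConfig = DEFAULT_QUAD,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Leave-N-out cross-validated fit of one model.

    The trial table is partitioned into test blocks; each fold fits on
    the complement and evaluates the held-out block. The first fold uses
    the full restart budget; with ``warm_start`` later folds run a single
    search from the previous fold's optimum (the folds share most data,
    so their optima are close).
    """
    model = Model(model)
    trials = trials.reset_index(drop=True)
    folds = _fold_indices(len(trials), config)
    single_fold = len(folds) == 1

    per_fold_params: list[ObserverParams] = []
    test_ll: list[float] = []
    train_ll: list[float] = []
    prev: ObserverParams | None = None
    for i, test_idx in enumerate(folds):
        train = trials if single_fold else trials.drop(index=test_idx)
        if config.warm_start and prev is not None:
            cfg = FitConfig(**{**config.__dict__, "optimizer_restarts": 1})
            params, ll = optimize_params(train, model, prior, quad, cfg, init=prev)
        else:
            params, ll = optimize_params(train, model, prior, quad, config)
        prev = params
        per_fold_params.append(params)
        train_ll.append(ll)
        test = trials.loc[test_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            test_ll.append(PredictiveDensity(params, prior, quad).log_likelihood(test))

    names = _param_names(model)
    avg = {
        n: float(np.mean([getattr(p, n) for p in per_fold_params])) for n in names
    }
    return FitResult(
        model=model,
        per_fold_params=per_fold_params,
        averaged_params=ObserverParams(model=model, **avg),
        per_fold_test_loglik=test_ll,
        per_fold_train_loglik=train_ll,
        fold_test_indices=folds,
        n_trials=len(trials),
    )


def classify_lapse_trials(
    trials: pd.DataFrame,
    params: ObserverParams,
    prior: PriorSpec,
    quad: QuadratureConfig = DEFAULT_QUAD,
) -> np.ndarray:
    """Flag trials whose lapse likelihood exceeds their non-lapse likelihood.

    Trial i is a lapse iff ``gamma * p(t_p | lapse) >
    (1 - gamma) * p_nonlapse(t_p | t_s, Theta)``, where the non-lapse
    density is marginalized over the unobserved measurements (the
    estimate itself is latent). ``gamma = 0`` flags nothing.
    """
    flags = np.zeros(len(trials), dtype=bool)
    if params.gamma == 0.0 or len(trials) == 0:
        return flags
    engine = PredictiveDensity(params, prior, quad)
    lo, hi = params.lapse_range
    trials = trials.reset_index(drop=True)
    n_meas = trials["condition"].map(lambda c: Condition.parse(c).n_meas)
    for (t_s, k), idx in trials.groupby([trials["ts_ms"], n_meas]).groups.items():
        tp = trials.loc[idx, "tp_ms"].to_numpy(dtype=float)
        p_nl = engine.nonlapse_density(tp, float(t_s), int(k))
        p_lapse = np.where((tp >= lo) & (tp <= hi), 1.0 / params.lapse_width, 0.0)
        flags[np.asarray(idx)] = params.gamma * p_lapse > (1.0 - params.gamma) * p_nl
    return flags


def loglik_ratio_vs_bls(fit_candidate: FitResult, fit_bls: FitResult) -> LoglikRatio:
    """Per-fold held-out log-likelihood of a candidate minus that of BLS.

    Both fits must have used identical fold partitions. Positive values
    favour the candidate.
    """
    if fit_bls.model is not Model.BLS:
        raise ValueError("reference fit must be the BLS model")
    if len(fit_candidate.fold_test_indices) != len(fit_bls.fold_test_indices) or any(
        not np.array_equal(a, b)
        for a, b in zip(fit_candidate.fold_test_indices, fit_bls.fold_test_indices)
    ):
        raise ValueError("fold partitions of the two fits do not match")
    per_fold = np.asarray(fit_candidate.per_fold_test_loglik) - np.asarray(
        fit_bls.per_fold_test_loglik
    )
    n = per_fold.size
    se = float(np.std(per_fold, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return LoglikRatio(
        model=fit_candidate.model,
        per_fold=per_fold,
        mean=float(np.mean(per_fold)),
        se=se,
    )
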