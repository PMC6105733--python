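"""Bias/variance summary statistics of interval reproduction.

For each distinct sample interval, let ``mean_tp`` and ``var_tp`` be the
mean and (unbiased, n-1) variance of the produced intervals. Then

    BIAS^2 = mean over distinct t_s of (mean_tp - t_s)^2     [ms^2]
    VAR    = mean over distinct t_s of var_tp                [ms^2]
    RMSE   = sqrt(BIAS^2 + VAR)                              [ms]

Observed statistics are computed on non-lapse trials after removing the
fitted offset; model-expected statistics average BIAS^2 and VAR over
repeated simulations with matched trial counts, lapse and offset off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import Condition, ObserverParams
from .prior import PriorSpec
from .simulate import _simulate_core

__all__ = [
    "SummaryStats",
    "PermutationResult",
    "bias_var_rmse",
    "expected_model_stats",
    "rmse_permutation_test",
    "normalized_rmse",
]


@dataclass(frozen=True)
class SummaryStats:
    """BIAS^2 / VAR / RMSE for one condition, plus the per-t_s moments."""

    condition: str
    source: str  # "observed" or "model_expected"
    per_ts_mean_tp: dict[float, float]
    per_ts_var_tp: dict[float, float]
    bias_sq: float
    var: float
    rmse: float

    @property
    def n_distinct_ts(self) -> int:
        return len(self.per_ts_mean_tp)


def _stats_from_groups(
    means: np.ndarray, variances: np.ndarray
) -> tuple[float, float, float]:
    bias_sq = float(np.mean(means))
    var = float(np.mean(variances))
    return bias_sq, var, float(np.sqrt(bias_sq + var))


def bias_var_rmse(
    trials: pd.DataFrame,
    fitted_b: float = 0.0,
    lapse_flags: np.ndarray | None = None,
    condition: str | None = None,
    source: str = "observed",
) -> SummaryStats:
    """Summary statistics of one condition's trials.

    The fitted offset is subtracted from every production before the
    moments are taken; lapse-flagged trials are excluded. Every distinct
    ``t_s`` needs at least 2 trials for the variance to exist.
    """
    trials = trials.reset_index(drop=True)
    if lapse_flags is not None:
        trials = trials[~np.asarray(lapse_flags, dtype=bool)]
    if condition is None:
        conds = trials["condition"].unique()
        if len(conds) > 1:
            raise ValueError(
                f"trials span several conditions {list(conds)}; pass one "
                "condition's trials or the condition argument"
            )
        condition = str(conds[0]) if len(conds) else "all"
    else:
        condition = Condition.parse(condition).value
        trials = trials[trials["condition"] == condition]
    tp = trials["tp_ms"].to_numpy(dtype=float) - fitted_b
    ts = trials["ts_ms"].to_numpy(dtype=float)
    mean_tp: dict[float, float] = {}
    var_tp: dict[float, float] = {}
    sq_dev, variances = [], []
    for t_s in np.unique(ts):
        vals = tp[ts == t_s]
        if vals.size < 2:
            raise ValueError(
                f"t_s = {t_s} has {vals.size} trial(s); variance undefined"
            )
        m = float(np.mean(vals))
        v = float(np.var(vals, ddof=1))
        mean_tp[float(t_s)] = m
        var_tp[float(t_s)] = v
        sq_dev.append((m - t_s) ** 2)
        variances.append(v)
    bias_sq, var, rmse = _stats_from_groups(np.array(sq_dev), np.array(variances))
    return SummaryStats(condition, source, mean_tp, var_tp, bias_sq, var, rmse)


def expected_model_stats(
    params: ObserverParams,
    prior: PriorSpec,
    trial_counts_per_ts: dict[float, int],
    condition: Condition | str,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> SummaryStats:
    """Model-expected statistics from repeated simulation with matched trial counts.

    Simulates ``reps`` full datasets (lapse rate and offset forced to
    zero), computes BIAS^2 and VAR of each, and averages the two
    components across repetitions; the RMSE is the root of the averaged
    components. Averaging over finite-size replicates keeps the
    small-sample inflation of the observed statistics in the prediction.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    cond = Condition.parse(condition)
    sim_params = params.replace(gamma=0.0, b=0.0)
    ts_values = sorted(trial_counts_per_ts)
    bias_acc = np.zeros(reps)
    var_acc = np.zeros(reps)
    mean_acc: dict[float, float] = {}
    var_by_ts: dict[float, float] = {}
    for t_s, count in ((float(t), int(trial_counts_per_ts[t])) for t in ts_values):
        if count < 2:
            raise ValueError(f"need >= 2 trials per t_s, got {count} for {t_s}")
        ts_arr = np.full(reps * count, t_s)
        conds = np.full(reps * count, cond.value)
        out = _simulate_core(conds, ts_arr, sim_params, prior, rng)
        tp = out["tp_ms"].reshape(reps, count)
        m = tp.mean(axis=1)
        v = tp.var(axis=1, ddof=1)
        bias_acc += (m - t_s) ** 2
        var_acc += v
        mean_acc[t_s] = float(m.mean())
        var_by_ts[t_s] = float(v.mean())
    n_ts = len(ts_values)
    bias_sq = float(np.mean(bias_acc / n_ts))
    var = float(np.mean(var_acc / n_ts))
    return SummaryStats(
        cond.value, "model_expected", mean_acc, var_by_ts,
        bias_sq, var, float(np.sqrt(bias_sq + var)),
    )


@dataclass(frozen=True)
class PermutationResult:
    observed: float  # RMSE(A) - RMSE(B), ms
    p_value: float
    n_perm: int


def rmse_permutation_test(
    trials_a: pd.DataFrame,
    trials_b: pd.DataFrame,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Two-sided permutation test of an RMSE difference between conditions.

    The statistic is ``RMSE(A) - RMSE(B)``. The null is built by
    shuffling the condition labels within each ``t_s`` stratum, which
    preserves each condition's t_s composition; the p-value is
    ``(1 + #{|null| >= |obs|}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng() if rng is None else rng
    ts_a = trials_a["ts_ms"].to_numpy(dtype=float)
    ts_b = trials_b["ts_ms"].to_numpy(dtype=float)
    tp_a = trials_a["tp_ms"].to_numpy(dtype=float)
    tp_b = trials_b["tp_ms"].to_numpy(dtype=float)
    strata = np.unique(np.concatenate([ts_a, ts_b]))

    def rmse_from(moments: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
        sq = np.mean([ (m - t) ** 2 for (m, _), t in zip(moments, strata)], axis=0)
        v = np.mean([v for _, v in moments], axis=0)
        return np.sqrt(sq + v)

    obs_moments_a, obs_moments_b = [], []
    null_a, null_b = [], []
    for t_s in strata:
        a_vals = tp_a[ts_a == t_s]
        b_vals = tp_b[ts_b == t_s]
        if a_vals.size < 2 or b_vals.size < 2:
            raise ValueError(f"stratum t_s = {t_s} needs >= 2 trials per condition")
        obs_moments_a.append((np.array([a_vals.mean()]), np.array([a_vals.var(ddof=1)])))
        obs_moments_b.append((np.array([b_vals.mean()]), np.array([b_vals.var(ddof=1)])))
        pool = np.concatenate([a_vals, b_vals])
        # one permutation per row: argsort of uniform noise
        perm = np.argsort(rng.random((n_perm, pool.size)), axis=1)
        shuffled = pool[perm]
        pa, pb = shuffled[:, : a_vals.size], shuffled[:, a_vals.size :]
        null_a.append((pa.mean(axis=1), pa.var(axis=1, ddof=1)))
        null_b.append((pb.mean(axis=1), pb.var(axis=1, ddof=1)))

    observed = float(rmse_from(obs_moments_a)[0] - rmse_from(obs_moments_b)[0])
    null = rmse_from(null_a) - rmse_from(null_b)
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return PermutationResult(observed=observed, p_value=float(p), n_perm=n_perm)


def normalized_rmse(
    observed: dict[str, SummaryStats], model_expected_123: SummaryStats
) -> dict[str, float]:
    """Observed RMSE of each condition divided by the model-expected 1-2-3-Go RMSE."""
    denom = model_expected_123.rmse
    if denom == 0.0:
        raise ValueError("model-expected RMSE is zero; ratios undefined")
    if model_expected_123.condition != Condition.ONE_TWO_THREE_GO.value:
        raise ValueError("normalizer must be the 1-2-3-Go model-expected statistics")
    return {cond: stats.rmse / denom for cond, stats in observed.items()}
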