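"""Synthetic sessions of the 1-2-Go / 1-2-3-Go interval reproduction task.

One trial is generated by (1) possibly lapsing (probability ``gamma``,
response uniform on the lapse range), otherwise (2) drawing one or two
noisy measurements with SD ``w * t_s``, (3) mapping them to an estimate
with the observer's estimator, and (4) drawing the produced interval from
a Gaussian centred at ``t_e + b`` with SD ``w_p * t_e`` (negative draws
are redrawn). The adaptive one-up/one-down correctness staircase tracks
feedback only; it never feeds back into the generative process, because
none of the observer models contain a feedback-dependent term.

All randomness flows through one injected ``numpy.random.Generator``:
identical seeds give byte-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from scipy.interpolate import RectBivariateSpline

from .models import Condition, Model, ObserverParams
from .observers import Bls1Table, bls1_map, bls2_map, blsmem_map
from .prior import DEFAULT_PRIOR, PriorSpec

__all__ = [
    "TrialRecord",
    "StaircaseState",
    "staircase_update",
    "simulate_trial",
    "simulate_session",
    "apply_exclusions",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "session", "index", "condition", "ts_ms", "tp_ms",
    "tm1_ms", "tm2_ms", "te_ms", "is_lapse", "correct", "threshold",
]


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial, with the simulator's latent variables."""

    session: str
    index: int
    condition: Condition
    ts_ms: float
    tp_ms: float
    tm1_ms: float | None = None
    tm2_ms: float | None = None
    te_ms: float | None = None
    is_lapse: bool | None = None
    correct: bool | None = None
    threshold: float | None = None


@dataclass(frozen=True)
class StaircaseState:
    """One-up/one-down threshold on the relative production error.

    ``k`` is the correctness threshold on ``|t_p - t_s| / t_s``; it moves
    down by ``step`` after a correct response and up after an incorrect
    one, equilibrating at 50% correct. Floored at ``step`` so it stays
    positive.
    """

    k: float = 0.15
    step: float = 0.001
    history: tuple[tuple[float, bool], ...] = field(default_factory=tuple)


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    delta = -state.step if correct else state.step
    return replace(
        state,
        k=max(state.step, state.k + delta),
        history=state.history + ((state.k, bool(correct)),),
    )


# ---------------------------------------------------------------------------
# generative core (vectorized over trials)
# ---------------------------------------------------------------------------

#: above this many trials the estimator maps are tabulated and
#: interpolated (sub-1e-3 ms error, far below production noise) instead
#: of evaluated by full quadrature per draw
_TABLE_THRESHOLD = 20_000


def _make_f1(w_m: float, prior: PriorSpec, lo: float, hi: float, tabulate: bool):
    if not tabulate:
        return lambda x: bls1_map(x, w_m, prior)
    return Bls1Table(w_m, prior, lo=lo - 2.0, hi=hi + 2.0, step=1.0)


def _make_f2(
    w1: float, w2: float, prior: PriorSpec, a: np.ndarray, b: np.ndarray,
    tabulate: bool,
):
    two = blsmem_map if w1 != w2 else None
    if not tabulate:
        if two is not None:
            return lambda x, y: blsmem_map(x, y, w1, w2, prior)
        return lambda x, y: bls2_map(x, y, w2, prior)
    ga = np.arange(np.floor(a.min()) - 4.0, a.max() + 8.0, 4.0)
    gb = np.arange(np.floor(b.min()) - 4.0, b.max() + 8.0, 4.0)
    if two is not None:
        vals = blsmem_map(ga[:, None], gb[None, :], w1, w2, prior)
    else:
        vals = bls2_map(ga[:, None], gb[None, :], w2, prior)
    spline = RectBivariateSpline(ga, gb, vals)
    return lambda x, y: spline(x, y, grid=False)


def _estimates_vec(
    tm1: np.ndarray,
    tm2: np.ndarray,
    two_meas: np.ndarray,
    params: ObserverParams,
    prior: PriorSpec,
) -> np.ndarray:
    """Model estimates for a batch of trials; ``tm2`` is ignored where ``~two_meas``."""
    te = np.empty_like(tm1)
    one = ~two_meas
    w = params.w_m
    tabulate = tm1.size >= _TABLE_THRESHOLD
    if np.any(one):
        x = tm1[one]
        te[one] = _make_f1(w, prior, x.min(), x.max(), tabulate)(x)
    if np.any(two_meas):
        a, b2 = tm1[two_meas], tm2[two_meas]
        if params.model in (Model.BLS, Model.BLS_MEM):
            w1 = params.w_first(2)
            te[two_meas] = _make_f2(w1, w, prior, a, b2, tabulate)(a, b2)
        elif params.model is Model.LNE:
            m = 0.5 * (a + b2)
            te[two_meas] = _make_f1(w, prior, m.min(), m.max(), tabulate)(m)
        else:  # EKF; the second gain is exactly 1/2 (see observers.ekf_update)
            te1 = _make_f1(w, prior, a.min(), a.max(), tabulate)(a)
            args = b2 - te1 + prior.mean
            f1b = _make_f1(w, prior, args.min(), args.max(), tabulate)
            te[two_meas] = te1 + 0.5 * (f1b(args) - prior.mean)
    return te


def _simulate_core(
    conditions: np.ndarray,
    ts: np.ndarray,
    params: ObserverParams,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    n = ts.size
    two_meas = conditions == Condition.ONE_TWO_THREE_GO.value
    is_lapse = rng.random(n) < params.gamma
    sd1 = np.where(
        two_meas & (params.model is Model.BLS_MEM), params.w_mem or np.nan, params.w_m
    ) * ts
    tm1 = rng.normal(ts, sd1)
    tm2 = np.where(two_meas, rng.normal(ts, params.w_m * ts), np.nan)
    te = _estimates_vec(tm1, np.nan_to_num(tm2, nan=0.0), two_meas, params, prior)
    tp = rng.normal(te + params.b, params.w_p * te)
    # anticipatory (negative) productions are not in the model: redraw
    bad = tp < 0
    while np.any(bad):
        tp[bad] = rng.normal(te[bad] + params.b, params.w_p * te[bad])
        bad = tp < 0
    lo, hi = params.lapse_range
    tp = np.where(is_lapse, rng.uniform(lo, hi, n), tp)
    return {
        "ts_ms": ts, "tp_ms": tp, "tm1_ms": tm1, "tm2_ms": tm2,
        "te_ms": te, "is_lapse": is_lapse,
    }


def simulate_trial(
    condition: Condition | str,
    t_s: float,
    params: ObserverParams,
    prior: PriorSpec,
    rng: np.random.Generator,
    session: str = "sim",
    index: int = 0,
) -> TrialRecord:
    """Generate a single trial, latents included."""
    cond = Condition.parse(condition)
    out = _simulate_core(
        np.array([cond.value]), np.array([float(t_s)]), params, prior, rng
    )
    tm2 = out["tm2_ms"][0]
    return TrialRecord(
        session=session,
        index=index,
        condition=cond,
        ts_ms=float(out["ts_ms"][0]),
        tp_ms=float(out["tp_ms"][0]),
        tm1_ms=float(out["tm1_ms"][0]),
        tm2_ms=None if np.isnan(tm2) else float(tm2),
        te_ms=float(out["te_ms"][0]),
        is_lapse=bool(out["is_lapse"][0]),
    )


def simulate_session(
    n_trials: int,
    params: ObserverParams,
    prior: PriorSpec = DEFAULT_PRIOR,
    rng: np.random.Generator | None = None,
    condition_mix: float = 0.5,
    with_staircase: bool = False,
    session: str = "S0",
    staircase_init: float = 0.15,
    staircase_step: float = 0.001,
) -> tuple[pd.DataFrame, StaircaseState | None]:
    """Simulate one session of randomly interleaved 1-2-Go / 1-2-3-Go trials.

    ``condition_mix`` is the fraction of 1-2-3-Go trials; ``t_s`` is drawn
    i.i.d. uniform from the discrete prior support. With the staircase
    enabled, correctness is ``|t_p - t_s| / t_s <= k`` (inclusive) and the
    threshold is updated after every trial.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0.0 <= condition_mix <= 1.0:
        raise ValueError("condition_mix must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    conds = np.where(
        rng.random(n_trials) < condition_mix,
        Condition.ONE_TWO_THREE_GO.value,
        Condition.ONE_TWO_GO.value,
    )
    ts = rng.choice(np.asarray(prior.support, dtype=float), size=n_trials)
    out = _simulate_core(conds, ts, params, prior, rng)
    frame = pd.DataFrame(
        {
            "session": session,
            "index": np.arange(n_trials),
            "condition": conds,
            **out,
        }
    )
    state: StaircaseState | None = None
    if with_staircase:
        state = StaircaseState(k=staircase_init, step=staircase_step)
        rel_err = np.abs(frame["tp_ms"].to_numpy() - ts) / ts
        thresholds = np.empty(n_trials)
        correct = np.empty(n_trials, dtype=bool)
        for i in range(n_trials):
            thresholds[i] = state.k
            correct[i] = rel_err[i] <= state.k
            state = staircase_update(state, correct[i])
        frame["correct"] = correct
        frame["threshold"] = thresholds
    else:
        frame["correct"] = pd.NA
        frame["threshold"] = np.nan
    return frame[TRIAL_COLUMNS], state


def apply_exclusions(
    trials: pd.DataFrame,
    warmup: int = 99,
    window_ms: float = 1000.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the standard trial-exclusion rules.

    Drops the first ``warmup`` trials of each session (adaptation to the
    prior), then any trial with a non-positive production (anticipatory
    response) or with ``t_p > t_s + window_ms`` (the window boundary is
    inclusive: ``t_p == t_s + window_ms`` survives). Returns the filtered
    table and the count removed by each rule.
    """
    counts = {"warmup": 0, "anticipatory": 0, "late": 0}
    kept = []
    for _, grp in trials.groupby("session", sort=False):
        order = grp.sort_values("index")
        counts["warmup"] += min(warmup, len(order))
        kept.append(order.iloc[warmup:])
    out = pd.concat(kept) if kept else trials.iloc[0:0]
    anticipatory = out["tp_ms"] <= 0
    counts["anticipatory"] = int(anticipatory.sum())
    out = out[~anticipatory]
    late = out["tp_ms"] > out["ts_ms"] + window_ms
    counts["late"] = int(late.sum())
    out = out[~late]
    return out.reset_index(drop=True), counts
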