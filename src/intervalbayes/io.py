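"""Trial-table readers/writers, run configuration, and result serialization."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitConfig, FitResult
from .likelihood import QuadratureConfig
from .models import Condition, Model, ObserverParams
from .prior import PriorSpec

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trials",
    "write_trials",
    "SimulateConfig",
    "RunConfig",
    "load_run_config",
    "fit_result_to_dict",
    "save_fit_result",
    "load_fit_result",
]

REQUIRED_COLUMNS = ["session", "index", "condition", "ts_ms", "tp_ms"]
_FLOAT_DIGITS = 9  # significant digits for parameters in JSON


def read_trials(
    path, dialect: str | None = None, prior: PriorSpec | None = None
) -> pd.DataFrame:
    """Read a CSV/TSV trial table and validate it.

    Requires the columns ``session, index, condition, ts_ms, tp_ms``;
    extra columns pass through. Condition tokens ``12G``/``123G`` are
    accepted case-insensitively. Malformed numeric rows are reported with
    their line numbers. If a ``prior`` is given, sample intervals off its
    discrete support are accepted with a warning (real data may differ
    from the default task configuration).
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning an empty trial table")
        return pd.DataFrame(columns=REQUIRED_COLUMNS)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s): {missing}")
    for col in ("ts_ms", "tp_ms"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            lines = (frame.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"non-numeric {col} at line(s) {lines} of {path}")
        frame[col] = coerced
    frame["condition"] = frame["condition"].map(lambda c: Condition.parse(c).value)
    if frame.empty:
        warnings.warn(f"{path} contains no trials")
    elif prior is not None:
        off = sorted(set(frame["ts_ms"].unique()) - set(prior.support))
        if off:
            warnings.warn(
                f"{path} contains sample intervals off the prior support: {off}"
            )
    return frame


def write_trials(trials: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    trials.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class SimulateConfig:
    """Generator settings of one synthetic run."""

    n_trials: int = 1000
    condition_mix: float = 0.5
    params: ObserverParams = field(
        default_factory=lambda: ObserverParams(Model.BLS, w_m=0.1, w_p=0.08)
    )
    with_staircase: bool = True
    session: str = "S0"


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs; fully serializable."""

    prior: PriorSpec = field(default_factory=PriorSpec)
    quad: QuadratureConfig = field(default_factory=QuadratureConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulate"]["params"]["model"] = self.simulate.params.model.value
        return out


def _params_from_dict(d: dict) -> ObserverParams:
    d = dict(d)
    model = Model.parse(d.pop("model"))
    if "lapse_range" in d:
        d["lapse_range"] = tuple(d["lapse_range"])
    return ObserverParams(model=model, **d)


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration; omitted sections keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw: dict = {}
    if "prior" in raw:
        p = dict(raw["prior"])
        if "support" in p:
            p["support"] = tuple(p["support"])
        kw["prior"] = PriorSpec(**p)
    if "quad" in raw:
        kw["quad"] = QuadratureConfig(**raw["quad"])
    if "fit" in raw:
        f = dict(raw["fit"])
        if "bounds" in f:
            f["bounds"] = {k: tuple(v) for k, v in f["bounds"].items()}
        kw["fit"] = FitConfig(**f)
    if "simulate" in raw:
        s = dict(raw["simulate"])
        if "params" in s:
            s["params"] = _params_from_dict(s["params"])
        kw["simulate"] = SimulateConfig(**s)
    for key in ("seed", "log_level"):
        if key in raw:
            kw[key] = raw[key]
    return RunConfig(**kw)


def _round_sig(x: float) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{_FLOAT_DIGITS}g}")


def _params_to_dict(p: ObserverParams) -> dict:
    out = {
        "model": p.model.value,
        "w_m": _round_sig(p.w_m),
        "w_p": _round_sig(p.w_p),
        "b": _round_sig(p.b),
        "gamma": _round_sig(p.gamma),
        "lapse_range": list(p.lapse_range),
    }
    if p.w_mem is not None:
        out["w_mem"] = _round_sig(p.w_mem)
    return out


def fit_result_to_dict(result: FitResult, seed: int | None = None) -> dict:
    out = {
        "model": result.model.value,
        "n_trials": result.n_trials,
        "averaged_params": _params_to_dict(result.averaged_params),
        "per_fold_params": [_params_to_dict(p) for p in result.per_fold_params],
        "per_fold_test_loglik": [float(v) for v in result.per_fold_test_loglik],
        "per_fold_train_loglik": [float(v) for v in result.per_fold_train_loglik],
        "fold_test_indices": [idx.tolist() for idx in result.fold_test_indices],
    }
    if seed is not None:
        out["seed"] = seed
    return out


def save_fit_result(result: FitResult, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(result, seed), fh, indent=2)


def load_fit_result(path) -> FitResult:
    with open(path) as fh:
        raw = json.load(fh)
    return FitResult(
        model=Model.parse(raw["model"]),
        per_fold_params=[_params_from_dict(d) for d in raw["per_fold_params"]],
        averaged_params=_params_from_dict(raw["averaged_params"]),
        per_fold_test_loglik=raw["per_fold_test_loglik"],
        per_fold_train_loglik=raw["per_fold_train_loglik"],
        fold_test_indices=[np.asarray(i) for i in raw["fold_test_indices"]],
        n_trials=raw["n_trials"],
    )
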