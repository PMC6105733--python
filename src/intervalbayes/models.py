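"""Observer-model identities and their parameter vectors."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum

__all__ = ["Model", "Condition", "ObserverParams"]


class Condition(str, Enum):
    """Trial type: one or two presentations of the sample interval."""

    ONE_TWO_GO = "12G"
    ONE_TWO_THREE_GO = "123G"

    @property
    def n_meas(self) -> int:
        return 1 if self is Condition.ONE_TWO_GO else 2

    @classmethod
    def parse(cls, token) -> "Condition":
        if isinstance(token, cls):
            return token
        t = str(token).strip().upper()
        for cond in cls:
            if t == cond.value.upper():
                return cond
        raise ValueError(f"unknown condition {token!r}; expected '12G' or '123G'")


class Model(str, Enum):
    """The four sequential-inference observer models.

    BLS
        Bayes least-squares: posterior mean under the scalar-noise
        likelihood, optimal for one or two measurements.
    BLS_MEM
        BLS with a distinct Weber fraction (``w_mem``) on the first
        measurement of a two-measurement trial (memory degradation or
        attentional differences between the two measurements).
    LNE
        Linear-nonlinear estimator: running average of the measurements
        passed through the single-measurement BLS nonlinearity.
    EKF
        Extended-Kalman-filter-style updater: a gain-scaled nonlinear
        function of the prediction error is added to the running estimate.
    """

    BLS = "bls"
    BLS_MEM = "blsmem"
    LNE = "lne"
    EKF = "ekf"

    @classmethod
    def parse(cls, token) -> "Model":
        if isinstance(token, cls):
            return token
        try:
            return cls(str(token).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown model {token!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class ObserverParams:
    """Parameter vector Theta of an observer model.

    Parameters
    ----------
    model
        Which estimator maps measurements to an interval estimate.
    w_m
        Weber fraction of the measurement noise (SD = ``w_m * t_s``).
    w_p
        Weber fraction of the production noise (SD = ``w_p * t_e``).
    b
        Constant production offset in ms; shifts the mean of the produced
        interval but not its SD.
    gamma
        Lapse probability: with probability ``gamma`` the response is
        drawn uniformly on ``lapse_range`` regardless of the stimulus.
    w_mem
        Weber fraction of the first measurement on two-measurement trials
        (BLS_MEM only; must be None for the other models).
    lapse_range
        Support of the lapse distribution in ms, default (0, 2000): the
        physically possible production window.
    """

    model: Model
    w_m: float
    w_p: float
    b: float = 0.0
    gamma: float = 0.0
    w_mem: float | None = None
    lapse_range: tuple[float, float] = (0.0, 2000.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))
        if not self.w_m > 0:
            raise ValueError(f"w_m must be > 0, got {self.w_m}")
        if not self.w_p > 0:
            raise ValueError(f"w_p must be > 0, got {self.w_p}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.model is Model.BLS_MEM:
            if self.w_mem is None or not self.w_mem > 0:
                raise ValueError("BLS_MEM requires w_mem > 0")
        elif self.w_mem is not None:
            raise ValueError(f"w_mem is only meaningful for BLS_MEM, not {self.model}")
        lo, hi = self.lapse_range
        if not (0.0 <= lo < hi):
            raise ValueError(f"lapse_range must satisfy 0 <= lo < hi, got {self.lapse_range}")
        object.__setattr__(self, "lapse_range", (float(lo), float(hi)))

    @property
    def lapse_width(self) -> float:
        return self.lapse_range[1] - self.lapse_range[0]

    def replace(self, **changes) -> "ObserverParams":
        return dataclasses.replace(self, **changes)

    def w_first(self, n_meas: int) -> float:
        """Weber fraction of the first measurement for an n-measurement trial."""
        if n_meas >= 2 and self.model is Model.BLS_MEM:
            return float(self.w_mem)
        return self.w_m
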