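"""Sample-interval prior for the 1-2-Go / 1-2-3-Go task.

The estimator integrals use a continuous uniform prior on [t_min, t_max];
the task itself draws ``t_s`` from a small discrete support inside that
range. Both views live on one object so that simulation and inference
cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PriorSpec", "DEFAULT_PRIOR"]


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior over sample intervals, in milliseconds.

    Parameters
    ----------
    t_min, t_max
        Bounds of the continuous uniform prior used by the estimators.
    support
        Discrete values of ``t_s`` actually presented by the task.
        Every value must lie in ``[t_min, t_max]``.
    """

    t_min: float = 600.0
    t_max: float = 1000.0
    support: tuple[float, ...] = (600.0, 700.0, 800.0, 900.0, 1000.0)

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(f"t_min must be < t_max, got [{self.t_min}, {self.t_max}]")
        if self.t_min <= 0:
            raise ValueError("t_min must be positive (durations in ms)")
        if len(self.support) == 0:
            raise ValueError("support must be non-empty")
        sup = np.asarray(self.support, dtype=float)
        if np.any(sup < self.t_min) or np.any(sup > self.t_max):
            raise ValueError("every support value must lie in [t_min, t_max]")
        object.__setattr__(self, "support", tuple(float(v) for v in sup))

    @property
    def mean(self) -> float:
        """Mean of the continuous uniform prior (EKF initial estimate)."""
        return 0.5 * (self.t_min + self.t_max)

    @property
    def width(self) -> float:
        return self.t_max - self.t_min

    def pdf(self, t_s) -> np.ndarray:
        """Density of the continuous uniform prior, per ms."""
        t_s = np.asarray(t_s, dtype=float)
        inside = (t_s >= self.t_min) & (t_s <= self.t_max)
        return np.where(inside, 1.0 / self.width, 0.0)


DEFAULT_PRIOR = PriorSpec()
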