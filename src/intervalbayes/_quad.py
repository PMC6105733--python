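"""Composite Simpson nodes/weights on a uniform grid."""

from __future__ import annotations

import numpy as np


def simpson_nodes(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights of composite Simpson's rule with ``n`` nodes.

    ``n`` must be odd and >= 3 (an even number of equal sub-intervals).
    The weights ``w`` satisfy ``w @ f(x) ~= integral_a^b f``.
    """
    if n < 3 or n % 2 == 0:
        raise ValueError(f"Simpson's rule needs an odd node count >= 3, got {n}")
    x = np.linspace(a, b, n)
    h = (b - a) / (n - 1)
    w = np.full(n, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    w *= h / 3.0
    return x, w
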