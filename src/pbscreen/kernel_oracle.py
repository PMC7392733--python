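"""Reference implementations used as oracles for the fast engines.

Deliberately naive and independent of :mod:`pbscreen._kernels`: the density
is an explicit outer-difference double loop in numpy, with no truncation, no
windowing and no single-precision shortcuts.
"""
from __future__ import annotations

import numpy as np


def brute_force_density(positions, h: float, eval_points) -> np.ndarray:
    """Direct O(n*m) evaluation of ``f(x) = sum_i exp(-(x - x_i)^2 / 2h^2)``."""
    pos = np.asarray(positions, dtype=np.float64)
    ev = np.asarray(eval_points, dtype=np.float64)
    d = ev[:, None] - pos[None, :]
    return np.exp(-(d * d) / (2.0 * float(h) ** 2)).sum(axis=1)
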