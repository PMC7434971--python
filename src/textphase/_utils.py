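"""Small shared helpers."""
from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def as_1d_float(x, name: str = "series") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr
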