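"""Per-document affective charge: Euclidean distance from the origin of
the squared-cosine factor space, and classification against the centroid
radius (the mean distance).  Documents whose distance exceeds the mean
are "outside" (label 2); ties and smaller values are "inside" (label 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._utils import as_1d_float

__all__ = ["INSIDE", "OUTSIDE", "ChargeSeries", "euclidean_charge",
           "centroid_classify"]

log = logging.getLogger(__name__)

INSIDE = 1
OUTSIDE = 2


@dataclass(frozen=True)
class ChargeSeries:
    """Euclidean-distance series with centroid classification."""

    ed: np.ndarray
    centroid_radius: float
    labels: np.ndarray  # INSIDE (1) / OUTSIDE (2)
    time_index: np.ndarray  # 1..N

    @property
    def n(self) -> int:
        return len(self.ed)

    @property
    def n_inside(self) -> int:
        return int(np.sum(self.labels == INSIDE))

    @property
    def n_outside(self) -> int:
        return int(np.sum(self.labels == OUTSIDE))

    @property
    def pct_inside(self) -> float:
        return 100.0 * self.n_inside / self.n

    @property
    def pct_outside(self) -> float:
        return 100.0 * self.n_outside / self.n

    def summary(self) -> dict:
        return {
            "n": self.n,
            "centroid_radius": self.centroid_radius,
            "n_inside": self.n_inside,
            "n_outside": self.n_outside,
            "pct_inside": round(self.pct_inside, 1),
            "pct_outside": round(self.pct_outside, 1),
        }


def euclidean_charge(vectors) -> np.ndarray:
    """Euclidean norm of each row of a squared-cosine matrix.

    ``ed_i = sqrt(sum_k v_ik**2)``; components must lie in [0, 1].
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("squared-cosine components must lie in [0, 1]")
    return np.linalg.norm(v, axis=1)


def centroid_classify(ed) -> ChargeSeries:
    """Classify each distance against the mean distance (centroid radius).

    A value strictly greater than the mean is OUTSIDE (2), otherwise
    INSIDE (1).  A constant series yields all-inside with a warning.
    """
    x = as_1d_float(ed, "ed")
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    if np.any(x < 0):
        raise ValueError("distances must be non-negative")
    radius = float(x.mean())
    labels = np.where(x > radius, OUTSIDE, INSIDE)
    if np.all(x == x[0]):
        log.warning("all distances identical; centroid threshold degenerate, "
                    "every document labelled inside")
    return ChargeSeries(x, radius, labels, np.arange(1, len(x) + 1))
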