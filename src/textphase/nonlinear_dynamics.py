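"""Windowed dynamic complexity, recurrence-distance matrices, and the
Stockwell time-frequency transform.

Dynamic complexity of a window of ``m`` points on a value scale
``[scale_min, scale_max]`` (width ``s``) is ``C = F * D`` with

* fluctuation ``F``: the summed absolute excursions between successive
  direction-change points (window endpoints plus every local extremum),
  normalised by the maximal possible per-step excursion ``s * (m - 1)``.
  Between consecutive direction-change points the window is monotone, so
  this sum equals the total variation of the window.
* distribution ``D``: one minus the normalised shortfall of the sorted
  window values against an ideally uniform spread over the scale:
  ``D = 1 - sum_{i<j} max(0, (j-i)*I - (y_(j) - y_(i))) / sum_{i<j} (j-i)*I``
  with ideal gap ``I = s/(m-1)``.

Both measures live in [0, 1]; a constant window scores 0 on both.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist, squareform

from ._utils import as_1d_float

__all__ = [
    "DCProfile",
    "RecurrenceMatrix",
    "TFDMatrix",
    "dynamic_complexity",
    "recurrence_matrix",
    "stockwell_transform",
    "stockwell_tfd",
]


@dataclass(frozen=True)
class DCProfile:
    """Windowed dynamic-complexity profile, aligned to the window end.

    Profile position ``j`` (0-based) summarises original samples
    ``j .. j + window_width - 1``; :meth:`to_series_index` maps a 1-based
    profile index to the 1-based original-series index of its window end.
    """

    window_width: int
    scale_min: float
    scale_max: float
    fluctuation: np.ndarray
    distribution: np.ndarray
    complexity: np.ndarray

    def __len__(self) -> int:
        return len(self.complexity)

    def to_series_index(self, profile_index: int) -> int:
        """Map a 1-based profile index to its window-end series index."""
        return profile_index + self.window_width - 1


def _distribution_measure(windows: np.ndarray, s: float) -> np.ndarray:
    """Vectorised D over rows of ``windows`` (each row one window)."""
    m = windows.shape[1]
    ideal_gap = s / (m - 1)
    y = np.sort(windows, axis=1)
    # pairwise differences y_(j) - y_(i) and ideal gaps (j-i)*I for i<j
    iu, ju = np.triu_indices(m, k=1)
    diffs = y[:, ju] - y[:, iu]
    ideal = (ju - iu) * ideal_gap
    shortfall = np.clip(ideal - diffs, 0.0, None).sum(axis=1)
    return 1.0 - shortfall / ideal.sum()


def dynamic_complexity(
    series,
    window: int = 7,
    scale: tuple[float, float] | None = None,
) -> DCProfile:
    """Moving-window dynamic complexity (fluctuation x distribution).

    Parameters
    ----------
    series
        Ordered observations, length >= ``window``.
    window
        Window width (>= 4); the window slides by one step.
    scale
        ``(scale_min, scale_max)`` of theoretically possible values.
        ``None`` uses the observed min/max of the full series.

    Returns
    -------
    DCProfile
        Per-window F, D and C = F*D, length ``N - window + 1``.
    """
    x = as_1d_float(series)
    n = len(x)
    if window < 4:
        raise ValueError(f"window must be >= 4, got {window}")
    if n < window:
        raise ValueError(f"series of length {n} shorter than window {window}")
    if scale is None:
        scale = (float(x.min()), float(x.max()))
    lo, hi = map(float, scale)
    s = hi - lo
    if s <= 0:
        # constant series under an observed scale: everything is zero
        if np.all(x == x[0]):
            z = np.zeros(n - window + 1)
            return DCProfile(window, lo, hi, z.copy(), z.copy(), z.copy())
        raise ValueError("scale_max must exceed scale_min")
    bad = np.flatnonzero((x < lo) | (x > hi))
    if bad.size:
        raise ValueError(
            f"value at index {int(bad[0])} ({x[bad[0]]!r}) outside scale [{lo}, {hi}]"
        )

    w = sliding_window_view(x, window)
    # total variation == summed excursions between direction-change points
    fluct = np.abs(np.diff(w, axis=1)).sum(axis=1) / (s * (window - 1))
    dist = _distribution_measure(w, s)
    return DCProfile(window, lo, hi, fluct, dist, fluct * dist)


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Unthresholded recurrence plot: pairwise distances of delay vectors.

    ``dist[s, t]`` is the Euclidean distance between the embedded snippets
    starting at series positions ``s`` and ``t`` (0-based); a snippet at
    position ``t`` spans ``x[t], x[t+tau], ..., x[t+(m-1)*tau]``.
    """

    m: int
    tau: int
    dist: np.ndarray

    @property
    def n_vectors(self) -> int:
        return self.dist.shape[0]


def recurrence_matrix(series, m: int = 3, tau: int = 1) -> RecurrenceMatrix:
    """Distance matrix between time-delay embedded snippets of a series."""
    x = as_1d_float(series)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be positive")
    span = (m - 1) * tau
    if len(x) < span + 2:
        raise ValueError(
            f"series of length {len(x)} too short for m={m}, tau={tau}"
        )
    emb = sliding_window_view(x, span + 1)[:, ::tau]  # (N - span) x m
    dist = squareform(pdist(emb, metric="euclidean"))
    return RecurrenceMatrix(m, tau, dist)


@dataclass(frozen=True)
class TFDMatrix:
    """Amplitude of the Stockwell transform over frequency bins x time."""

    amplitude: np.ndarray  # (N//2 + 1) x N, non-negative

    @property
    def n_freqs(self) -> int:
        return self.amplitude.shape[0]


def stockwell_transform(series) -> np.ndarray:
    """Complex discrete S-transform of a real series.

    Frequency-domain (voice) implementation: for positive frequency bin
    ``f`` the voice is the spectrum shifted by ``f`` and windowed with a
    Gaussian ``exp(-2 pi^2 m^2 / f^2)``, transformed back to time.  The
    zero-frequency voice is the signal mean at every time position.

    Uses the DFT normalised by ``N`` so that the time average of the
    transform at bin ``f`` equals ``fft(x)[f] / N`` exactly.

    Returns
    -------
    ndarray of complex, shape ``(N//2 + 1, N)``.
    """
    x = as_1d_float(series)
    n = len(x)
    if n < 8:
        raise ValueError(f"need at least 8 samples, got {n}")
    spec = np.fft.fft(x) / n
    n_f = n // 2 + 1
    out = np.empty((n_f, n), dtype=complex)
    out[0] = x.mean()
    mvals = np.arange(n)
    mvals = np.where(mvals > n // 2, mvals - n, mvals)  # centred shifts
    for f in range(1, n_f):
        voice = spec[(mvals + f) % n] * np.exp(-2.0 * np.pi**2 * mvals**2 / f**2)
        out[f] = np.fft.ifft(voice) * n
    return out


def stockwell_tfd(series, remove_mean: bool = False) -> TFDMatrix:
    """Amplitude time-frequency distribution via the S-transform.

    ``remove_mean=True`` subtracts the series mean first (display variant,
    suppressing the dominant zero-frequency voice).
    """
    x = as_1d_float(series)
    if remove_mean:
        x = x - x.mean()
    return TFDMatrix(np.abs(stockwell_transform(x)))
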