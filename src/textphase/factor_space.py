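"""Correspondence analysis of a binary document x lemma matrix.

Simple CA of the indicator matrix: with correspondence matrix
``P = X / X.sum()``, row masses ``r`` and column masses ``c``, the
standardised residual matrix

    S = diag(r)^(-1/2) (P - r c^T) diag(c)^(-1/2)

is decomposed by SVD.  Eigenvalues (principal inertias) are the squared
singular values; row principal coordinates are
``diag(r)^(-1/2) U diag(sigma)``.  A row's squared cosine on an axis is
its squared principal coordinate divided by its squared chi-square
distance to the centroid, so the squared cosines of a row sum to one
over all axes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError

__all__ = ["FactorSpace", "fit_correspondence", "dream_vectors"]

log = logging.getLogger(__name__)

_SV_TOL = 1e-10  # relative cutoff for structural (zero) singular values


@dataclass(frozen=True)
class FactorSpace:
    """Row geometry of a fitted correspondence analysis.

    Attributes
    ----------
    row_coords
        N x R row principal coordinates (excluded rows are zero-filled).
    sq_cos
        N x R squared cosines; rows with a nonzero profile sum to 1
        across all R axes.
    eigenvalues
        Principal inertias, non-increasing.
    explained_pct
        Percent of total inertia per axis (sums to 100).
    K
        Number of axes retained for downstream use.
    excluded_rows
        0-based indices of all-zero rows that were excluded from the fit
        and carry placeholder zero vectors.
    """

    row_coords: np.ndarray
    sq_cos: np.ndarray
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    K: int
    excluded_rows: tuple[int, ...] = ()

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def _as_array(matrix) -> np.ndarray:
    X = getattr(matrix, "values", matrix)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    if np.any(X < 0):
        raise ValueError("matrix entries must be non-negative")
    return X


def fit_correspondence(matrix, K: int = 10) -> FactorSpace:
    """Fit a simple correspondence analysis to a non-negative matrix.

    Parameters
    ----------
    matrix
        Documents x lemmas indicator matrix (anything array-like,
        including a :class:`~textphase.corpus_prep.LemmaMatrix` or a
        pandas DataFrame).  All-zero rows are excluded from the fit and
        reported; all-zero columns are dropped.
    K
        Number of axes to mark for downstream use (clamped with a
        warning if fewer axes exist).

    Raises
    ------
    DegenerateInputError
        If total inertia is zero (all row profiles identical).
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    X = _as_array(matrix)
    n_rows = X.shape[0]

    row_ok = X.sum(axis=1) > 0
    excluded = tuple(int(i) for i in np.flatnonzero(~row_ok))
    if excluded:
        log.warning("excluding %d all-zero row(s) from CA: %s",
                    len(excluded), excluded)
    col_ok = X.sum(axis=0) > 0
    X = X[np.ix_(row_ok, col_ok)]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 non-zero rows and columns")

    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    keep = sv > _SV_TOL * max(sv[0], 1.0)
    if not np.any(keep):
        raise DegenerateInputError("degenerate matrix: total inertia is zero")
    U, sv = U[:, keep], sv[keep]

    eig = sv**2
    explained = eig / eig.sum() * 100.0
    coords = U * sv / np.sqrt(r)[:, None]
    d2 = (coords**2).sum(axis=1)  # squared chi-square distance to centroid
    with np.errstate(invalid="ignore", divide="ignore"):
        sqcos = np.where(d2[:, None] > 0, coords**2 / d2[:, None], 0.0)

    R = len(eig)
    if K > R:
        log.warning("K=%d exceeds available axes (%d); clamped", K, R)
        K = R

    full_coords = np.zeros((n_rows, R))
    full_sqcos = np.zeros((n_rows, R))
    full_coords[row_ok] = coords
    full_sqcos[row_ok] = sqcos
    return FactorSpace(full_coords, full_sqcos, eig, explained, K, excluded)


def dream_vectors(space: FactorSpace, K: int | None = None) -> np.ndarray:
    """Squared-cosine vectors on the first ``K`` retained axes.

    Row order equals document order; ``K`` defaults to ``space.K``.
    """
    k = space.K if K is None else K
    if k < 1 or k > space.n_axes:
        raise ValueError(f"K must be in [1, {space.n_axes}]")
    return space.sq_cos[:, :k]
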