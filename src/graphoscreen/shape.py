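"""Landmark selection, matching, and Procrustes shape distance.

Landmarks are the strict local extrema of a periodic curve, taken as 2-D
points in the time-value plane.  Two curves are compared by selecting the N
extrema furthest from the time axis on each, pairing them either by value
order (distance from the axis) or by time order, and computing the full
Procrustes disparity: both point sets are centred, scaled to unit norm, and
optimally aligned by an orthogonal map (rotation, reflection permitted)
with optimal isotropic scaling; the residual sum of squares is the
distance.  With the optimal scale s* = sum of the singular values of the
cross-covariance, the disparity is 1 - s*^2, identical to the classical
full-Procrustes statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import PeriodicCurve
from .errors import (DegenerateShapeError, InsufficientLandmarksError,
                     InvalidInputError)

MATCHING_SCHEMES = ("value_order", "time_order")


@dataclass
class LandmarkSet:
    """N (time, value) extremum points, stored in descending-|value| order
    (ties broken by earlier time)."""

    points: np.ndarray  # (N, 2)
    source: tuple = ("curve",)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidInputError("landmarks must be an (N, 2) array")
        if self.points.shape[0] < 2:
            raise InvalidInputError("need at least 2 landmarks")

    @property
    def n(self) -> int:
        return self.points.shape[0]


def find_extrema(curve: PeriodicCurve) -> list[tuple[float, float]]:
    """Interior grid points where the discrete difference changes sign,
    ordered by time.  A plateau contributes a single extremum at its
    midpoint; endpoints are never extrema; a monotone curve yields []."""
    t, v = curve.grid, curve.values
    if t.shape[0] < 3:
        raise InvalidInputError("curve must have at least 3 points")
    d = np.diff(v)
    nz = np.flatnonzero(d != 0)
    if nz.size < 2:
        return []
    signs = np.sign(d[nz])
    out = []
    for k in np.flatnonzero(signs[:-1] != signs[1:]):
        i, j = nz[k], nz[k + 1]  # plateau spans grid indices i+1 .. j
        tm = 0.5 * (t[i + 1] + t[j])
        out.append((float(tm), float(v[i + 1])))
    return out


def _landmark_order(points: np.ndarray) -> np.ndarray:
    """Sort order: |value| descending, ties by time ascending."""
    return np.lexsort((points[:, 0], -np.abs(points[:, 1])))


def select_landmarks(extrema: list[tuple[float, float]], n: int,
                     source: tuple = ("curve",)) -> LandmarkSet:
    """Keep the n extrema furthest from the time axis (largest |value|)."""
    if n < 2:
        raise InvalidInputError("n must be >= 2")
    if len(extrema) < n:
        raise InsufficientLandmarksError(
            f"{len(extrema)} extrema available, {n} requested")
    pts = np.asarray(extrema, dtype=float)
    return LandmarkSet(pts[_landmark_order(pts)][:n], source=source)


def match_landmarks(a: LandmarkSet, b: LandmarkSet, scheme: str
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pair two equal-size landmark sets positionally after ordering both
    by the scheme's key (|value| or time)."""
    if a.n != b.n:
        raise InvalidInputError("landmark sets must have the same size")
    if scheme == "value_order":
        pa = a.points[_landmark_order(a.points)]
        pb = b.points[_landmark_order(b.points)]
    elif scheme == "time_order":
        pa = a.points[np.lexsort((a.points[:, 1], a.points[:, 0]))]
        pb = b.points[np.lexsort((b.points[:, 1], b.points[:, 0]))]
    else:
        raise InvalidInputError(f"unknown matching scheme {scheme!r}")
    return pa, pb


def _standardize(pts: np.ndarray) -> np.ndarray:
    c = pts - pts.mean(axis=0)
    norm = np.sqrt(np.sum(c * c))
    if norm == 0:
        raise DegenerateShapeError("zero-variance landmark set")
    return c / norm


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes disparity between two matched 2-D point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
        raise InvalidInputError("inputs must be matched (N, 2) arrays, N >= 2")
    sa = _standardize(a)
    sb = _standardize(b)
    sv = np.linalg.svd(sa.T @ sb, compute_uv=False)
    return float(max(1.0 - sv.sum() ** 2, 0.0))


def procrustes_distance_batch(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Disparity of each point set in ``A`` (B, N, 2) against ``b`` (N, 2).

    Degenerate (zero-variance) or NaN-containing members yield NaN.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    cb = b - b.mean(axis=0)
    nb = np.sqrt(np.sum(cb * cb))
    if nb == 0:
        raise DegenerateShapeError("zero-variance reference landmark set")
    sb = cb / nb
    cA = A - A.mean(axis=1, keepdims=True)
    nA = np.sqrt(np.sum(cA * cA, axis=(1, 2)))
    ok = np.isfinite(nA) & (nA > 0)
    out = np.full(A.shape[0], np.nan)
    if ok.any():
        sA = cA[ok] / nA[ok, None, None]
        M = np.einsum("bnj,nk->bjk", sA, sb)
        sv = np.linalg.svd(M, compute_uv=False)
        out[ok] = np.maximum(1.0 - sv.sum(axis=1) ** 2, 0.0)
    return out
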