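"""Recombining learned sinusoids into representative periodic curves.

Two aggregation configurations are supported:

* ``abs_weighted_mean`` — average of the s sinusoids weighted by the
  absolute decoder weights (weights normalised to sum to one, so the
  combination is bounded in [-1, 1]);
* ``weighted_sum`` — sum of the sinusoids weighted by the signed decoder
  weights (unbounded).

The linear Time2Vec term never enters these curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddedSignal
from .errors import DegenerateWeightsError, InvalidInputError

AGGREGATION_MODES = ("abs_weighted_mean", "weighted_sum")
#: default evaluation grid: fine enough to resolve extrema of band-limited
#: combinations (pulsations up to ~2*pi*8 rad per unit)
DEFAULT_CURVE_GRID = 501


def curve_grid(n: int = DEFAULT_CURVE_GRID) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


@dataclass
class PeriodicCurve:
    """A combined-sinusoid curve sampled on a grid over [0, 1]."""

    grid: np.ndarray
    values: np.ndarray
    provenance: tuple  # (child or "average", id_label, feature, mode)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise InvalidInputError("grid and values must be aligned")
        if np.any(np.diff(self.grid) <= 0):
            raise InvalidInputError("grid must be strictly increasing")


def _combination_weights(p: np.ndarray, mode: str) -> np.ndarray:
    if mode == "abs_weighted_mean":
        total = np.sum(np.abs(p))
        if total == 0:
            raise DegenerateWeightsError("all decoder weights are zero")
        return np.abs(p) / total
    if mode == "weighted_sum":
        return p
    raise InvalidInputError(f"unknown aggregation mode {mode!r}")


def combine_sinusoids(emb: EmbeddedSignal, mode: str,
                      grid: np.ndarray | None = None,
                      provenance: tuple | None = None) -> PeriodicCurve:
    """Evaluate the weighted sinusoid combination of an embedding on a grid."""
    if grid is None:
        grid = curve_grid()
    w = _combination_weights(emb.p, mode)
    values = np.sin(np.outer(grid, emb.omega) + emb.phi) @ w
    return PeriodicCurve(grid, values,
                         provenance or ("signal", None, None, mode))


def combine_sinusoids_batch(omega: np.ndarray, phi: np.ndarray, p: np.ndarray,
                            mode: str, grid: np.ndarray | None = None
                            ) -> np.ndarray:
    """Vectorised combination for stacked embeddings.

    ``omega``, ``phi``, ``p`` have shape (..., s); returns (..., len(grid)).
    Rows with all-zero p under ``abs_weighted_mean`` yield NaN curves rather
    than raising (callers mask them).
    """
    if grid is None:
        grid = curve_grid()
    if mode == "abs_weighted_mean":
        total = np.sum(np.abs(p), axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(total > 0, np.abs(p) / total, np.nan)
    elif mode == "weighted_sum":
        w = p
    else:
        raise InvalidInputError(f"unknown aggregation mode {mode!r}")
    # (..., s, G)
    phases = omega[..., :, None] * grid + phi[..., :, None]
    return np.einsum("...sg,...s->...g", np.sin(phases), w)


def average_curve(curves: list[PeriodicCurve]) -> PeriodicCurve:
    """Pointwise mean of curves sharing a grid and (ID, feature, mode)."""
    if not curves:
        raise InvalidInputError("no curves to average")
    g0 = curves[0].grid
    for c in curves[1:]:
        if c.grid.shape != g0.shape or not np.allclose(c.grid, g0):
            raise InvalidInputError("curves must share the same grid")
    tails = {c.provenance[1:] for c in curves}
    if len(tails) > 1:
        raise InvalidInputError("curves must share (ID, feature, mode) provenance")
    values = np.mean([c.values for c in curves], axis=0)
    return PeriodicCurve(g0.copy(), values, ("average",) + curves[0].provenance[1:])
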