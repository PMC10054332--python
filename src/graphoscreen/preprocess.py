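"""Session cleaning: resampling, truncation, normalisation, ID grouping.

The raw 240 Hz stylus streams are linearly resampled onto a uniform 50 Hz
grid, clipped by 5% at each end to remove border effects, position-zeroed at
the first sample and put on a common [0, 1] time axis.  Executions of the
same difficulty group (ID) are then averaged on a shared grid into one
representative series per (child, time-point, game, ID).
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from .errors import DegenerateSeriesError, InvalidInputError
from .sessions import CleanSeries, RawSession

DEFAULT_TARGET_HZ = 50.0
DEFAULT_TRUNCATE_FRAC = 0.05
#: length of the common averaging grid on [0, 1]
DEFAULT_GRID_POINTS = 101


def resample(session: RawSession, target_hz: float = DEFAULT_TARGET_HZ) -> RawSession:
    """Linearly interpolate all channels onto a uniform grid at ``target_hz``.

    The grid starts at the first timestamp and steps by 1/target_hz up to
    the last timestamp inclusive (floor(span*hz) + 1 points).
    """
    t = session.t
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("timestamps must be strictly increasing")
    if target_hz <= 0:
        raise InvalidInputError("target_hz must be positive")
    span = t[-1] - t[0]
    n_out = int(math.floor(span * target_hz + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / target_hz
    out = np.empty((n_out, 6))
    out[:, 0] = grid
    for c in range(1, 6):
        out[:, c] = np.interp(grid, t, session.samples[:, c])
    res = session.with_samples(out)
    res.rate_hz = float(target_hz)
    return res


def truncate_ends(obj: RawSession | CleanSeries, frac: float = DEFAULT_TRUNCATE_FRAC):
    """Drop floor(frac * length) samples from each end of a session or series."""
    if not 0 <= frac < 0.5:
        raise InvalidInputError("frac must be in [0, 0.5)")
    n = obj.n_samples
    k = int(math.floor(frac * n))
    if n - 2 * k < 2:
        raise DegenerateSeriesError(f"truncation leaves {n - 2 * k} samples")
    if k == 0:
        return obj
    sl = slice(k, n - k)
    if isinstance(obj, RawSession):
        return obj.with_samples(obj.samples[sl])
    return CleanSeries(obj.child_id, obj.time_point, obj.game, obj.id_label,
                       obj.t[sl], {f: v[sl] for f, v in obj.features.items()})


def normalize(session: RawSession) -> CleanSeries:
    """Rescale time to [0, 1], zero x/y at the first sample, drop the
    (on average constant, hence uninformative) inclination channels."""
    t = session.t
    span = t[-1] - t[0]
    if span <= 0:
        raise DegenerateSeriesError("zero time span")
    tt = (t - t[0]) / span
    x = session.samples[:, 1] - session.samples[0, 1]
    y = session.samples[:, 2] - session.samples[0, 2]
    pressure = session.samples[:, 3]
    return CleanSeries(session.child_id, session.time_point, session.game,
                       session.id_label, tt, {"x": x, "y": y, "pressure": pressure})


def _regrid(series: CleanSeries, grid: np.ndarray) -> dict[str, np.ndarray]:
    return {f: np.interp(grid, series.t, v) for f, v in series.features.items()}


def group_by_id(executions: list[CleanSeries],
                grid_points: int = DEFAULT_GRID_POINTS) -> dict[str, CleanSeries]:
    """Average the executions sharing an ID into one representative series.

    All executions are first linearly resampled onto a common uniform grid
    on [0, 1] (executions of unequal length are only comparable there), then
    averaged pointwise per feature.  Returns one series per id_label.
    """
    if not executions:
        raise InvalidInputError("no executions to group")
    heads = {(e.child_id, e.time_point, e.game) for e in executions}
    if len(heads) > 1:
        raise InvalidInputError("executions span multiple children/time-points/games")
    grid = np.linspace(0.0, 1.0, grid_points)
    buckets: dict[str, list[CleanSeries]] = defaultdict(list)
    for e in executions:
        buckets[e.id_label].append(e)
    out = {}
    for id_label, members in buckets.items():
        stacked = {f: np.mean([_regrid(m, grid)[f] for m in members], axis=0)
                   for f in members[0].features}
        m0 = members[0]
        out[id_label] = CleanSeries(m0.child_id, m0.time_point, m0.game,
                                    id_label, grid.copy(), stacked)
    return out


def clean_session(session: RawSession,
                  target_hz: float = DEFAULT_TARGET_HZ,
                  frac: float = DEFAULT_TRUNCATE_FRAC) -> CleanSeries:
    """The per-execution cleaning chain: resample -> truncate -> normalize."""
    return normalize(truncate_ends(resample(session, target_hz), frac))


def preprocess_sessions(sessions: list[RawSession],
                        target_hz: float = DEFAULT_TARGET_HZ,
                        frac: float = DEFAULT_TRUNCATE_FRAC,
                        grid_points: int = DEFAULT_GRID_POINTS,
                        ) -> dict[tuple[str, str, str], dict[str, CleanSeries]]:
    """Clean every session and collapse executions into representatives.

    Returns a mapping (child_id, time_point, game) -> {id_label -> CleanSeries}.
    """
    cleaned: dict[tuple[str, str, str], list[CleanSeries]] = defaultdict(list)
    for s in sessions:
        cleaned[(s.child_id, s.time_point, s.game)].append(
            clean_session(s, target_hz, frac))
    return {key: group_by_id(execs, grid_points) for key, execs in cleaned.items()}
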