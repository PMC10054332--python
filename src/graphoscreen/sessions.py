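"""Session and label data model, with CSV/JSON readers and writers.

A *session* is one execution of one serious game by one child at one
time-point: the ordered stream of stylus samples (timestamp, x, y, pressure,
altitude, azimuth) captured by the tablet.  Labels are BVSCO-2-style
handwriting z-scores collected at the final time-point; the median of the
three exercise z-scores, thresholded at -2, defines the at-risk class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError

TIME_POINTS = ("y1", "y2a", "y2b", "y3a", "y3b")
GAMES = ("copy_square", "copy_sequence", "tunnel_square", "tunnel_word")
COPY_GAMES = ("copy_square", "copy_sequence")
TUNNEL_GAMES = ("tunnel_square", "tunnel_word")
COPY_MODES = ("spontaneous", "big", "small")
FEATURES = ("x", "y", "pressure")

#: number of executions per game in the acquisition protocol
EXECUTIONS_PER_GAME = {
    "copy_square": 3,
    "copy_sequence": 3,
    "tunnel_square": 15,
    "tunnel_word": 15,
}
#: number of distinct difficulty groups each game's executions collapse into
IDS_PER_GAME = {
    "copy_square": 3,
    "copy_sequence": 3,
    "tunnel_square": 5,
    "tunnel_word": 8,
}

SESSION_COLUMNS = [
    "child_id", "time_point", "game", "execution_index", "id_label",
    "t", "x", "y", "pressure", "altitude", "azimuth",
]
LABEL_COLUMNS = ["child_id", "z1", "z2", "z3"]

AT_RISK_THRESHOLD = -2.0


@dataclass
class RawSession:
    """One child x time-point x game x execution stylus stream.

    ``samples`` is a float array of shape (n, 6) whose columns are
    timestamp [s], x, y, pressure (device units), altitude, azimuth [rad].
    """

    child_id: str
    time_point: str
    game: str
    execution_index: int
    id_label: str
    samples: np.ndarray
    rate_hz: float = 240.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise InvalidInputError("samples must be an (n, 6) array")
        if self.samples.shape[0] < 2:
            raise InvalidInputError("a session needs at least 2 samples")
        if np.any(np.diff(self.samples[:, 0]) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if self.time_point not in TIME_POINTS:
            raise InvalidInputError(f"unknown time_point {self.time_point!r}")
        if self.game not in GAMES:
            raise InvalidInputError(f"unknown game {self.game!r}")

    @property
    def t(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def with_samples(self, samples: np.ndarray) -> "RawSession":
        return replace(self, samples=samples)


@dataclass
class CleanSeries:
    """A cleaned, normalised execution: time on [0, 1], x/y zeroed at the
    first sample, inclination channels dropped."""

    child_id: str
    time_point: str
    game: str
    id_label: str
    t: np.ndarray
    features: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.features = {k: np.asarray(v, dtype=float) for k, v in self.features.items()}
        for name, v in self.features.items():
            if v.shape != self.t.shape:
                raise InvalidInputError(f"feature {name!r} not aligned with t")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]


@dataclass(frozen=True)
class TunnelSpec:
    """Geometry of one tunnel: path length (amplitude) A and width W.

    The Index of Difficulty is their ratio A/W: longer or narrower tunnels
    are harder to traverse without crossing the borders.
    """

    amplitude: float
    width: float

    def __post_init__(self):
        if self.amplitude <= 0 or self.width <= 0:
            raise InvalidInputError("amplitude and width must be positive")

    @property
    def id_value(self) -> float:
        return self.amplitude / self.width


@dataclass(frozen=True)
class LabelRecord:
    """A child's three handwriting-test z-scores and the derived risk label."""

    child_id: str
    z1: float
    z2: float
    z3: float
    median_z: float
    at_risk: bool


def label_from_zscores(child_id: str, z1: float, z2: float, z3: float) -> LabelRecord:
    """Apply the risk-labelling rule: median of the three exercise z-scores,
    at-risk iff strictly below -2."""
    zs = np.array([z1, z2, z3], dtype=float)
    if not np.all(np.isfinite(zs)):
        raise InvalidInputError("z-scores must be finite")
    med = float(np.median(zs))
    return LabelRecord(child_id, float(z1), float(z2), float(z3), med,
                       bool(med < AT_RISK_THRESHOLD))


# ---------------------------------------------------------------------------
# persistence

def sessions_to_frame(sessions: list[RawSession]) -> pd.DataFrame:
    frames = []
    for s in sessions:
        n = s.n_samples
        frames.append(pd.DataFrame({
            "child_id": np.repeat(s.child_id, n),
            "time_point": np.repeat(s.time_point, n),
            "game": np.repeat(s.game, n),
            "execution_index": np.repeat(s.execution_index, n),
            "id_label": np.repeat(s.id_label, n),
            "t": s.samples[:, 0],
            "x": s.samples[:, 1],
            "y": s.samples[:, 2],
            "pressure": s.samples[:, 3],
            "altitude": s.samples[:, 4],
            "azimuth": s.samples[:, 5],
        }))
    if not frames:
        return pd.DataFrame(columns=SESSION_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SESSION_COLUMNS]


def frame_to_sessions(df: pd.DataFrame, rate_hz: float = 240.0) -> list[RawSession]:
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"session table missing columns {sorted(missing)}")
    out = []
    keys = ["child_id", "time_point", "game", "execution_index", "id_label"]
    for (child, tp, game, execi, idl), g in df.groupby(keys, sort=False):
        samples = g[["t", "x", "y", "pressure", "altitude", "azimuth"]].to_numpy(float)
        out.append(RawSession(str(child), str(tp), str(game), int(execi), str(idl),
                              samples, rate_hz=rate_hz))
    return out


def write_sessions_csv(sessions: list[RawSession], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions_csv(path: str | Path, rate_hz: float = 240.0) -> list[RawSession]:
    return frame_to_sessions(pd.read_csv(path), rate_hz=rate_hz)


def write_sessions_json(sessions: list[RawSession], path: str | Path) -> None:
    payload = sessions_to_frame(sessions).to_dict(orient="list")
    Path(path).write_text(json.dumps(payload))


def read_sessions_json(path: str | Path, rate_hz: float = 240.0) -> list[RawSession]:
    payload = json.loads(Path(path).read_text())
    return frame_to_sessions(pd.DataFrame(payload), rate_hz=rate_hz)


def write_labels_csv(labels: list[LabelRecord], path: str | Path) -> None:
    pd.DataFrame({
        "child_id": [l.child_id for l in labels],
        "z1": [l.z1 for l in labels],
        "z2": [l.z2 for l in labels],
        "z3": [l.z3 for l in labels],
    }).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> list[LabelRecord]:
    df = pd.read_csv(path)
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"label table missing columns {sorted(missing)}")
    return [label_from_zscores(str(r.child_id), r.z1, r.z2, r.z3)
            for r in df.itertuples(index=False)]
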