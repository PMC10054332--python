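"""Distance-threshold voting risk classifier.

The fit procedure, for a fixed aggregation mode, matching scheme and
landmark count N: for every (ID, feature) unit, combine each child's
sinusoids into a periodic curve, average the curves of the training
children into a cohort-average curve, select its N strongest landmarks,
compute every child's Procrustes distance to the average (landmarks matched
per the scheme), and fit the F1-optimal distance threshold on the training
children.  Each unit then votes "at-risk" when a child's distance exceeds
its threshold (an outlier relative to the cohort average); the fraction of
positive votes is the child's risk probability, and an F1-optimal
probability threshold turns it into a class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curves import combine_sinusoids_batch, curve_grid, PeriodicCurve
from .embedding import EmbeddedSignal, GameEmbeddings
from .errors import (DegenerateLabelsError, InsufficientLandmarksError,
                     InvalidInputError, UnfitConfigurationError,
                     UnpredictableChildError)
from .shape import (LandmarkSet, _landmark_order, find_extrema,
                    match_landmarks, procrustes_distance,
                    procrustes_distance_batch, select_landmarks)

logger = logging.getLogger(__name__)

AGG_MODES = ("abs_weighted_mean", "weighted_sum")
SCHEMES = ("value_order", "time_order")


@dataclass(frozen=True)
class ClassifierConfig:
    """One point of the ablation grid: aggregation mode, landmark matching
    scheme, and number of landmarks N."""

    mode: str
    scheme: str
    n_landmarks: int

    def __post_init__(self):
        if self.mode not in AGG_MODES:
            raise InvalidInputError(f"unknown mode {self.mode!r}")
        if self.scheme not in SCHEMES:
            raise InvalidInputError(f"unknown scheme {self.scheme!r}")
        if self.n_landmarks < 2:
            raise InvalidInputError("n_landmarks must be >= 2")


#: the four (mode, scheme) configurations of the ablation study
CONFIGURATIONS = tuple((m, s) for m in AGG_MODES for s in SCHEMES)


def _f1_from_preds(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = np.sum(y_pred & y_true)
    fp = np.sum(y_pred & ~y_true)
    fn = np.sum(~y_pred & y_true)
    if tp == 0:
        return 0.0
    return float(2 * tp / (2 * tp + fp + fn))


def best_threshold(values: np.ndarray, labels: np.ndarray,
                   rule: str = "gt") -> tuple[float, float]:
    """F1-optimal cut on per-child scalars.

    ``rule="gt"`` classifies value > threshold as positive (distances);
    candidates are the midpoints of consecutive distinct sorted values plus
    one candidate below the minimum and one above the maximum.
    ``rule="ge"`` classifies value >= threshold as positive (probabilities);
    candidates are the midpoints plus 0 and 1.  Ties are broken by the
    smallest (most sensitive) threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise InvalidInputError("values and labels must be aligned vectors")
    if values.shape[0] < 2:
        raise DegenerateLabelsError("need at least 2 children")
    if labels.all() or not labels.any():
        raise DegenerateLabelsError("need both classes to fit a threshold")
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    if rule == "gt":
        cands = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
        preds = values[None, :] > cands[:, None]
    elif rule == "ge":
        cands = np.unique(np.concatenate(([0.0], mids, [1.0])))
        preds = values[None, :] >= cands[:, None]
    else:
        raise InvalidInputError(f"unknown rule {rule!r}")
    tp = (preds & labels).sum(axis=1)
    fp = (preds & ~labels).sum(axis=1)
    fn = (~preds & labels).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(tp > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
    k = int(np.argmax(f1))  # first (= smallest) candidate on ties
    return float(cands[k]), float(f1[k])


@dataclass
class UnitClassifier:
    """One (ID, feature) distance-threshold voter."""

    id_label: str
    feature: str
    average_landmarks: LandmarkSet
    distance_threshold: float
    training_f1: float


class ThresholdVotingModel:
    """Model object: a game's cohort embeddings plus labels and a
    configuration; :meth:`fit` runs the fit procedure."""

    def __init__(self, embeddings: GameEmbeddings, labels: np.ndarray,
                 config: ClassifierConfig):
        self.embeddings = embeddings
        self.labels = np.asarray(labels, dtype=bool)
        if self.labels.shape[0] != len(embeddings.children):
            raise InvalidInputError("labels must align with embedded children")
        self.config = config
        self._ctx = GameFitContext(embeddings)

    def fit(self, train_idx: np.ndarray | None = None) -> "RiskClassifierResults":
        if train_idx is None:
            train_idx = np.arange(len(self.embeddings.children))
        return self._ctx.fit(train_idx, self.labels, self.config)


class GameFitContext:
    """Precomputed curves and extrema for one game, reused across the many
    (train subset, configuration, N) fits of the cross-validation."""

    def __init__(self, ge: GameEmbeddings, grid: np.ndarray | None = None):
        self.ge = ge
        self.grid = curve_grid() if grid is None else grid
        self.curves: dict[str, np.ndarray] = {}
        # per (mode, unit, child): extrema points sorted |v| desc, t asc
        self.sorted_extrema: dict[str, list[list[np.ndarray]]] = {}
        for mode in AGG_MODES:
            cur = combine_sinusoids_batch(ge.omega, ge.phi, ge.p, mode, self.grid)
            self.curves[mode] = cur
            per_unit = []
            for u in range(cur.shape[0]):
                per_child = []
                for c in range(cur.shape[1]):
                    if not np.all(np.isfinite(cur[u, c])):
                        per_child.append(np.empty((0, 2)))
                        continue
                    ex = find_extrema(PeriodicCurve(self.grid, cur[u, c],
                                                    ("child", None, None, mode)))
                    pts = np.asarray(ex, dtype=float).reshape(-1, 2)
                    per_child.append(pts[_landmark_order(pts)] if len(pts) else pts)
                per_unit.append(per_child)
            self.sorted_extrema[mode] = per_unit

    # -- landmark bookkeeping -------------------------------------------

    def average_landmarks(self, mode: str, unit: int, train_idx: np.ndarray,
                          n: int) -> LandmarkSet:
        avg = self.curves[mode][unit, train_idx].mean(axis=0)
        ex = find_extrema(PeriodicCurve(self.grid, avg, ("average", None, None, mode)))
        return select_landmarks(ex, n, source=("average", self.ge.units[unit]))

    def max_landmarks(self, mode: str, train_idx: np.ndarray) -> int:
        """Largest N available on every unit's average curve for this
        training set (the fold's cap on the landmark-count search)."""
        counts = []
        for u in range(len(self.ge.units)):
            avg = self.curves[mode][u, train_idx].mean(axis=0)
            ex = find_extrema(PeriodicCurve(self.grid, avg,
                                            ("average", None, None, mode)))
            counts.append(len(ex))
        return min(counts) if counts else 0

    def _matched_child_points(self, mode: str, scheme: str, unit: int,
                              n: int) -> np.ndarray:
        """(C, n, 2) matched landmark arrays; NaN rows where a child lacks
        enough extrema."""
        C = len(self.ge.children)
        out = np.full((C, n, 2), np.nan)
        for c, pts in enumerate(self.sorted_extrema[mode][unit]):
            if pts.shape[0] < n:
                continue
            sel = pts[:n]  # already |v| desc, t asc
            if scheme == "time_order":
                sel = sel[np.lexsort((sel[:, 1], sel[:, 0]))]
            out[c] = sel
        return out

    def unit_distances(self, config: ClassifierConfig, unit: int,
                       avg: LandmarkSet) -> np.ndarray:
        """Every child's Procrustes distance to the average landmarks."""
        pts = avg.points  # stored |v| desc, t asc == value_order
        if config.scheme == "time_order":
            pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
        A = self._matched_child_points(config.mode, config.scheme, unit,
                                       config.n_landmarks)
        return procrustes_distance_batch(A, pts)

    # -- fitting ---------------------------------------------------------

    def fit(self, train_idx: np.ndarray, labels: np.ndarray,
            config: ClassifierConfig) -> "RiskClassifierResults":
        labels = np.asarray(labels, dtype=bool)
        y_train = labels[train_idx]
        if y_train.all() or not y_train.any():
            raise DegenerateLabelsError("training labels contain one class")
        units, dists = [], []
        for u, (idl, feat) in enumerate(self.ge.units):
            try:
                avg = self.average_landmarks(config.mode, u, train_idx,
                                             config.n_landmarks)
            except InsufficientLandmarksError:
                logger.warning("unit (%s, %s) dropped: too few extrema on the "
                               "average curve for N=%d", idl, feat,
                               config.n_landmarks)
                continue
            d = self.unit_distances(config, u, avg)
            dtr = d[train_idx]
            valid = np.isfinite(dtr)
            yv = y_train[valid]
            if valid.sum() < 2 or yv.all() or not yv.any():
                logger.warning("unit (%s, %s) dropped: degenerate training "
                               "distances", idl, feat)
                continue
            theta, f1 = best_threshold(dtr[valid], yv, rule="gt")
            units.append(UnitClassifier(idl, feat, avg, theta, f1))
            dists.append(d)
        if not units:
            raise UnfitConfigurationError(
                f"no unit survived for configuration {config}")
        D = np.stack(dists)  # (U_kept, C)
        votes = D > np.array([u.distance_threshold for u in units])[:, None]
        valid = np.isfinite(D)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(valid.sum(0) > 0,
                             (votes & valid).sum(0) / valid.sum(0), np.nan)
        ptr = probs[train_idx]
        ok = np.isfinite(ptr)
        theta_p, train_f1 = best_threshold(ptr[ok], y_train[ok], rule="ge")
        return RiskClassifierResults(self, config, units, float(theta_p),
                                     float(train_f1), probs, train_idx)


class RiskClassifierResults:
    """A fitted voting classifier: per-unit thresholds plus the probability
    threshold, with cached probabilities for the cohort it was fitted in."""

    def __init__(self, ctx: GameFitContext, config: ClassifierConfig,
                 units: list[UnitClassifier], probability_threshold: float,
                 training_f1: float, probabilities: np.ndarray,
                 train_idx: np.ndarray):
        self.ctx = ctx
        self.config = config
        self.units = units
        self.probability_threshold = probability_threshold
        self.training_f1 = training_f1
        self._probabilities = probabilities
        self.train_idx = np.asarray(train_idx)

    def predict_proba(self, idx: np.ndarray | None = None) -> np.ndarray:
        if idx is None:
            return self._probabilities.copy()
        return self._probabilities[np.asarray(idx)]

    def predict(self, idx: np.ndarray | None = None) -> np.ndarray:
        return self.predict_proba(idx) >= self.probability_threshold

    def predict_child(self, embeddings: dict[tuple[str, str], EmbeddedSignal]
                      ) -> tuple[float, bool]:
        """Classify a single out-of-cohort child from its per-(ID, feature)
        embeddings.  Units whose inputs are missing or yield too few
        extrema are skipped."""
        votes, used = 0, 0
        for unit in self.units:
            emb = embeddings.get((unit.id_label, unit.feature))
            if emb is None:
                continue
            from .curves import combine_sinusoids
            try:
                curve = combine_sinusoids(emb, self.config.mode, self.ctx.grid)
                lm = select_landmarks(find_extrema(curve), self.config.n_landmarks)
            except InsufficientLandmarksError:
                continue
            pa, pb = match_landmarks(lm, unit.average_landmarks,
                                     self.config.scheme)
            d = procrustes_distance(pa, pb)
            used += 1
            votes += d > unit.distance_threshold
        if used == 0:
            raise UnpredictableChildError("no usable unit inputs for child")
        prob = votes / used
        return float(prob), bool(prob >= self.probability_threshold)

    def summary(self) -> str:
        lines = [
            "Threshold-voting risk classifier".center(62),
            "=" * 62,
            f"game: {self.ctx.ge.game:<14} mode: {self.config.mode:<18} "
            f"scheme: {self.config.scheme}",
            f"landmarks N: {self.config.n_landmarks:<4d} units: "
            f"{len(self.units):<4d} theta_p: {self.probability_threshold:.3f} "
            f"train F1: {self.training_f1:.3f}",
            "-" * 62,
            f"{'ID':>8} {'feature':>9} {'theta':>10} {'unit F1':>8}",
        ]
        for u in self.units:
            lines.append(f"{u.id_label:>8} {u.feature:>9} "
                         f"{u.distance_threshold:>10.4f} {u.training_f1:>8.3f}")
        lines.append("=" * 62)
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": {"mode": self.config.mode, "scheme": self.config.scheme,
                       "n_landmarks": self.config.n_landmarks},
            "probability_threshold": self.probability_threshold,
            "training_f1": self.training_f1,
            "units": [{
                "id_label": u.id_label, "feature": u.feature,
                "distance_threshold": u.distance_threshold,
                "training_f1": u.training_f1,
                "average_landmarks": u.average_landmarks.points.tolist(),
            } for u in self.units],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_risk_classifier(embeddings: GameEmbeddings, labels: np.ndarray,
                        config: ClassifierConfig) -> RiskClassifierResults:
    """Fit the voting classifier on the full cohort (Algorithm 1)."""
    return ThresholdVotingModel(embeddings, labels, config).fit()
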