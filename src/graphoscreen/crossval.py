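"""Stratified nested 5-fold cross-validation and the evaluation metric suite.

The outer loop partitions the cohort into k stratified test folds.  For
each outer fold, k overlapping inner validation subsets (stratified 25%
subsamples of the outer-train children) drive the tuning: for every
(aggregation mode, matching scheme) configuration and every inner fold, the
fit procedure is run on the inner-train children for each candidate
landmark count N and the best N is chosen on that validation subset; the
configuration with the best mean validation F1 across the k inner folds
wins the outer fold.  At test time the k inner classifiers of the winning
configuration vote by averaging their risk probabilities, thresholded at
the mean of their probability thresholds.  All outer-test predictions are
finally concatenated and scored once (micro-averaging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import (CONFIGURATIONS, ClassifierConfig, GameFitContext,
                         RiskClassifierResults)
from .embedding import GameEmbeddings
from .errors import (DegenerateLabelsError, InfeasibleStratificationError,
                     InvalidInputError, UnfitConfigurationError)

logger = logging.getLogger(__name__)

DEFAULT_K = 5
#: fraction of the outer-train children in each inner validation subset
INNER_VALIDATION_FRACTION = 0.25
DEFAULT_N_RANGE = tuple(range(2, 11))


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class MetricsReport:
    """Binary classification metrics, in percent, plus the confusion counts
    and the support-weighted two-class averages."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    precision_wavg: float
    recall_wavg: float
    f1_wavg: float
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("accuracy", "precision", "recall", "specificity", "f1",
              "precision_wavg", "recall_wavg", "f1_wavg")}
        d["confusion"] = {"tp": self.confusion[0], "fp": self.confusion[1],
                          "tn": self.confusion[2], "fn": self.confusion[3]}
        return d


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * prec * rec / (prec + rec)) if prec + rec > 0 else 0.0
    return prec, rec, f1


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Compute the full metric suite from true and predicted labels.

    Precision/recall/F1 treat "at-risk" as positive; the weighted averages
    sum each class's one-vs-rest metric weighted by its support fraction.
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise InvalidInputError("y_true and y_pred must be aligned non-empty")
    tp = int(np.sum(y_pred & y_true))
    fp = int(np.sum(y_pred & ~y_true))
    tn = int(np.sum(~y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    n = tp + fp + tn + fn
    prec, rec, f1 = _prf(tp, fp, fn)
    spec = tn / (tn + fp) if tn + fp > 0 else 0.0
    # negative class as positive: TP' = tn, FP' = fn, FN' = fp
    nprec, nrec, nf1 = _prf(tn, fn, fp)
    w_pos = (tp + fn) / n
    w_neg = (tn + fp) / n
    return MetricsReport(
        accuracy=100.0 * (tp + tn) / n,
        precision=100.0 * prec,
        recall=100.0 * rec,
        specificity=100.0 * spec,
        f1=100.0 * f1,
        precision_wavg=100.0 * (w_pos * prec + w_neg * nprec),
        recall_wavg=100.0 * (w_pos * rec + w_neg * nrec),
        f1_wavg=100.0 * (w_pos * f1 + w_neg * nf1),
        confusion=(tp, fp, tn, fn),
    )


def baseline_metrics(y_true: np.ndarray) -> MetricsReport:
    """The all-negative dummy classifier (always predicts the majority,
    not-at-risk, class)."""
    y_true = np.asarray(y_true, dtype=bool)
    return metrics(y_true, np.zeros_like(y_true))


# ---------------------------------------------------------------------------
# fold plans

@dataclass
class FoldPlan:
    """Outer stratified partition plus, per outer fold, k overlapping
    stratified inner validation subsets of the outer-train children."""

    k: int
    outer: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    inner: list[list[np.ndarray]]               # [outer][inner] -> val_idx
    seed: int


def _stratified_subset(rng: np.random.Generator, idx: np.ndarray,
                       labels: np.ndarray, fraction: float) -> np.ndarray:
    chosen = []
    for cls in (False, True):
        members = idx[labels[idx] == cls]
        n_take = max(1, int(round(fraction * members.size)))
        chosen.append(rng.choice(members, size=n_take, replace=False))
    return np.sort(np.concatenate(chosen))


def make_fold_plan(labels: np.ndarray, k: int = DEFAULT_K,
                   seed: int = 0) -> FoldPlan:
    """Build the nested plan: a stratified k-fold outer partition and, per
    outer fold, k independently drawn stratified 25% validation subsets of
    the outer-train (so inner folds may overlap)."""
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if min(n_pos, n_neg) < k:
        raise InfeasibleStratificationError(
            f"minority class has {min(n_pos, n_neg)} members, need >= {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(seed) % (2 ** 32 - 1))
    outer = [(tr.copy(), te.copy())
             for tr, te in skf.split(np.zeros(labels.size), labels)]
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 1])
    inner = []
    for tr, _ in outer:
        inner.append([_stratified_subset(rng, tr, labels,
                                         INNER_VALIDATION_FRACTION)
                      for _ in range(k)])
    return FoldPlan(k=k, outer=outer, inner=inner, seed=int(seed))


# ---------------------------------------------------------------------------
# nested CV

@dataclass
class ValidationRecord:
    child_idx: int
    outer_fold: int
    inner_fold: int
    probability: float


@dataclass
class TestRecord:
    child_idx: int
    outer_fold: int
    probability: float
    predicted: bool


@dataclass
class NestedCVResult:
    """Everything Algorithm 2 produces for one game."""

    game: str
    children: list[str]
    test_records: list[TestRecord]
    validation_records: list[ValidationRecord]
    selections: list[tuple[str, str]]        # winning (mode, scheme) per outer fold
    selected_n: list[list[int]]              # [outer][inner] best N (winning config)
    fold_classifiers: list[list[RiskClassifierResults]]
    report: MetricsReport

    def concatenated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(child_idx, probability, predicted) over all outer test folds."""
        idx = np.array([r.child_idx for r in self.test_records])
        prob = np.array([r.probability for r in self.test_records])
        pred = np.array([r.predicted for r in self.test_records])
        return idx, prob, pred


def _clip_n_range(ctx: GameFitContext, mode: str, train_idx: np.ndarray,
                  n_range) -> list[int]:
    n_max = ctx.max_landmarks(mode, train_idx)
    return [n for n in n_range if 2 <= n <= n_max]


def run_nested_cv(embeddings: GameEmbeddings, labels: np.ndarray,
                  plan: FoldPlan, n_range=DEFAULT_N_RANGE,
                  configs=CONFIGURATIONS) -> NestedCVResult:
    """Run the stratified nested cross-validation for one game."""
    labels = np.asarray(labels, dtype=bool)
    ctx = GameFitContext(embeddings)
    test_records: list[TestRecord] = []
    val_records: list[ValidationRecord] = []
    selections: list[tuple[str, str]] = []
    selected_n: list[list[int]] = []
    fold_classifiers: list[list[RiskClassifierResults]] = []

    for o, (tr, te) in enumerate(plan.outer):
        per_config: dict[tuple[str, str], dict] = {}
        for mode, scheme in configs:
            entry = {"clfs": [], "f1s": [], "ns": [], "vals": []}
            failed = False
            for i, val_idx in enumerate(plan.inner[o]):
                inner_tr = np.setdiff1d(tr, val_idx)
                best = None
                for n in _clip_n_range(ctx, mode, inner_tr, n_range):
                    cfg = ClassifierConfig(mode, scheme, n)
                    try:
                        clf = ctx.fit(inner_tr, labels, cfg)
                    except (UnfitConfigurationError, DegenerateLabelsError):
                        continue
                    vp = clf.predict_proba(val_idx)
                    ok = np.isfinite(vp)
                    pred = vp[ok] >= clf.probability_threshold
                    from .classifier import _f1_from_preds
                    f1 = _f1_from_preds(labels[val_idx][ok], pred)
                    if best is None or f1 > best[0]:
                        best = (f1, n, clf, vp)
                if best is None:
                    failed = True
                    break
                entry["f1s"].append(best[0])
                entry["ns"].append(best[1])
                entry["clfs"].append(best[2])
                entry["vals"].append((val_idx, best[3]))
            if not failed:
                entry["mean_f1"] = float(np.mean(entry["f1s"]))
                per_config[(mode, scheme)] = entry
            else:
                logger.warning("configuration (%s, %s) skipped on outer fold "
                               "%d", mode, scheme, o)
        if not per_config:
            raise UnfitConfigurationError(
                f"no configuration could be fitted on outer fold {o}")
        win = max(per_config, key=lambda kk: per_config[kk]["mean_f1"])
        entry = per_config[win]
        selections.append(win)
        selected_n.append(entry["ns"])
        fold_classifiers.append(entry["clfs"])
        for i, (val_idx, vp) in enumerate(entry["vals"]):
            for j, cidx in enumerate(val_idx):
                if np.isfinite(vp[j]):
                    val_records.append(ValidationRecord(int(cidx), o, i,
                                                        float(vp[j])))
        probs = np.nanmean(np.stack([c.predict_proba(te)
                                     for c in entry["clfs"]]), axis=0)
        thr = float(np.mean([c.probability_threshold for c in entry["clfs"]]))
        preds = probs >= thr
        for j, cidx in enumerate(te):
            test_records.append(TestRecord(int(cidx), o, float(probs[j]),
                                           bool(preds[j])))

    idx = np.array([r.child_idx for r in test_records])
    pred = np.array([r.predicted for r in test_records])
    report = metrics(labels[idx], pred)
    return NestedCVResult(embeddings.game, list(embeddings.children),
                          test_records, val_records, selections, selected_n,
                          fold_classifiers, report)


def config_tally(selections: list[tuple[str, str]]) -> dict[tuple[str, str], float]:
    """Selection frequency of each (mode, scheme) configuration."""
    if not selections:
        raise InvalidInputError("no recorded selections")
    out = {c: 0.0 for c in CONFIGURATIONS}
    for s in selections:
        out[tuple(s)] = out.get(tuple(s), 0.0) + 1.0
    return {c: v / len(selections) for c, v in out.items()}
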