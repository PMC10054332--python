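"""Blending meta-model over the four per-game classifiers (Quasi-SVM).

The meta-dataset has one row per child with four features: the predicted
risk probability from each game's threshold-voting classifier.  Rows built
from inner validation folds form the meta-training set (a child appearing
in several validation folds contributes the mean of its probabilities);
rows built from the outer test folds form the meta-test set.

The meta-model is a Quasi-SVM: a fixed randomized trigonometric feature
expansion (random Fourier features approximating an RBF kernel, with a
trainable kernel length-scale) followed by a single output unit.  The
sigmoid output is affinely mapped to (-1, 1) and trained with class-
weighted hinge loss against labels in {-1, +1} — a small network imitating
a kernel support-vector machine.  Optimisation is full-batch Adam with a
stratified 80/20 train/holdout split and early stopping on the holdout
loss (best-epoch weights restored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import (DegenerateLabelsError, InvalidInputError,
                     MissingGameError, TrainingDivergenceError)
from .sessions import GAMES

META_FEATURES = tuple(f"prob_{g}" for g in GAMES)


@dataclass
class QuasiSVMSpec:
    """Training recipe for the meta-model."""

    n_random_features: int = 512
    kernel_scale: float = 1.0
    learning_rate: float = 1e-4
    max_epochs: int = 1000
    patience: int = 50
    holdout_fraction: float = 0.2
    seed: int = 0
    class_weighting: bool = True

    def __post_init__(self):
        if not 0 < self.holdout_fraction < 1:
            raise InvalidInputError("holdout_fraction must be in (0, 1)")
        if min(self.n_random_features, self.kernel_scale, self.learning_rate,
               self.max_epochs, self.patience) <= 0:
            raise InvalidInputError("QuasiSVMSpec fields must be positive")


def assemble_meta(validation_records: dict[str, list[tuple[str, float]]],
                  test_records: dict[str, list[tuple[str, float]]],
                  labels: dict[str, bool],
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the meta-training and meta-test tables.

    ``validation_records[game]`` is a list of (child_id, probability), one
    entry per validation appearance; ``test_records[game]`` holds each
    child's single outer-test probability.  Children missing a game have
    the feature imputed with the meta-training column mean.
    """
    for game in GAMES:
        if game not in validation_records or game not in test_records:
            raise MissingGameError(f"records for {game!r} are required")

    def build(records, reference_means=None):
        per_game = {}
        for game in GAMES:
            df = pd.DataFrame(records[game], columns=["child_id", "prob"])
            per_game[game] = df.groupby("child_id")["prob"].mean()
        children = sorted(set().union(*[s.index for s in per_game.values()]))
        out = pd.DataFrame({"child_id": children})
        for game in GAMES:
            col = per_game[game].reindex(children)
            fill = (reference_means[f"prob_{game}"] if reference_means is not None
                    else col.mean())
            out[f"prob_{game}"] = col.fillna(fill).to_numpy()
        out["label"] = [bool(labels[c]) for c in children]
        return out

    meta_train = build(validation_records)
    train_means = {c: float(meta_train[c].mean()) for c in META_FEATURES}
    meta_test = build(test_records, reference_means=train_means)
    return meta_train, meta_test


class QuasiSVM:
    """Model object for the blending meta-model."""

    def __init__(self, meta_train: pd.DataFrame,
                 spec: QuasiSVMSpec | None = None):
        missing = set(META_FEATURES) - set(meta_train.columns)
        if missing:
            raise InvalidInputError(f"meta table missing columns {sorted(missing)}")
        self.spec = spec or QuasiSVMSpec()
        self.X = meta_train[list(META_FEATURES)].to_numpy(float)
        self.y = meta_train["label"].to_numpy(bool)
        if self.y.all() or not self.y.any():
            raise DegenerateLabelsError("meta-training labels contain one class")

    def fit(self) -> "QuasiSVMResults":
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        d = self.X.shape[1]
        D = spec.n_random_features
        Wrf = rng.standard_normal((d, D))
        brf = rng.uniform(0.0, 2 * np.pi, D)

        idx = np.arange(self.X.shape[0])
        tr, ho = train_test_split(idx, test_size=spec.holdout_fraction,
                                  stratify=self.y,
                                  random_state=int(spec.seed) % (2 ** 32 - 1))
        Xtr, ytr = self.X[tr], np.where(self.y[tr], 1.0, -1.0)
        Xho, yho = self.X[ho], np.where(self.y[ho], 1.0, -1.0)

        n = ytr.size
        if spec.class_weighting:
            n_pos, n_neg = (ytr > 0).sum(), (ytr < 0).sum()
            w_tr = np.where(ytr > 0, n / (2.0 * n_pos), n / (2.0 * n_neg))
            hp, hn = (yho > 0).sum(), (yho < 0).sum()
            w_ho = np.where(yho > 0, yho.size / (2.0 * max(hp, 1)),
                            yho.size / (2.0 * max(hn, 1)))
        else:
            w_tr = np.ones(n)
            w_ho = np.ones(yho.size)

        # trainable parameters: output weights, bias, log kernel scale
        w = rng.normal(0.0, 1e-2, D)
        b0 = 0.0
        rho = np.log(spec.kernel_scale)
        params = {"w": w, "b0": np.array(b0), "rho": np.array(rho)}
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v2 = {k: np.zeros_like(v) for k, v in params.items()}
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        scale = np.sqrt(2.0 / D)

        def forward(X, par):
            U = X @ Wrf / np.exp(par["rho"]) + brf
            Z = scale * np.cos(U)
            f = Z @ par["w"] + par["b0"]
            sig = 1.0 / (1.0 + np.exp(-f))
            o = 2.0 * sig - 1.0
            return U, Z, f, sig, o

        def loss_of(o, y, wgt):
            return float(np.mean(wgt * np.maximum(0.0, 1.0 - y * o)))

        best = {k: np.copy(val) for k, val in params.items()}
        best_loss = np.inf
        since = 0
        step = 0
        for epoch in range(spec.max_epochs):
            U, Z, f, sig, o = forward(Xtr, params)
            margin_active = (1.0 - ytr * o) > 0
            _, _, _, _, o_ho = forward(Xho, params)
            ho_loss = loss_of(o_ho, yho, w_ho)
            if not np.isfinite(ho_loss):
                raise TrainingDivergenceError("non-finite holdout loss",
                                              epoch=epoch)
            if ho_loss < best_loss - 1e-12:
                best_loss = ho_loss
                best = {k: np.copy(val) for k, val in params.items()}
                since = 0
            else:
                since += 1
                if since >= spec.patience:
                    break

            # dL/df = w * active * (-y) * 2 sig (1-sig) / n
            dd = (w_tr * margin_active * (-ytr) * 2.0 * sig * (1 - sig)) / n
            gw = Z.T @ dd
            gb0 = dd.sum()
            dZ = np.outer(dd, params["w"])
            dU = -scale * np.sin(U) * dZ
            # U = XW e^{-rho} + b  =>  dU/drho = -(U - brf)
            grho = float(np.sum(dU * -(U - brf)))
            grads = {"w": gw, "b0": np.array(gb0), "rho": np.array(grho)}

            step += 1
            c1, c2 = 1 - b1m ** step, 1 - b2m ** step
            for k in params:
                m[k] = b1m * m[k] + (1 - b1m) * grads[k]
                v2[k] = b2m * v2[k] + (1 - b2m) * grads[k] ** 2
                params[k] = params[k] - spec.learning_rate * (m[k] / c1) / (
                    np.sqrt(v2[k] / c2) + eps)

        return QuasiSVMResults(self, Wrf, brf, best, float(best_loss))


class QuasiSVMResults:
    """Fitted meta-model with frozen random features and best-epoch weights."""

    def __init__(self, model: QuasiSVM, Wrf, brf, params, holdout_loss):
        self.model = model
        self.Wrf = Wrf
        self.brf = brf
        self.params = params
        self.holdout_loss = holdout_loss

    def decision_function(self, meta: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = (meta[list(META_FEATURES)].to_numpy(float)
             if isinstance(meta, pd.DataFrame) else np.asarray(meta, float))
        if X.ndim != 2 or X.shape[1] != len(META_FEATURES):
            raise InvalidInputError(
                f"expected {len(META_FEATURES)} features per row")
        U = X @ self.Wrf / np.exp(self.params["rho"]) + self.brf
        Z = np.sqrt(2.0 / self.Wrf.shape[1]) * np.cos(U)
        return Z @ self.params["w"] + float(self.params["b0"])

    def predict_proba(self, meta) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(meta)))

    def predict(self, meta) -> np.ndarray:
        """Positive iff the (-1, 1)-mapped output is strictly positive."""
        return self.decision_function(meta) > 0

    def summary(self) -> str:
        sp = self.model.spec
        return "\n".join([
            "Quasi-SVM blending meta-model".center(54),
            "=" * 54,
            f"random features: {sp.n_random_features:>5d}    "
            f"kernel scale: {float(np.exp(self.params['rho'])):.4f}",
            f"train rows: {self.model.X.shape[0]:>10d}    "
            f"holdout hinge loss: {self.holdout_loss:.4f}",
            "=" * 54,
        ])


def fit_quasi_svm(meta_train: pd.DataFrame,
                  spec: QuasiSVMSpec | None = None) -> QuasiSVMResults:
    return QuasiSVM(meta_train, spec).fit()


def predict_quasi_svm(results: QuasiSVMResults, meta: pd.DataFrame
                      ) -> pd.DataFrame:
    """Per-row probability and predicted label for a meta table."""
    prob = results.predict_proba(meta)
    pred = results.predict(meta)
    out = meta[["child_id"]].copy() if "child_id" in meta else pd.DataFrame(
        index=range(len(prob)))
    out["probability"] = prob
    out["predicted"] = pred
    return out
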