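"""End-to-end orchestration: simulate/load -> clean -> embed -> per-game
nested cross-validation -> blending meta-model -> reports.

Every stage's randomness is derived deterministically from the single
global seed by hashing the stage name (CRC-32) into a seed sequence, so a
run is reproducible bit-for-bit from its configuration.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .blending import QuasiSVMSpec, assemble_meta, fit_quasi_svm, predict_quasi_svm
from .crossval import (DEFAULT_K, DEFAULT_N_RANGE, MetricsReport,
                       NestedCVResult, baseline_metrics, config_tally,
                       make_fold_plan, metrics, run_nested_cv)
from .embedding import TrainSpec, embed_cohort
from .errors import InvalidInputError
from .preprocess import preprocess_sessions
from .sessions import GAMES, LabelRecord, RawSession, read_labels_csv, read_sessions_csv
from .simulate import CohortConfig, generate_cohort


def derive_seed(global_seed: int, *tags: str | int) -> int:
    """Deterministic per-stage seed below 2**31."""
    parts = [int(global_seed) & 0x7FFFFFFF]
    for t in tags:
        parts.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(parts).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Configuration of one full run: either a simulation block or input
    paths, plus the stage specs."""

    simulation: CohortConfig | None = None
    sessions_path: str | None = None
    labels_path: str | None = None
    seed: int = 0
    train: TrainSpec = field(default_factory=TrainSpec)
    k: int = DEFAULT_K
    n_range: tuple[int, ...] = DEFAULT_N_RANGE
    quasi: QuasiSVMSpec = field(default_factory=QuasiSVMSpec)
    out_dir: str | None = None

    def __post_init__(self):
        has_sim = self.simulation is not None
        has_paths = self.sessions_path is not None
        if has_sim == has_paths:
            raise InvalidInputError(
                "exactly one of simulation block / input paths is required")
        if has_paths and self.labels_path is None:
            raise InvalidInputError("labels_path is required with sessions_path")


@dataclass
class TimePointReport:
    time_point: str
    game_results: dict[str, NestedCVResult]
    game_metrics: dict[str, MetricsReport]
    meta_metrics: MetricsReport
    baseline: MetricsReport
    tally: dict[tuple[str, str], float]
    meta_train: pd.DataFrame
    meta_test: pd.DataFrame
    meta_predictions: pd.DataFrame


@dataclass
class PipelineReport:
    config_seed: int
    labels: dict[str, bool]
    time_points: dict[str, TimePointReport]

    def summary(self) -> dict:
        out = {"seed": self.config_seed, "n_children": len(self.labels),
               "prevalence": float(np.mean(list(self.labels.values()))),
               "time_points": {}}
        for tp, rep in sorted(self.time_points.items()):
            out["time_points"][tp] = {
                "games": {g: m.as_dict() for g, m in sorted(rep.game_metrics.items())},
                "quasi_svm": rep.meta_metrics.as_dict(),
                "baseline": rep.baseline.as_dict(),
                "config_tally": {f"{m}|{s}": v for (m, s), v in
                                 sorted(rep.tally.items())},
            }
        return out

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def _load_data(config: RunConfig) -> tuple[list[RawSession], list[LabelRecord]]:
    if config.simulation is not None:
        sim = replace(config.simulation,
                      seed=derive_seed(config.seed, "simulate",
                                       config.simulation.seed))
        return generate_cohort(sim)
    sessions = read_sessions_csv(config.sessions_path)
    labels = read_labels_csv(config.labels_path)
    return sessions, labels


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute every stage and return the full report bundle."""
    sessions, labels = _load_data(config)
    label_map = {l.child_id: l.at_risk for l in labels}
    # children without labels are dropped at load time
    sessions = [s for s in sessions if s.child_id in label_map]

    representatives = preprocess_sessions(sessions)
    train_spec = replace(config.train, seed=derive_seed(config.seed, "embed"))
    embeddings = embed_cohort(representatives, train_spec)

    time_points = sorted({tp for tp, _ in embeddings})
    reports: dict[str, TimePointReport] = {}
    for tp in time_points:
        game_results: dict[str, NestedCVResult] = {}
        game_metrics: dict[str, MetricsReport] = {}
        val_rec: dict[str, list[tuple[str, float]]] = {}
        test_rec: dict[str, list[tuple[str, float]]] = {}
        selections = []
        children_ref = None
        for game in GAMES:
            ge = embeddings.get((tp, game))
            if ge is None:
                continue
            y = np.array([label_map[c] for c in ge.children])
            plan = make_fold_plan(y, k=config.k,
                                  seed=derive_seed(config.seed, "folds", tp, game))
            res = run_nested_cv(ge, y, plan, n_range=config.n_range)
            game_results[game] = res
            game_metrics[game] = res.report
            selections.extend(res.selections)
            val_rec[game] = [(ge.children[r.child_idx], r.probability)
                             for r in res.validation_records]
            test_rec[game] = [(ge.children[r.child_idx], r.probability)
                              for r in res.test_records]
            children_ref = ge.children

        meta_train, meta_test = assemble_meta(val_rec, test_rec, label_map)
        qspec = replace(config.quasi, seed=derive_seed(config.seed, "quasi", tp))
        qfit = fit_quasi_svm(meta_train, qspec)
        meta_pred = predict_quasi_svm(qfit, meta_test)
        y_test = meta_test["label"].to_numpy(bool)
        meta_metrics = metrics(y_test, meta_pred["predicted"].to_numpy(bool))
        base = baseline_metrics(y_test)
        reports[tp] = TimePointReport(
            tp, game_results, game_metrics, meta_metrics, base,
            config_tally(selections), meta_train, meta_test, meta_pred)

    report = PipelineReport(config.seed, label_map, reports)
    if config.out_dir is not None:
        _write_outputs(report, Path(config.out_dir))
    return report


def _write_outputs(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.json").write_text(report.summary_json())
    pred_dir = out_dir / "predictions"
    pred_dir.mkdir(exist_ok=True)
    for tp, rep in report.time_points.items():
        for game, res in rep.game_results.items():
            rows = [{"child_id": res.children[r.child_idx], "fold": r.outer_fold,
                     "probability": r.probability, "predicted": r.predicted,
                     "true": report.labels[res.children[r.child_idx]]}
                    for r in res.test_records]
            pd.DataFrame(rows).to_csv(pred_dir / f"{tp}_{game}.csv", index=False)
        rep.meta_predictions.assign(
            true=[report.labels[c] for c in rep.meta_predictions["child_id"]]
        ).to_csv(pred_dir / f"{tp}_quasi_svm.csv", index=False)
        rep.meta_train.to_csv(out_dir / f"{tp}_meta_train.csv", index=False)
        rep.meta_test.to_csv(out_dir / f"{tp}_meta_test.csv", index=False)
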