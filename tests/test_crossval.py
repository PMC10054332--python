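"""Metric suite, fold plans, and the nested cross-validation loop."""

import numpy as np
import pytest

from graphoscreen.crossval import (FoldPlan, baseline_metrics, config_tally,
                                   make_fold_plan, metrics, run_nested_cv)
from graphoscreen.errors import (InfeasibleStratificationError,
                                 InvalidInputError)


def vectors_from_counts(tp, fp, tn, fn):
    y_true = np.array([True] * tp + [False] * fp + [False] * tn + [True] * fn)
    y_pred = np.array([True] * tp + [True] * fp + [False] * tn + [False] * fn)
    return y_true, y_pred


class TestMetrics:
    def test_printed_worked_example_f1(self):
        # precision 100.00%, recall 6.25% (1 of 16 positives found, no FP)
        y_true, y_pred = vectors_from_counts(tp=1, fp=0, tn=88, fn=15)
        m = metrics(y_true, y_pred)
        assert m.precision == pytest.approx(100.0)
        assert m.recall == pytest.approx(6.25)
        assert round(m.f1, 2) == 11.76

    @pytest.mark.parametrize("neg,total,wprec,wf1", [
        (8359, 10000, 69.87, 76.12),
        (8209, 10000, 67.39, None),
    ])
    def test_all_negative_weighted_average_rows(self, neg, total, wprec, wf1):
        y_true = np.array([False] * neg + [True] * (total - neg))
        m = baseline_metrics(y_true)
        assert round(m.precision_wavg, 2) == wprec
        if wf1 is not None:
            assert round(m.f1_wavg, 2) == wf1
        assert m.accuracy == pytest.approx(100.0 * neg / total)

    def test_perfect_predictions(self):
        y = np.array([True, False, True, False])
        m = metrics(y, y)
        for fieldname in ("accuracy", "precision", "recall", "specificity",
                          "f1", "precision_wavg", "recall_wavg", "f1_wavg"):
            assert getattr(m, fieldname) == pytest.approx(100.0)

    def test_exhaustive_contingency_closed_forms(self):
        """Every 2x2 table with n <= 50 against direct arithmetic."""
        for n in range(1, 51):
            for tp in range(n + 1):
                for fp in range(n - tp + 1):
                    for tn in range(n - tp - fp + 1):
                        fn = n - tp - fp - tn
                        m = metrics(*vectors_from_counts(tp, fp, tn, fn))
                        assert m.confusion == (tp, fp, tn, fn)
                        acc = 100 * (tp + tn) / n
                        prec = 100 * tp / (tp + fp) if tp + fp else 0.0
                        rec = 100 * tp / (tp + fn) if tp + fn else 0.0
                        f1 = (2 * prec * rec / (prec + rec)
                              if prec + rec else 0.0)
                        assert m.accuracy == pytest.approx(acc)
                        assert m.precision == pytest.approx(prec)
                        assert m.recall == pytest.approx(rec)
                        assert m.f1 == pytest.approx(f1)

    def test_all_negative_identities_random_q(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 400))
            pos = int(rng.integers(1, n))
            y = np.zeros(n, bool)
            y[:pos] = True
            q = 1 - pos / n
            m = baseline_metrics(y)
            assert m.accuracy == pytest.approx(100 * q)
            assert m.precision_wavg == pytest.approx(100 * q * q)
            assert m.recall_wavg == pytest.approx(100 * q)
            assert m.f1_wavg == pytest.approx(200 * q * q / (1 + q))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            metrics(np.array([True]), np.array([True, False]))


class TestFoldPlan:
    def test_nested_structure_counts(self):
        y = np.array([True] * 10 + [False] * 40)
        plan = make_fold_plan(y, k=5, seed=0)
        assert len(plan.outer) == 5
        assert sum(len(inner) for inner in plan.inner) == 25

    def test_outer_folds_partition_cohort(self):
        y = np.array([True] * 10 + [False] * 40)
        plan = make_fold_plan(y, k=5, seed=1)
        seen = np.concatenate([te for _, te in plan.outer])
        assert sorted(seen) == list(range(50))

    def test_stratification_within_one(self):
        y = np.array([True] * 11 + [False] * 39)
        plan = make_fold_plan(y, k=5, seed=2)
        pos_counts = [y[te].sum() for _, te in plan.outer]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_inner_subsets_from_outer_train_only(self):
        y = np.array([True] * 10 + [False] * 40)
        plan = make_fold_plan(y, k=5, seed=3)
        for (tr, te), inner in zip(plan.outer, plan.inner):
            for val in inner:
                assert set(val) <= set(tr)
                assert y[val].any() and (~y[val]).any()

    def test_small_class_rejected(self):
        with pytest.raises(InfeasibleStratificationError):
            make_fold_plan(np.array([True] * 3 + [False] * 20), k=5, seed=0)


@pytest.fixture(scope="module")
def cv_setup(small_game_embeddings, small_labels):
    plan = FoldPlan(
        k=2,
        outer=[(np.arange(6, 12), np.arange(0, 6)),
               (np.arange(0, 6), np.arange(6, 12))],
        inner=[[np.array([6, 8]), np.array([7, 11])],
               [np.array([0, 2]), np.array([1, 5])]],
        seed=0)
    res = run_nested_cv(small_game_embeddings, small_labels, plan,
                        n_range=(2, 3))
    return plan, res


class TestNestedCV:
    def test_each_child_tested_exactly_once(self, cv_setup):
        _, res = cv_setup
        idx, _, _ = res.concatenated()
        assert sorted(idx) == list(range(12))

    def test_report_matches_concatenated_predictions(self, cv_setup,
                                                     small_labels):
        _, res = cv_setup
        idx, _, pred = res.concatenated()
        m = metrics(small_labels[idx], pred)
        assert m.as_dict() == res.report.as_dict()

    def test_no_test_label_leakage(self, small_game_embeddings, small_labels,
                                   cv_setup):
        """Permuting test-fold labels must leave that fold's fitted
        classifiers bit-identical."""
        plan, res = cv_setup
        permuted = small_labels.copy()
        te0 = plan.outer[0][1]
        # swap a positive and negative child inside outer test fold 0
        pos = te0[small_labels[te0]][0]
        neg = te0[~small_labels[te0]][0]
        permuted[pos], permuted[neg] = permuted[neg], permuted[pos]
        res2 = run_nested_cv(small_game_embeddings, permuted, plan,
                             n_range=(2, 3))
        assert res.selections[0] == res2.selections[0]
        assert res.selected_n[0] == res2.selected_n[0]
        for c1, c2 in zip(res.fold_classifiers[0], res2.fold_classifiers[0]):
            assert c1.probability_threshold == c2.probability_threshold
            for u1, u2 in zip(c1.units, c2.units):
                assert u1.distance_threshold == u2.distance_threshold
                np.testing.assert_array_equal(u1.average_landmarks.points,
                                              u2.average_landmarks.points)
        t1 = [r for r in res.test_records if r.outer_fold == 0]
        t2 = [r for r in res2.test_records if r.outer_fold == 0]
        assert [r.probability for r in t1] == [r.probability for r in t2]
        assert [r.predicted for r in t1] == [r.predicted for r in t2]


class TestConfigTally:
    def test_single_configuration(self):
        tally = config_tally([("weighted_sum", "time_order")] * 7)
        assert tally[("weighted_sum", "time_order")] == 1.0
        assert sum(tally.values()) == pytest.approx(1.0)

    def test_uniform_four(self):
        from graphoscreen.classifier import CONFIGURATIONS
        tally = config_tally(list(CONFIGURATIONS))
        assert all(v == pytest.approx(0.25) for v in tally.values())

    def test_against_counter_oracle(self):
        from collections import Counter
        rng = np.random.default_rng(1)
        from graphoscreen.classifier import CONFIGURATIONS
        log = [CONFIGURATIONS[i] for i in rng.integers(0, 4, 40)]
        tally = config_tally(log)
        counts = Counter(log)
        for cfg, frac in tally.items():
            assert frac == pytest.approx(counts.get(cfg, 0) / len(log))

    def test_empty_log_rejected(self):
        with pytest.raises(InvalidInputError):
            config_tally([])
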