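"""Threshold search and the voting risk classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphoscreen.classifier import (ClassifierConfig, ThresholdVotingModel,
                                     best_threshold, fit_risk_classifier)
from graphoscreen.embedding import GameEmbeddings
from graphoscreen.errors import DegenerateLabelsError


def exhaustive_best_f1(values, labels, rule="gt"):
    """Oracle: scan every candidate rule over midpoints and boundaries."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2
    if rule == "gt":
        cands = np.concatenate(([distinct[0] - 1], mids, [distinct[-1] + 1]))
    else:
        cands = np.unique(np.concatenate(([0.0], mids, [1.0])))
    best = 0.0
    for c in cands:
        pred = values > c if rule == "gt" else values >= c
        tp = np.sum(pred & labels)
        fp = np.sum(pred & ~labels)
        fn = np.sum(~pred & labels)
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        best = max(best, f1)
    return best


class TestBestThreshold:
    def test_separable_case(self):
        thr, f1 = best_threshold(np.array([1.0, 2, 9, 10]),
                                 np.array([0, 0, 1, 1], bool))
        assert thr == pytest.approx(5.5)
        assert f1 == 1.0

    def test_interleaved_matches_exhaustive(self):
        values = np.array([1.0, 2, 3, 4])
        labels = np.array([1, 0, 1, 0], bool)
        _, f1 = best_threshold(values, labels)
        assert f1 == pytest.approx(exhaustive_best_f1(values, labels))

    def test_all_equal_values_boundary_rules(self):
        values = np.full(6, 3.3)
        labels = np.array([1, 0, 0, 1, 0, 0], bool)
        _, f1 = best_threshold(values, labels)
        # all-positive rule: precision 1/3, recall 1 -> F1 = 0.5
        assert f1 == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            best_threshold(np.array([1.0, 2.0]), np.array([1, 1], bool))

    @given(st.lists(st.floats(min_value=0, max_value=10, allow_nan=False),
                    min_size=4, max_size=30),
           st.integers(min_value=0, max_value=10 ** 9))
    @settings(max_examples=80, deadline=None)
    def test_matches_exhaustive_scan_property(self, vals, label_seed):
        rng = np.random.default_rng(label_seed)
        labels = rng.random(len(vals)) < 0.4
        if labels.all() or not labels.any():
            labels[0] = True
            labels[-1] = False
        values = np.asarray(vals)
        _, f1 = best_threshold(values, labels)
        assert f1 == pytest.approx(exhaustive_best_f1(values, labels))

    def test_probability_rule_endpoints(self):
        probs = np.array([0.0, 0.25, 0.75, 1.0])
        labels = np.array([0, 0, 1, 1], bool)
        thr, f1 = best_threshold(probs, labels, rule="ge")
        assert 0.0 <= thr <= 1.0
        assert f1 == 1.0


class TestFitRiskClassifier:
    def test_separates_frequency_coded_classes(self, small_game_embeddings,
                                               small_labels):
        model = ThresholdVotingModel(small_game_embeddings, small_labels,
                                     ClassifierConfig("weighted_sum",
                                                      "time_order", 3))
        res = model.fit()
        assert res.training_f1 >= 0.7
        assert "Threshold-voting" in res.summary()
        probs = res.predict_proba()
        assert np.all((probs >= 0) & (probs <= 1))

    def test_probabilities_rational_in_unit_count(self, small_game_embeddings,
                                                  small_labels):
        res = fit_risk_classifier(small_game_embeddings, small_labels,
                                  ClassifierConfig("abs_weighted_mean",
                                                   "value_order", 3))
        u = len(res.units)
        probs = res.predict_proba()
        probs = probs[np.isfinite(probs)]
        np.testing.assert_allclose(np.round(probs * u), probs * u, atol=1e-9)

    def test_all_negative_labels_rejected(self, small_game_embeddings):
        with pytest.raises(DegenerateLabelsError):
            fit_risk_classifier(small_game_embeddings,
                                np.zeros(12, dtype=bool),
                                ClassifierConfig("weighted_sum",
                                                 "time_order", 2))

    def test_identical_children_forced_degeneracy(self, small_game_embeddings):
        ge = small_game_embeddings
        omega = np.repeat(ge.omega[:, :1, :], 12, axis=1)
        phi = np.repeat(ge.phi[:, :1, :], 12, axis=1)
        p = np.repeat(ge.p[:, :1, :], 12, axis=1)
        clones = GameEmbeddings(ge.time_point, ge.game, ge.children, ge.units,
                                omega, phi, p, np.zeros((4, 12)))
        labels = np.array([True] * 3 + [False] * 9)
        res = fit_risk_classifier(clones, labels,
                                  ClassifierConfig("weighted_sum",
                                                   "time_order", 2))
        probs = res.predict_proba()
        assert np.allclose(probs, probs[0])
        # all probabilities equal -> best constant rule: all-positive F1
        assert res.training_f1 == pytest.approx(2 * 3 / (2 * 3 + 9), abs=1e-9)

    def test_train_then_predict_round_trip(self, small_game_embeddings,
                                           small_labels):
        from graphoscreen.classifier import _f1_from_preds

        res = fit_risk_classifier(small_game_embeddings, small_labels,
                                  ClassifierConfig("weighted_sum",
                                                   "value_order", 3))
        preds = res.predict()
        assert _f1_from_preds(small_labels, preds) == pytest.approx(
            res.training_f1)

    def test_child_order_invariance(self, small_game_embeddings, small_labels):
        ge = small_game_embeddings
        perm = np.random.default_rng(0).permutation(12)
        ge_perm = GameEmbeddings(ge.time_point, ge.game,
                                 [ge.children[i] for i in perm], ge.units,
                                 ge.omega[:, perm], ge.phi[:, perm],
                                 ge.p[:, perm], ge.recon_mse[:, perm])
        cfg = ClassifierConfig("abs_weighted_mean", "time_order", 3)
        r1 = fit_risk_classifier(ge, small_labels, cfg)
        r2 = fit_risk_classifier(ge_perm, small_labels[perm], cfg)
        assert r1.probability_threshold == pytest.approx(
            r2.probability_threshold)
        np.testing.assert_allclose(r1.predict_proba()[perm],
                                   r2.predict_proba(), atol=1e-12)
        for u1, u2 in zip(r1.units, r2.units):
            assert u1.distance_threshold == pytest.approx(u2.distance_threshold)

    def test_predict_child_self_distance(self, small_game_embeddings,
                                         small_labels):
        res = fit_risk_classifier(small_game_embeddings, small_labels,
                                  ClassifierConfig("weighted_sum",
                                                   "time_order", 3))
        child = {(u.id_label, u.feature):
                 small_game_embeddings.signal(
                     [i for i, un in enumerate(small_game_embeddings.units)
                      if un == (u.id_label, u.feature)][0], 0)
                 for u in res.units}
        prob, _ = res.predict_child(child)
        assert prob == pytest.approx(res.predict_proba(np.array([0]))[0])

    def test_serialization_round_trip(self, small_game_embeddings,
                                      small_labels, tmp_path):
        import json

        res = fit_risk_classifier(small_game_embeddings, small_labels,
                                  ClassifierConfig("weighted_sum",
                                                   "time_order", 3))
        path = tmp_path / "clf.json"
        res.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["config"]["n_landmarks"] == 3
        assert len(payload["units"]) == len(res.units)
        assert payload["probability_threshold"] == res.probability_threshold
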