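"""Nearest-template posture classifier: training, decision rule, evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wss.features import extract_features, window_posture_truth
from wss.postures import gravity_template, orientation_table
from wss.posture import (
    PostureModel,
    classify,
    classify_batch,
    confusion_from_labels,
    evaluate,
    train,
    train_from_recording,
)
from wss.simulate import NoiseModel, generate_calibration, generate_randomized_test


def test_noise_free_training_recovers_canonical_templates(silent_calibration):
    model = train_from_recording(silent_calibration)
    canonical = PostureModel.canonical()
    assert np.allclose(model.templates, canonical.templates, atol=1e-12)


def test_training_with_accel_noise_stays_within_2_degrees():
    """Pure sensor noise (SD 0.05 g, no placement jitter) averages out to
    leave each template within 2 degrees of its canonical direction."""
    calib = generate_calibration(NoiseModel(orientation_jitter_sd=0.0, seed=12))
    model = train_from_recording(calib)
    canonical = PostureModel.canonical()
    cos = np.clip(
        np.einsum("msx,msx->ms", model.templates, canonical.templates), -1, 1
    )
    assert np.degrees(np.arccos(cos)).max() < 2.0


def test_training_rejects_missing_posture(silent_calibration):
    feats = extract_features(silent_calibration)
    labels, valid = window_posture_truth(silent_calibration)
    keep = valid & (labels != 5)
    with pytest.raises(ValueError, match="posture 5"):
        train(feats.vectors[keep], labels[keep])


def test_antipodal_perturbations_cancel_in_training():
    """Two feature vectors per posture perturbed symmetrically about the
    canonical direction train back to the canonical template."""
    rng = np.random.default_rng(0)
    vecs, labels = [], []
    for m in range(1, 9):
        base = gravity_template(m)
        d = rng.normal(0, 0.1, (3, 3))
        d -= (d * base).sum(axis=1, keepdims=True) * base  # orthogonal to base
        for sign in (+1, -1):
            v = base + sign * d
            vecs.append(v / np.linalg.norm(v, axis=1, keepdims=True))
            labels.extend([m])
    model = train(np.array(vecs), np.array(labels))
    assert np.allclose(model.templates, PostureModel.canonical().templates, atol=1e-12)


def test_exact_template_classifies_with_zero_distance():
    model = PostureModel.canonical()
    label, scores = classify(model, model.templates[4])
    assert label == 5
    assert scores[4] == pytest.approx(0.0, abs=1e-12)


def _rotate_towards(v_from, v_to, deg):
    # v_from and v_to are orthogonal unit vectors here
    th = math.radians(deg)
    return math.cos(th) * v_from + math.sin(th) * v_to


def test_feature_between_pair_templates_goes_to_nearer_one():
    model = PostureModel.canonical()
    t1, t2 = model.templates[0].copy(), model.templates[1]
    assert abs(np.dot(t1[2], t2[2])) < 1e-9  # right forearms are orthogonal
    feat = t1.copy()
    feat[2] = _rotate_towards(t1[2], t2[2], 40.0)
    label, scores = classify(model, feat)
    # explicit angular sums: 40 deg to posture 1, 50 deg to posture 2
    assert scores[0] == pytest.approx(math.radians(40.0))
    assert scores[1] == pytest.approx(math.radians(50.0))
    assert label == 1


def test_equidistant_feature_breaks_tie_to_lower_index():
    model = PostureModel.canonical()
    t3, t4 = model.templates[2], model.templates[3]
    feat = t3.copy()
    for s in range(3):
        if abs(np.dot(t3[s], t4[s])) < 1e-9:
            feat[s] = _rotate_towards(t3[s], t4[s], 45.0)
    label, scores = classify(model, feat)
    assert scores[2] == pytest.approx(scores[3])
    assert label == 3


def test_classify_rejects_non_unit_features():
    model = PostureModel.canonical()
    with pytest.raises(ValueError, match="unit-norm"):
        classify(model, np.full((3, 3), 0.5))


def test_classify_matches_brute_force_oracle(rng):
    """Vectorized decision agrees with an explicit loop over all 8 postures."""
    model = train_from_recording(generate_calibration(NoiseModel(seed=2)))
    feats = rng.normal(size=(200, 3, 3))
    feats /= np.linalg.norm(feats, axis=2, keepdims=True)
    predicted = classify_batch(model, feats)
    for feat, pred in zip(feats, predicted):
        best, best_score = None, None
        for p in range(8):
            score = 0.0
            for s in range(3):
                dot = min(1.0, max(-1.0, float(np.dot(feat[s], model.templates[p, s]))))
                score += math.acos(dot)
            if best_score is None or score < best_score - 1e-15:
                best, best_score = p + 1, score
        assert pred == best


def test_confusion_arithmetic_for_within_pair_swap():
    """All posture-1 windows predicted as 2 (rest correct): 8-class accuracy
    drops to 87.5% while the 4-class accuracy stays 100%."""
    truth = np.repeat(np.arange(1, 9), 10)
    pred = truth.copy()
    pred[truth == 1] = 2
    res = confusion_from_labels(truth, pred)
    assert res.accuracy_8 == pytest.approx(87.5)
    assert res.accuracy_4 == pytest.approx(100.0)
    assert res.matrix.sum() == 80
    assert (res.matrix.sum(axis=1) == 10).all()


def test_perfect_predictions_give_diagonal_matrix():
    truth = np.repeat(np.arange(1, 9), 5)
    res = confusion_from_labels(truth, truth)
    assert res.accuracy_8 == res.accuracy_4 == 100.0
    assert np.array_equal(res.matrix, np.diag([5] * 8))


@given(
    truth=st.lists(st.integers(1, 8), min_size=1, max_size=200),
    pred=st.lists(st.integers(1, 8), min_size=200, max_size=200),
)
def test_collapse_monotonicity(truth, pred):
    """4-class accuracy is never below 8-class accuracy."""
    t = np.array(truth)
    p = np.array(pred[: len(t)])
    res = confusion_from_labels(t, p)
    assert res.accuracy_4 >= res.accuracy_8


def test_noise_free_round_trip_is_perfect(silent_calibration, silent_noise):
    model = train_from_recording(silent_calibration)
    test = generate_randomized_test(silent_noise, seed=9)
    res = evaluate(model, test)
    assert res.accuracy_8 == 100.0
    assert res.accuracy_4 == 100.0


def test_confusability_concentrates_within_pairs_as_offset_shrinks():
    """With the within-pair forearm offset shrunk to 8 degrees, classification
    errors land (almost) exclusively inside the within-pair blocks, mirroring
    the difficulty of separating postures 1 and 2."""
    table = orientation_table(pair_offset_deg=8.0)
    noise = NoiseModel(seed=17)
    calib = generate_calibration(noise, orientations=table)
    model = train_from_recording(calib)
    test = generate_randomized_test(NoiseModel(seed=18), seed=18, orientations=table)
    res = evaluate(model, test)
    within_pair_err = sum(
        res.matrix[i, j]
        for i in range(8)
        for j in range(8)
        if i != j and i // 2 == j // 2
    )
    cross_pair_err = res.matrix.sum() - np.trace(res.matrix) - within_pair_err
    assert within_pair_err > 0
    assert cross_pair_err == 0
    assert res.accuracy_4 == 100.0
    assert res.accuracy_8 < 100.0


def test_evaluate_requires_evaluable_windows(silent_calibration):
    model = train_from_recording(silent_calibration)
    import copy

    rec = copy.copy(silent_calibration)
    rec.posture_truth = np.zeros_like(rec.posture_truth)
    with pytest.raises(ValueError, match="evaluable"):
        evaluate(model, rec)
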