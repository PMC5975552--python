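"""Calibration-trained posture classifier and confusion-matrix evaluation.

The classifier is a nearest-template rule on gravity directions: training
averages the calibration feature vectors of each minor posture into a
template triple (trunk, left forearm, right forearm), and classification
assigns a window to the posture minimizing the sum of the three angular
distances between feature and template components.  Ties go to the lowest
posture index.  The rule is deterministic and fully auditable — every
decision exposes its eight distance scores.

Evaluation scores held postures only: windows that straddle a posture switch
or overlap a transition burst are excluded.  Accuracy is reported on the
8-minor-posture scale and, after collapsing pairs onto the four major
postures (right / supine / left / prone), on the 4-major scale.  Collapsing
can only merge errors, so the 4-class accuracy is always >= the 8-class one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSet, extract_features, window_posture_truth
from .postures import MAJORS, MINOR_POSTURES, gravity_template
from .simulate import LabeledRecording

__all__ = [
    "PostureModel",
    "ConfusionResult",
    "train",
    "train_from_recording",
    "classify",
    "classify_batch",
    "evaluate",
    "confusion_from_labels",
    "combine_results",
    "format_confusion_percent",
]

_UNIT_TOL = 1e-6


@dataclass
class PostureModel:
    """Per-posture gravity-direction templates.

    templates has shape (8, 3, 3): minor postures 1..8 (row order), sensors
    (trunk, left_forearm, right_forearm), xyz.  Every 3-vector is unit-norm.
    sensor_weights allows re-weighting the per-sensor angular distances in
    classification (equal by default).
    """

    templates: np.ndarray
    sensor_weights: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.sensor_weights = np.asarray(self.sensor_weights, dtype=float)
        if self.templates.shape != (8, 3, 3):
            raise ValueError("templates must have shape (8, 3, 3)")
        norms = np.linalg.norm(self.templates, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("template components must be unit-norm")

    @classmethod
    def canonical(cls, pair_offset_deg: float = 90.0) -> "PostureModel":
        """The noise-free model: templates equal the canonical gravity triples."""
        return cls(np.stack([gravity_template(m, pair_offset_deg) for m in MINOR_POSTURES]))


def train(features: FeatureSet | np.ndarray, labels: np.ndarray) -> PostureModel:
    """Train templates as normalized per-posture means of calibration features.

    Every minor posture 1..8 must be represented by at least one feature
    vector; otherwise the missing posture is named in the error.
    """
    vectors = features.vectors if isinstance(features, FeatureSet) else np.asarray(features)
    labels = np.asarray(labels, dtype=int)
    if len(vectors) != len(labels):
        raise ValueError("features and labels must have equal length")
    templates = np.empty((8, 3, 3))
    for m in MINOR_POSTURES:
        sel = vectors[labels == m]
        if len(sel) == 0:
            raise ValueError(f"calibration is missing posture {m}")
        mean = sel.mean(axis=0)
        norms = np.linalg.norm(mean, axis=1, keepdims=True)
        if norms.min() < 1e-9:
            raise ValueError(f"degenerate mean feature for posture {m}")
        templates[m - 1] = mean / norms
    return PostureModel(templates)


def train_from_recording(
    recording: LabeledRecording, window: float = 2.0, step: float = 0.5
) -> PostureModel:
    """Extract features from a labelled calibration pass and train on the
    evaluable (single-posture) windows."""
    feats = extract_features(recording, window, step)
    labels, valid = window_posture_truth(recording, window, step)
    return train(feats.vectors[valid], labels[valid])


def _angular_distances(model: PostureModel, vectors: np.ndarray) -> np.ndarray:
    """(n, 8) weighted summed angular distances (radians) to each template."""
    norms = np.linalg.norm(vectors, axis=2)
    if not np.allclose(norms, 1.0, atol=_UNIT_TOL):
        raise ValueError("feature components must be unit-norm")
    # cos of angle between each feature sensor-vector and each template's.
    cos = np.einsum("nsx,msx->nms", vectors, model.templates)
    ang = np.arccos(np.clip(cos, -1.0, 1.0))
    return ang @ model.sensor_weights


def classify(model: PostureModel, feature: np.ndarray) -> tuple[int, np.ndarray]:
    """Classify one feature triple; returns (minor label, per-posture scores).

    The label is the argmin of the summed angular distances; np.argmin breaks
    ties toward the lowest posture index.
    """
    feature = np.asarray(feature, dtype=float).reshape(1, 3, 3)
    scores = _angular_distances(model, feature)[0]
    return int(np.argmin(scores)) + 1, scores


def classify_batch(model: PostureModel, features: FeatureSet | np.ndarray) -> np.ndarray:
    """Minor posture labels for a batch of feature triples."""
    vectors = features.vectors if isinstance(features, FeatureSet) else np.asarray(features)
    scores = _angular_distances(model, vectors)
    return np.argmin(scores, axis=1) + 1


@dataclass
class ConfusionResult:
    """8x8 confusion matrix (rows = truth, columns = predicted) and accuracies.

    accuracy_8 / accuracy_4 are percentages; the 4-class figures apply the
    fixed minor->major collapse map to both truth and prediction.  When built
    by :func:`combine_results` the per-subject accuracy lists are populated.
    """

    matrix: np.ndarray
    accuracy_8: float
    accuracy_4: float
    n_windows: int
    per_subject_accuracy_8: list[float] | None = None
    per_subject_accuracy_4: list[float] | None = None

    @property
    def matrix_4(self) -> np.ndarray:
        m4 = np.zeros((4, 4), dtype=int)
        for i in range(8):
            for j in range(8):
                m4[i // 2, j // 2] += self.matrix[i, j]
        return m4


def confusion_from_labels(truth: np.ndarray, predicted: np.ndarray) -> ConfusionResult:
    """Build a ConfusionResult from aligned minor-posture label arrays."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted label arrays must align")
    if len(truth) == 0:
        raise ValueError("no evaluable windows")
    matrix = np.zeros((8, 8), dtype=int)
    np.add.at(matrix, (truth - 1, predicted - 1), 1)
    total = matrix.sum()
    acc8 = 100.0 * np.trace(matrix) / total
    acc4 = 100.0 * ((truth - 1) // 2 == (predicted - 1) // 2).mean()
    return ConfusionResult(matrix=matrix, accuracy_8=acc8, accuracy_4=acc4, n_windows=int(total))


def evaluate(
    model: PostureModel,
    recording: LabeledRecording,
    window: float = 2.0,
    step: float = 0.5,
) -> ConfusionResult:
    """Score a labelled test recording window-by-window.

    Windows overlapping transition bursts or posture switches are excluded;
    the remaining windows are classified and tallied against truth.
    """
    feats = extract_features(recording, window, step)
    labels, valid = window_posture_truth(recording, window, step)
    if not valid.any():
        raise ValueError("recording contains no evaluable (single-posture) windows")
    predicted = classify_batch(model, feats.vectors[valid])
    return confusion_from_labels(labels[valid], predicted)


def combine_results(results: list[ConfusionResult]) -> ConfusionResult:
    """Pool per-subject confusion results; accuracies are pooled-window, the
    per-subject lists carry the individual figures."""
    if not results:
        raise ValueError("no results to combine")
    matrix = np.sum([r.matrix for r in results], axis=0)
    total = matrix.sum()
    acc8 = 100.0 * np.trace(matrix) / total
    m4 = np.zeros((4, 4), dtype=int)
    for i in range(8):
        for j in range(8):
            m4[i // 2, j // 2] += matrix[i, j]
    acc4 = 100.0 * np.trace(m4) / total
    return ConfusionResult(
        matrix=matrix,
        accuracy_8=acc8,
        accuracy_4=acc4,
        n_windows=int(total),
        per_subject_accuracy_8=[r.accuracy_8 for r in results],
        per_subject_accuracy_4=[r.accuracy_4 for r in results],
    )


def format_confusion_percent(matrix: np.ndarray) -> str:
    """Row-normalized percentage confusion matrix as a printable table."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    names = (
        [f"{i + 1}" for i in range(8)] if n == 8 else list(MAJORS[:n])
    )
    rows = ["truth\\pred  " + "  ".join(f"{c:>6s}" for c in names)]
    for i in range(n):
        total = matrix[i].sum()
        pct = matrix[i] / total * 100.0 if total else np.zeros(n)
        rows.append(f"{names[i]:>10s}  " + "  ".join(f"{v:6.1f}" for v in pct))
    return "\n".join(rows)
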