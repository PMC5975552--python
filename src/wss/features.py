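"""Orientation features for posture classification.

Postures are static holds, so the low-pass (window-mean) accelerometer signal
of each sensor points along gravity in that sensor's frame.  The feature for
a window is therefore the triple of unit gravity-direction vectors for
(trunk, left forearm, right forearm) — nine numbers per window.  Heading
(magnetometer) is excluded by default: the postures differ in roll/pitch, and
compass heading depends on bed orientation, not posture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .postures import LOCATIONS
from .simulate import LabeledRecording

__all__ = [
    "FeatureSet",
    "gravity_direction",
    "extract_features",
    "sliding_window_starts",
    "window_mean",
    "window_sd",
    "window_posture_truth",
    "window_stage_truth",
]


@dataclass
class FeatureSet:
    """Per-window gravity-direction features.

    vectors has shape (n_windows, 3 sensors, 3); sensor order is
    (trunk, left_forearm, right_forearm).  centers are window-center times in
    seconds.  window/step record the extraction parameters.
    """

    centers: np.ndarray
    vectors: np.ndarray
    window: float
    step: float

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def flat(self) -> np.ndarray:
        """(n_windows, 9) view: trunk xyz, left-forearm xyz, right-forearm xyz."""
        return self.vectors.reshape(len(self), 9)


def gravity_direction(accel_window: np.ndarray) -> np.ndarray:
    """Unit gravity direction of a static accelerometer window.

    Returns the normalized per-axis mean of the (n, 3) window.  Raises on an
    (near-)all-zero mean, which indicates free fall or degenerate input
    rather than a static hold.
    """
    accel_window = np.asarray(accel_window, dtype=float)
    if accel_window.ndim != 2 or accel_window.shape[1] != 3 or len(accel_window) == 0:
        raise ValueError("accel_window must be a non-empty (n, 3) array")
    mean = accel_window.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-9:
        raise ValueError("degenerate accelerometer window: mean acceleration is zero")
    return mean / norm


def sliding_window_starts(
    n_samples: int, rate: float, window: float, step: float
) -> tuple[np.ndarray, int]:
    """Start indices and window length (samples) for half-open sliding windows.

    Windows cover [start, start + window) and are placed every ``step``
    seconds while they fit entirely inside the recording.
    """
    wn = int(round(window * rate))
    sn = int(round(step * rate))
    if wn < 2:
        raise ValueError("window must span at least 2 samples")
    if sn < 1:
        raise ValueError("step must span at least 1 sample")
    if n_samples < wn:
        return np.empty(0, dtype=int), wn
    starts = np.arange(0, n_samples - wn + 1, sn)
    return starts, wn


def window_mean(x: np.ndarray, starts: np.ndarray, wn: int) -> np.ndarray:
    """Mean of x over each window [s, s + wn); x is 1-D."""
    c = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    return (c[starts + wn] - c[starts]) / wn


def window_sd(x: np.ndarray, starts: np.ndarray, wn: int) -> np.ndarray:
    """Population SD of x over each window [s, s + wn); x is 1-D."""
    m = window_mean(x, starts, wn)
    c2 = np.concatenate(([0.0], np.cumsum(np.asarray(x, dtype=float) ** 2)))
    var = (c2[starts + wn] - c2[starts]) / wn - m**2
    return np.sqrt(np.clip(var, 0.0, None))


def _require_locations(recording: LabeledRecording) -> None:
    for loc in LOCATIONS:
        if loc not in recording.streams:
            raise ValueError(f"recording is missing sensor location '{loc}'")


def extract_features(
    recording: LabeledRecording, window: float = 2.0, step: float = 0.5
) -> FeatureSet:
    """Gravity-direction features over sliding windows of a 3-sensor recording."""
    _require_locations(recording)
    starts, wn = sliding_window_starts(recording.n_samples, recording.rate, window, step)
    centers = starts / recording.rate + window / 2.0
    vectors = np.empty((len(starts), 3, 3))
    for si, loc in enumerate(LOCATIONS):
        accel = recording.streams[loc].accel
        means = np.stack([window_mean(accel[:, a], starts, wn) for a in range(3)], axis=1)
        norms = np.linalg.norm(means, axis=1)
        # A window straddling an antipodal posture switch can average to a
        # zero vector; such windows carry no orientation and are marked NaN
        # (they are never evaluable, so downstream scoring skips them).
        degenerate = norms < 1e-9
        norms[degenerate] = np.nan
        vectors[:, si, :] = means / norms[:, None]
    return FeatureSet(centers=centers, vectors=vectors, window=window, step=step)


def window_posture_truth(
    recording: LabeledRecording, window: float = 2.0, step: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window posture truth labels and an evaluability mask.

    A window is evaluable only when every sample in it carries the same
    non-zero minor posture label, i.e. it neither straddles a posture switch
    nor overlaps a transition burst.
    """
    starts, wn = sliding_window_starts(recording.n_samples, recording.rate, window, step)
    truth = recording.posture_truth
    labels = np.zeros(len(starts), dtype=int)
    valid = np.zeros(len(starts), dtype=bool)
    for i, s in enumerate(starts):
        seg = truth[s : s + wn]
        first = seg[0]
        if first != 0 and (seg == first).all():
            labels[i] = first
            valid[i] = True
    return labels, valid


def window_stage_truth(
    recording: LabeledRecording, window: float = 2.0, step: float = 0.5
) -> np.ndarray:
    """Per-window stage truth: the stage code at each window's center sample."""
    if recording.stage_truth is None:
        raise ValueError("recording carries no stage truth")
    starts, wn = sliding_window_starts(recording.n_samples, recording.rate, window, step)
    return recording.stage_truth[starts + wn // 2]
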