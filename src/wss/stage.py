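"""Activity-based sleep staging: combined coefficient of variation,
threshold classification and time-in-phase summaries.

The activity metric for a window is the *combined coefficient of variation*
across all nine accelerometer axes of the three sensors: each axis
contributes SD / (denominator + eps), and the nine contributions are
averaged.  By default the denominator is the magnitude of that sensor's
window-mean acceleration vector (about 1 g during a hold), so the combined
value is essentially the within-window acceleration SD expressed relative to
gravity — near zero at rest and rising with movement.  A per-axis |mean|
denominator (the literal axis-wise CoV) is available via
``denominator="axis_mean"``, but note that axes lying across gravity have
near-zero means, which makes that variant orientation-dependent.

Stages are assigned by a nested threshold rule on the combined CoV value v:

    v > high         -> 3 (awake)
    low < v <= high  -> 2 (sleep)
    v <= low         -> 1 (REM)

with defaults high = 0.14 and low = 0.058.  The rule is a monotone step
function; a value exactly at a threshold falls to the lower stage.
Subject-specific thresholds can be derived from a labelled slice as
midpoints between the per-stage mean activities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import sliding_window_starts, window_mean, window_sd
from .postures import LOCATIONS
from .simulate import STAGE_NAMES, LabeledRecording

__all__ = [
    "ActivitySeries",
    "StageSeries",
    "StageThresholds",
    "PhaseSummary",
    "activity_series",
    "stage_from_activity",
    "derive_thresholds",
    "time_in_phase",
    "stage_accuracy",
]


@dataclass(frozen=True)
class StageThresholds:
    """Awake (high) and REM/sleep (low) activity thresholds."""

    high: float = 0.14
    low: float = 0.058

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"thresholds must satisfy 0 < low < high, got low={self.low}, high={self.high}"
            )


@dataclass
class ActivitySeries:
    """Windowed combined-CoV activity values (dimensionless, >= 0)."""

    centers: np.ndarray
    values: np.ndarray
    window: float
    step: float

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class StageSeries:
    """Per-window sleep-stage codes: 1 = REM, 2 = sleep, 3 = awake."""

    centers: np.ndarray
    stages: np.ndarray

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class PhaseSummary:
    """Window counts and percentage of time per stage."""

    counts: dict[int, int]
    percent: dict[int, float]
    total: int

    @property
    def percent_rem(self) -> float:
        return self.percent[1]

    @property
    def percent_sleep(self) -> float:
        return self.percent[2]

    @property
    def percent_awake(self) -> float:
        return self.percent[3]

    def to_dict(self) -> dict:
        return {
            "total_windows": self.total,
            **{
                f"percent_{STAGE_NAMES[c]}": self.percent[c] for c in (3, 2, 1)
            },
            **{f"count_{STAGE_NAMES[c]}": self.counts[c] for c in (3, 2, 1)},
        }


def activity_series(
    recording: LabeledRecording,
    window: float = 2.0,
    step: float = 0.5,
    eps: float = 0.01,
    denominator: str = "sensor_norm",
    combine: str = "mean",
) -> ActivitySeries:
    """Combined coefficient-of-variation activity over sliding windows.

    Parameters
    ----------
    eps
        Guard (g) added to the denominator so free-fall/degenerate windows
        stay finite.
    denominator
        "sensor_norm" (default): each axis SD is divided by the norm of that
        sensor's window-mean acceleration vector; "axis_mean": divided by the
        absolute window mean of the axis itself.
    combine
        "mean" (default) or "sum" of the nine axis contributions.
    """
    if denominator not in ("sensor_norm", "axis_mean"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if combine not in ("mean", "sum"):
        raise ValueError(f"unknown combine mode {combine!r}")
    for loc in LOCATIONS:
        if loc not in recording.streams:
            raise ValueError(f"recording is missing sensor location '{loc}'")
    starts, wn = sliding_window_starts(recording.n_samples, recording.rate, window, step)
    centers = starts / recording.rate + window / 2.0
    contribs = []
    for loc in LOCATIONS:
        accel = recording.streams[loc].accel
        means = np.stack([window_mean(accel[:, a], starts, wn) for a in range(3)], axis=1)
        sds = np.stack([window_sd(accel[:, a], starts, wn) for a in range(3)], axis=1)
        if denominator == "sensor_norm":
            denom = np.linalg.norm(means, axis=1, keepdims=True) + eps
        else:
            denom = np.abs(means) + eps
        contribs.append(sds / denom)
    axes = np.concatenate(contribs, axis=1)  # (n_windows, 9)
    values = axes.mean(axis=1) if combine == "mean" else axes.sum(axis=1)
    return ActivitySeries(centers=centers, values=values, window=window, step=step)


def stage_from_activity(
    values: np.ndarray | float, thresholds: StageThresholds = StageThresholds()
) -> np.ndarray | int:
    """Nested threshold rule mapping activity to stage codes {1, 2, 3}."""
    scalar = np.isscalar(values)
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("activity values must be non-negative")
    stages = np.where(v > thresholds.high, 3, np.where(v > thresholds.low, 2, 1))
    return int(stages) if scalar else stages


def derive_thresholds(values: np.ndarray, stage_truth: np.ndarray) -> StageThresholds:
    """Subject-specific thresholds as midpoints of per-stage typical activity.

    low = midpoint of the REM and sleep levels, high = midpoint of the sleep
    and awake levels, where each stage's level is the *median* of its window
    activities.  The median rather than the mean is used because windows that
    straddle a posture flip can carry extreme CoV values (the window-mean
    acceleration passes through zero), and a single such window would drag a
    mean-based threshold across the bulk of the stage's distribution.  All
    three stages must be represented and their levels ordered REM < sleep <
    awake; otherwise the levels are reported in the error.
    """
    values = np.asarray(values, dtype=float)
    stage_truth = np.asarray(stage_truth, dtype=int)
    if values.shape != stage_truth.shape:
        raise ValueError("values and stage_truth must align")
    levels = {}
    for code in (1, 2, 3):
        sel = values[stage_truth == code]
        if len(sel) == 0:
            raise ValueError(f"no windows labelled stage {code} ({STAGE_NAMES[code]})")
        levels[code] = float(np.median(sel))
    if not (levels[1] < levels[2] < levels[3]):
        raise ValueError(
            "stage activity levels are not separable (need REM < sleep < awake): "
            f"rem={levels[1]:.4g}, sleep={levels[2]:.4g}, awake={levels[3]:.4g}"
        )
    return StageThresholds(low=(levels[1] + levels[2]) / 2.0, high=(levels[2] + levels[3]) / 2.0)


def time_in_phase(stages: StageSeries | np.ndarray) -> PhaseSummary:
    """Fraction of windows (or samples) spent in each stage."""
    arr = stages.stages if isinstance(stages, StageSeries) else np.asarray(stages, dtype=int)
    if len(arr) == 0:
        raise ValueError("empty stage series")
    total = len(arr)
    counts = {c: int((arr == c).sum()) for c in (1, 2, 3)}
    percent = {c: 100.0 * counts[c] / total for c in (1, 2, 3)}
    return PhaseSummary(counts=counts, percent=percent, total=total)


def stage_accuracy(predicted: StageSeries | np.ndarray, truth: StageSeries | np.ndarray) -> float:
    """Percent of windows where predicted and true stage agree."""
    p = predicted.stages if isinstance(predicted, StageSeries) else np.asarray(predicted)
    t = truth.stages if isinstance(truth, StageSeries) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("predicted and truth stage series must align")
    if len(p) == 0:
        raise ValueError("empty stage series")
    return float(100.0 * (p == t).mean())
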