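"""Plain-text I/O for recordings, features, models and derived series.

All artifacts are CSV or JSON.  A recording on disk is a directory holding
one CSV per sensor (``trunk.csv``, ``left_forearm.csv``,
``right_forearm.csv``) with header ``t,ax,ay,az,gx,gy,gz,mx,my,mz`` (t in
seconds to 6 decimal places; accel in g, gyro in deg/s, mag in unit field),
plus an optional ``truth.csv`` with header ``t,posture,stage`` where the
posture field is empty during transition bursts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .postures import LOCATIONS
from .simulate import LabeledRecording, SensorStream
from .stage import ActivitySeries, StageSeries

__all__ = [
    "RecordingFormatError",
    "write_recording",
    "read_recording",
    "write_features",
    "write_model",
    "read_model",
    "write_confusion",
    "write_activity",
    "read_activity",
    "write_stages",
    "read_stages",
    "write_json",
]

STREAM_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]

#: Maximum tolerated deviation of any sampling interval from the median.
RATE_DRIFT_TOL = 0.01


class RecordingFormatError(ValueError):
    """A recording file violates the stream schema."""


def _stream_frame(stream: SensorStream) -> pd.DataFrame:
    data = {"t": [f"{x:.6f}" for x in stream.t]}
    for prefix, arr in (("a", stream.accel), ("g", stream.gyro), ("m", stream.mag)):
        for i, axis in enumerate("xyz"):
            data[f"{prefix}{axis}"] = [f"{v:.9g}" for v in arr[:, i]]
    return pd.DataFrame(data)


def write_recording(recording: LabeledRecording, outdir: str | Path) -> Path:
    """Write one CSV per sensor plus a truth CSV; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for loc in LOCATIONS:
        _stream_frame(recording.streams[loc]).to_csv(outdir / f"{loc}.csv", index=False)
    t = recording.streams[LOCATIONS[0]].t
    posture = ["" if p == 0 else str(int(p)) for p in recording.posture_truth]
    truth = pd.DataFrame({"t": [f"{x:.6f}" for x in t], "posture": posture})
    if recording.stage_truth is not None:
        truth["stage"] = recording.stage_truth.astype(int)
    else:
        truth["stage"] = ""
    truth.to_csv(outdir / "truth.csv", index=False)
    return outdir


def _read_stream(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise RecordingFormatError(f"missing sensor file '{path.name}'")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise RecordingFormatError(f"cannot parse '{path.name}': {exc}") from exc
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingFormatError(
            f"'{path.name}' is missing column(s) {', '.join(repr(c) for c in missing)}"
        )
    df = df[STREAM_COLUMNS]
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise RecordingFormatError(f"malformed row {int(bad[0]) + 2} in '{path.name}'")
    return df


def _validate_time(t: np.ndarray, name: str) -> float:
    dt = np.diff(t)
    nonmono = np.nonzero(dt <= 0)[0]
    if len(nonmono):
        raise RecordingFormatError(
            f"non-monotone time at row {int(nonmono[0]) + 3} in '{name}'"
        )
    med = float(np.median(dt))
    drift = np.abs(dt - med) / med
    bad = np.nonzero(drift > RATE_DRIFT_TOL)[0]
    if len(bad):
        raise RecordingFormatError(
            f"sampling-interval drift > {RATE_DRIFT_TOL:.0%} at row {int(bad[0]) + 3} "
            f"in '{name}'"
        )
    return 1.0 / med


def read_recording(path: str | Path) -> LabeledRecording:
    """Read and validate a recording directory; truth tracks are optional."""
    path = Path(path)
    streams: dict[str, SensorStream] = {}
    rate = None
    t0 = None
    for loc in LOCATIONS:
        df = _read_stream(path / f"{loc}.csv")
        t = df["t"].to_numpy(dtype=float)
        if len(t) < 2:
            raise RecordingFormatError(f"'{loc}.csv' holds fewer than 2 samples")
        r = _validate_time(t, f"{loc}.csv")
        if rate is None:
            rate, t0 = r, t
        elif not np.allclose(t, t0, atol=1e-6):
            raise RecordingFormatError(f"time base of '{loc}.csv' differs from '{LOCATIONS[0]}.csv'")
        streams[loc] = SensorStream(
            location=loc,
            rate=rate,
            t=t,
            accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
            gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
            mag=df[["mx", "my", "mz"]].to_numpy(dtype=float),
        )
    n = len(t0)
    truth_path = path / "truth.csv"
    posture_truth = np.zeros(n, dtype=int)
    stage_truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        for col in ("t", "posture"):
            if col not in truth.columns:
                raise RecordingFormatError(f"'truth.csv' is missing column '{col}'")
        if len(truth) != n:
            raise RecordingFormatError(
                f"'truth.csv' has {len(truth)} rows but streams have {n} samples"
            )
        posture_truth = truth["posture"].fillna(0).to_numpy(dtype=float).astype(int)
        if "stage" in truth.columns and truth["stage"].notna().all():
            stage_truth = truth["stage"].to_numpy(dtype=float).astype(int)
    return LabeledRecording(
        streams=streams, rate=float(rate), posture_truth=posture_truth, stage_truth=stage_truth
    )


def write_features(features, path: str | Path) -> None:
    """Feature CSV: t,trunk_x,...,rf_z (9 unit-vector components per window)."""
    cols = ["trunk", "lf", "rf"]
    data = {"t": features.centers}
    flat = features.flat
    for si, c in enumerate(cols):
        for ai, axis in enumerate("xyz"):
            data[f"{c}_{axis}"] = flat[:, 3 * si + ai]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_model(model, path: str | Path) -> None:
    """Plain-text posture model: one row per minor posture, 9 template values."""
    lines = ["posture trunk_x trunk_y trunk_z lf_x lf_y lf_z rf_x rf_y rf_z"]
    for m in range(8):
        vals = " ".join(f"{v:.12g}" for v in model.templates[m].ravel())
        lines.append(f"{m + 1} {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path):
    from .posture import PostureModel

    raw = np.loadtxt(path, skiprows=1)
    if raw.shape != (8, 10):
        raise ValueError("posture model file must hold 8 rows of 10 columns")
    order = np.argsort(raw[:, 0])
    return PostureModel(raw[order, 1:].reshape(8, 3, 3))


def write_confusion(result, path: str | Path) -> None:
    """Confusion-matrix counts as CSV (rows = truth 1..8, cols = predicted)."""
    df = pd.DataFrame(
        result.matrix,
        index=[f"true_{i + 1}" for i in range(8)],
        columns=[f"pred_{j + 1}" for j in range(8)],
    )
    df.to_csv(path)


def write_activity(series: ActivitySeries, path: str | Path) -> None:
    pd.DataFrame({"t": series.centers, "activity": series.values}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_activity(path: str | Path, window: float = 2.0, step: float = 0.5) -> ActivitySeries:
    df = pd.read_csv(path)
    return ActivitySeries(
        centers=df["t"].to_numpy(float),
        values=df["activity"].to_numpy(float),
        window=window,
        step=step,
    )


def write_stages(series: StageSeries, path: str | Path) -> None:
    pd.DataFrame({"t": series.centers, "stage": series.stages.astype(int)}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_stages(path: str | Path) -> StageSeries:
    df = pd.read_csv(path)
    return StageSeries(
        centers=df["t"].to_numpy(float), stages=df["stage"].to_numpy(int)
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
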