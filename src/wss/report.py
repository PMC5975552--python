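"""End-to-end pipeline runs and machine-readable session reports.

The proof-of-concept run replays the full study workflow for one synthetic
subject: simulate a calibration pass, train the posture classifier, simulate
the staged sleep protocol, derive subject-specific activity thresholds from
the first labelled occurrence of each stage, classify postures and stages
window-by-window, and emit a self-describing JSON report (timelines,
time-in-phase summary, confusion matrix, thresholds, provenance).

Cohort helpers repeat the posture and staging experiments across several
independently seeded synthetic subjects and report per-subject and mean
accuracies; they are the basis of the package's headline evaluation numbers.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import __version__
from .features import extract_features, window_posture_truth, window_stage_truth
from .postures import MAJORS, major_index
from .posture import (
    ConfusionResult,
    classify_batch,
    combine_results,
    confusion_from_labels,
    evaluate,
    train_from_recording,
)
from .simulate import (
    STAGE_CODES,
    LabeledRecording,
    NoiseModel,
    ProtocolSpec,
    generate_calibration,
    generate_randomized_test,
    generate_sleep_protocol,
)
from .stage import (
    StageSeries,
    StageThresholds,
    activity_series,
    derive_thresholds,
    stage_accuracy,
    stage_from_activity,
    time_in_phase,
)

__all__ = [
    "DEFAULT_CONFIG",
    "SessionReport",
    "run_proof_of_concept",
    "posture_cohort",
    "stage_cohort",
    "first_stage_window_mask",
    "subject_seeds",
]

DEFAULT_CONFIG: dict = {
    "rate": 50.0,
    "hold": 10.0,
    "window": 2.0,
    "step": 0.5,
    "noise": {},  # NoiseModel field overrides
    "protocol": {},  # ProtocolSpec field overrides
    "activity": {"eps": 0.01, "denominator": "sensor_norm", "combine": "mean"},
    "thresholds": "derived",  # or {"low": ..., "high": ...}
    "subject": {},
}


def merge_config(config: dict | None) -> dict:
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def noise_from_config(config: dict, seed: int | None = None) -> NoiseModel:
    kwargs = dict(config.get("noise", {}))
    if seed is not None:
        kwargs["seed"] = int(seed)
    return NoiseModel(**kwargs)


def protocol_from_config(config: dict) -> ProtocolSpec:
    return ProtocolSpec(**config.get("protocol", {}))


def subject_seeds(seed: int, n: int) -> np.ndarray:
    """n deterministic per-subject seeds (< 2^31) derived from one base seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def first_stage_window_mask(protocol: ProtocolSpec, centers: np.ndarray) -> np.ndarray:
    """Mask of windows lying in the first occurrence of each distinct stage.

    Used to derive subject-specific thresholds from a labelled slice: with
    the default sequence A,B,C,B,C,B,A this selects the first three segments.
    """
    seen: dict[str, int] = {}
    for i, letter in enumerate(protocol.stage_sequence):
        seen.setdefault(letter, i)
    mask = np.zeros(len(centers), dtype=bool)
    for i in seen.values():
        t0 = i * protocol.stage_duration
        mask |= (centers >= t0) & (centers < t0 + protocol.stage_duration)
    return mask


@dataclass
class SessionReport:
    """Self-describing record of one pipeline run (JSON-serializable)."""

    subject: dict
    provenance: dict
    parameters: dict
    thresholds: dict
    posture: dict
    stage: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _config_hash(config: dict, seed: int) -> str:
    canon = json.dumps({"config": config, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_proof_of_concept(config: dict | None = None, seed: int = 0) -> SessionReport:
    """Calibration -> posture model -> protocol -> staging, for one subject."""
    cfg = merge_config(config)
    rate, hold = float(cfg["rate"]), float(cfg["hold"])
    window, step = float(cfg["window"]), float(cfg["step"])
    act_cfg = cfg["activity"]
    protocol = protocol_from_config(cfg)
    seeds = subject_seeds(seed, 2)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"proof-of-concept stage '{name}' failed: {exc}") from exc

    calib = _stage(
        "simulate-calibration",
        generate_calibration,
        noise_from_config(cfg, seed=int(seeds[0])),
        rate,
        hold,
    )
    model = _stage("train-posture-model", train_from_recording, calib, window, step)
    recording = _stage(
        "simulate-protocol",
        generate_sleep_protocol,
        protocol,
        noise_from_config(cfg, seed=int(seeds[1])),
        rate,
    )

    # Posture arm: classify evaluable windows of the protocol recording.
    feats = _stage("extract-features", extract_features, recording, window, step)
    truth_labels, valid = window_posture_truth(recording, window, step)
    predicted = _stage("classify-postures", classify_batch, model, feats.vectors[valid])
    confusion = _stage(
        "score-postures", confusion_from_labels, truth_labels[valid], predicted
    )
    posture_timeline = [
        [round(float(t), 3), int(p), MAJORS[major_index(int(p))]]
        for t, p in zip(feats.centers[valid], predicted)
    ]

    # Stage arm: activity, thresholds, per-window staging.
    activity = _stage(
        "compute-activity",
        activity_series,
        recording,
        window,
        step,
        act_cfg["eps"],
        act_cfg["denominator"],
        act_cfg["combine"],
    )
    stage_truth = window_stage_truth(recording, window, step)
    if cfg["thresholds"] == "derived":
        mask = first_stage_window_mask(protocol, activity.centers)
        thresholds = _stage(
            "derive-thresholds", derive_thresholds, activity.values[mask], stage_truth[mask]
        )
    else:
        thresholds = StageThresholds(**cfg["thresholds"])
    stages = stage_from_activity(activity.values, thresholds)
    agreement = stage_accuracy(stages, stage_truth)
    phase_pred = time_in_phase(stages)
    phase_truth = time_in_phase(stage_truth)
    stage_timeline = [
        [round(float(t), 3), int(s)] for t, s in zip(activity.centers, stages)
    ]

    params = {
        "rate": rate,
        "hold": hold,
        "window": window,
        "step": step,
        "activity": act_cfg,
        "noise": asdict(noise_from_config(cfg)),
        "protocol": {
            "stage_sequence": list(protocol.stage_sequence),
            "stage_duration": protocol.stage_duration,
            "major_transition_period_awake": protocol.major_transition_period_awake,
            "minor_transition_period_sleep": protocol.minor_transition_period_sleep,
        },
    }
    return SessionReport(
        subject=dict(cfg.get("subject", {})),
        provenance={
            "version": __version__,
            "seed": int(seed),
            "config_hash": _config_hash(cfg, seed),
        },
        parameters=params,
        thresholds={"low": thresholds.low, "high": thresholds.high},
        posture={
            "timeline": posture_timeline,
            "n_windows": int(valid.sum()),
            "n_excluded_windows": int((~valid).sum()),
            "confusion_matrix": confusion.matrix.tolist(),
            "accuracy_8": confusion.accuracy_8,
            "accuracy_4": confusion.accuracy_4,
        },
        stage={
            "timeline": stage_timeline,
            "n_windows": len(activity),
            "agreement_percent": agreement,
            "phase_predicted": phase_pred.to_dict(),
            "phase_truth": phase_truth.to_dict(),
        },
    )


def posture_cohort(
    n_subjects: int = 10,
    seed: int = 1,
    noise: NoiseModel | None = None,
    rate: float = 50.0,
    hold: float = 10.0,
    window: float = 2.0,
    step: float = 0.5,
) -> dict:
    """Train-on-calibration / evaluate-on-randomized-test for a synthetic cohort.

    Each subject gets independent seeds for its calibration and test passes.
    Returns per-subject and mean 4-class / 8-class accuracies plus the pooled
    confusion result.
    """
    base = NoiseModel() if noise is None else noise
    seeds = subject_seeds(seed, 2 * n_subjects)
    results: list[ConfusionResult] = []
    for i in range(n_subjects):
        calib = generate_calibration(replace(base, seed=int(seeds[2 * i])), rate, hold)
        model = train_from_recording(calib, window, step)
        test = generate_randomized_test(replace(base, seed=int(seeds[2 * i + 1])), rate, hold)
        results.append(evaluate(model, test, window, step))
    combined = combine_results(results)
    return {
        "n_subjects": n_subjects,
        "per_subject_accuracy_4": combined.per_subject_accuracy_4,
        "per_subject_accuracy_8": combined.per_subject_accuracy_8,
        "mean_accuracy_4": float(np.mean(combined.per_subject_accuracy_4)),
        "mean_accuracy_8": float(np.mean(combined.per_subject_accuracy_8)),
        "combined": combined,
    }


def stage_cohort(
    n_subjects: int = 5,
    seed: int = 1,
    noise: NoiseModel | None = None,
    protocol: ProtocolSpec | None = None,
    rate: float = 50.0,
    window: float = 2.0,
    step: float = 0.5,
    eps: float = 0.01,
    denominator: str = "sensor_norm",
    combine: str = "mean",
) -> dict:
    """Protocol staging with per-subject derived thresholds for a cohort.

    Thresholds come from the first labelled occurrence of each stage; all
    windows are then classified and compared with center-sample truth.
    """
    base = NoiseModel() if noise is None else noise
    protocol = ProtocolSpec() if protocol is None else protocol
    seeds = subject_seeds(seed, n_subjects)
    agreements: list[float] = []
    phases_pred: list[dict] = []
    phase_truth: dict | None = None
    for i in range(n_subjects):
        rec = generate_sleep_protocol(protocol, replace(base, seed=int(seeds[i])), rate)
        act = activity_series(rec, window, step, eps, denominator, combine)
        truth = window_stage_truth(rec, window, step)
        mask = first_stage_window_mask(protocol, act.centers)
        thr = derive_thresholds(act.values[mask], truth[mask])
        pred = stage_from_activity(act.values, thr)
        agreements.append(stage_accuracy(pred, truth))
        phases_pred.append(time_in_phase(pred).to_dict())
        if phase_truth is None:
            phase_truth = time_in_phase(truth).to_dict()
    return {
        "n_subjects": n_subjects,
        "per_subject_agreement": agreements,
        "mean_agreement": float(np.mean(agreements)),
        "phase_predicted": phases_pred,
        "phase_truth": phase_truth,
    }
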