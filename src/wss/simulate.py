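"""Synthetic three-sensor IMU recordings for sleep-posture and sleep-stage studies.

Generates labelled 9-DoF streams (accelerometer in g, gyroscope in deg/s,
magnetometer in unit field) for three body-worn sensors (trunk and both
forearms) under three protocols:

* a **calibration pass** — the eight minor postures held in ascending order;
* a **randomized test pass** — sixteen holds, each minor posture twice, in a
  seeded random order;
* a **staged sleep protocol** — awake (A) / sleep (B) / REM (C) segments in
  the sequence A, B, C, B, C, B, A of 2 min each, with major posture changes
  every 30 s while awake, minor (within-pair) changes every minute while
  asleep, and no movement during REM.

Static holds obey |accel| = 1 g exactly when noise-free.  Posture changes are
instantaneous orientation switches wrapped in a short burst of elevated
accelerometer/gyroscope noise; the downstream activity metric measures
variance, so burst energy rather than trajectory fidelity is what matters.

Randomness is drawn from a single ``numpy`` Generator per recording in a
fixed, documented order (see :func:`_render_holds`), so a seed fully
determines the output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .postures import LOCATIONS, MINOR_POSTURES, orientation_table

__all__ = [
    "GRAVITY_W",
    "MAG_FIELD_W",
    "STAGE_CODES",
    "STAGE_NAMES",
    "SensorStream",
    "LabeledRecording",
    "NoiseModel",
    "ProtocolSpec",
    "Transition",
    "generate_calibration",
    "generate_randomized_test",
    "generate_sleep_protocol",
]

#: World-frame gravity direction (g units).
GRAVITY_W = np.array([0.0, 0.0, -1.0])

#: World-frame magnetic reference direction (unit norm, 30 deg inclination).
MAG_FIELD_W = np.array([0.0, 0.8660254037844386, -0.5])

#: Protocol stage letter -> stage code (1 = REM, 2 = sleep, 3 = awake).
STAGE_CODES = {"A": 3, "B": 2, "C": 1}

#: Stage code -> descriptive name.
STAGE_NAMES = {1: "rem", 2: "sleep", 3: "awake"}


@dataclass
class SensorStream:
    """Time-ordered 9-DoF samples from one sensor location.

    accel is in g, gyro in deg/s, mag in arbitrary unit-field units; all are
    (n, 3) arrays sharing the time base ``t`` (seconds, constant interval).
    """

    location: str
    rate: float
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class Transition:
    """A posture change in a protocol recording."""

    t: float
    kind: str  # "major" or "minor"
    minor_before: int
    minor_after: int


@dataclass
class LabeledRecording:
    """Three aligned sensor streams plus per-sample ground truth.

    posture_truth holds the minor posture label (1..8) per sample, 0 where no
    posture is defined (during transition bursts).  stage_truth holds stage
    codes {1, 2, 3} per sample, or None for recordings without a staged
    protocol.
    """

    streams: dict[str, SensorStream]
    rate: float
    posture_truth: np.ndarray
    stage_truth: np.ndarray | None = None
    transitions: list[Transition] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.posture_truth)

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


def _default_tremor() -> dict[str, float]:
    return {"rem": 0.015, "sleep": 0.07, "awake": 0.16}


@dataclass(frozen=True)
class NoiseModel:
    """Noise and movement-variability parameters for the simulator.

    accel_noise_sd (g) and orientation_jitter_sd (degrees) apply to static
    posture passes; stage_tremor_sd gives the *total* short-time
    accelerometer variability during each simulated sleep stage (it stands in
    for both residual body movement and sensor noise, and supersedes
    accel_noise_sd inside protocol segments).  Transitions add a burst of
    transition_burst_sd (quadrature) for transition_burst_duration seconds.
    """

    accel_noise_sd: float = 0.05
    orientation_jitter_sd: float = 3.0
    gyro_noise_sd: float = 0.5
    mag_noise_sd: float = 0.02
    stage_tremor_sd: Mapping[str, float] = field(default_factory=_default_tremor)
    transition_burst_duration: float = 2.0
    transition_burst_sd: float = 0.3
    transition_gyro_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "accel_noise_sd",
            "orientation_jitter_sd",
            "gyro_noise_sd",
            "mag_noise_sd",
            "transition_burst_duration",
            "transition_burst_sd",
            "transition_gyro_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for stage, sd in self.stage_tremor_sd.items():
            if stage not in STAGE_NAMES.values():
                raise ValueError(f"unknown stage name {stage!r} in stage_tremor_sd")
            if sd < 0:
                raise ValueError(f"stage_tremor_sd[{stage!r}] must be non-negative")

    def silent_sensors(self) -> "NoiseModel":
        """Copy with all *measurement* noise zeroed (tremor and bursts kept)."""
        return replace(
            self,
            accel_noise_sd=0.0,
            orientation_jitter_sd=0.0,
            gyro_noise_sd=0.0,
            mag_noise_sd=0.0,
        )

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        """A fully noise-free model (static physics checks)."""
        return cls(
            accel_noise_sd=0.0,
            orientation_jitter_sd=0.0,
            gyro_noise_sd=0.0,
            mag_noise_sd=0.0,
            stage_tremor_sd={"rem": 0.0, "sleep": 0.0, "awake": 0.0},
            transition_burst_sd=0.0,
            transition_gyro_sd=0.0,
            seed=seed,
        )


@dataclass(frozen=True)
class ProtocolSpec:
    """Staged sleep protocol: stage letters, durations and transition periods."""

    stage_sequence: Sequence[str] = ("A", "B", "C", "B", "C", "B", "A")
    stage_duration: float = 120.0
    major_transition_period_awake: float = 30.0
    minor_transition_period_sleep: float = 60.0

    def __post_init__(self) -> None:
        for s in self.stage_sequence:
            if s not in STAGE_CODES:
                raise ValueError(f"unknown stage letter {s!r}: expected A, B or C")
        if self.stage_duration <= 0:
            raise ValueError("stage_duration must be positive")
        if self.major_transition_period_awake <= 0 or self.minor_transition_period_sleep <= 0:
            raise ValueError("transition periods must be positive")

    @property
    def total_duration(self) -> float:
        return len(self.stage_sequence) * self.stage_duration


def _check_rate_hold(rate: float, hold: float) -> None:
    if rate <= 0:
        raise ValueError("rate must be positive")
    if hold <= 0:
        raise ValueError("hold must be positive")


def _render_holds(
    rng: np.random.Generator,
    rate: float,
    n_total: int,
    holds: list[tuple[int, int, int]],
    accel_sd: np.ndarray,
    gyro_sd: np.ndarray,
    noise: NoiseModel,
    orientations: dict[int, dict[str, Rotation]],
) -> dict[str, SensorStream]:
    """Render the three sensor streams for a sequence of posture holds.

    holds is a list of (start_index, stop_index, minor_label); accel_sd and
    gyro_sd are per-sample noise standard deviations.

    RNG draw order (fixed so seeds are portable): for each sensor in
    LOCATIONS order — one 3-vector orientation-jitter draw per hold, then the
    full accel noise array, then gyro, then mag.
    """
    t = np.arange(n_total) / rate
    jitter_rad = np.deg2rad(noise.orientation_jitter_sd)
    streams: dict[str, SensorStream] = {}
    for loc in LOCATIONS:
        grav = np.empty((n_total, 3))
        magv = np.empty((n_total, 3))
        for start, stop, minor in holds:
            rot = orientations[minor][loc]
            # One jitter draw per hold regardless of magnitude keeps the RNG
            # stream layout identical across noise settings.
            jv = jitter_rad * rng.standard_normal(3)
            rot = Rotation.from_rotvec(jv) * rot
            grav[start:stop] = rot.apply(GRAVITY_W)
            magv[start:stop] = rot.apply(MAG_FIELD_W)
        accel = grav + accel_sd[:, None] * rng.standard_normal((n_total, 3))
        gyro = gyro_sd[:, None] * rng.standard_normal((n_total, 3))
        mag = magv + noise.mag_noise_sd * rng.standard_normal((n_total, 3))
        streams[loc] = SensorStream(loc, rate, t, accel, gyro, mag)
    return streams


def _static_pass(
    labels: Sequence[int],
    noise: NoiseModel,
    rate: float,
    hold: float,
    rng: np.random.Generator,
    orientations: dict[int, dict[str, Rotation]] | None,
) -> LabeledRecording:
    if orientations is None:
        orientations = orientation_table()
    n_hold = int(round(hold * rate))
    n_total = n_hold * len(labels)
    holds = [(i * n_hold, (i + 1) * n_hold, int(lab)) for i, lab in enumerate(labels)]
    accel_sd = np.full(n_total, noise.accel_noise_sd)
    gyro_sd = np.full(n_total, noise.gyro_noise_sd)
    streams = _render_holds(rng, rate, n_total, holds, accel_sd, gyro_sd, noise, orientations)
    posture_truth = np.repeat(np.asarray(labels, dtype=int), n_hold)
    return LabeledRecording(streams=streams, rate=rate, posture_truth=posture_truth)


def generate_calibration(
    noise: NoiseModel,
    rate: float = 50.0,
    hold: float = 10.0,
    orientations: dict[int, dict[str, Rotation]] | None = None,
) -> LabeledRecording:
    """Calibration pass: minor postures 1..8 in order, each held ``hold`` seconds."""
    _check_rate_hold(rate, hold)
    rng = np.random.default_rng(noise.seed)
    return _static_pass(MINOR_POSTURES, noise, rate, hold, rng, orientations)


def generate_randomized_test(
    noise: NoiseModel,
    rate: float = 50.0,
    hold: float = 10.0,
    seed: int | None = None,
    orientations: dict[int, dict[str, Rotation]] | None = None,
) -> LabeledRecording:
    """Randomized test pass: 16 holds, each minor posture exactly twice.

    The hold order is a seeded permutation; ``seed`` overrides the noise
    model's seed when given.
    """
    _check_rate_hold(rate, hold)
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    order = rng.permutation(np.repeat(MINOR_POSTURES, 2))
    return _static_pass(order, noise, rate, hold, rng, orientations)


def _protocol_timeline(
    protocol: ProtocolSpec, rng: np.random.Generator, initial_minor: int = 3
) -> list[Transition]:
    """Draw the posture-transition timeline for a protocol run.

    Awake (A) segments switch to a uniformly chosen *different* major posture
    every major_transition_period_awake seconds; sleep (B) segments toggle to
    the pair partner every minor_transition_period_sleep seconds; REM (C)
    segments have no transitions.  A transition falling exactly on a segment
    boundary is suppressed (the segment ends first).
    """
    transitions: list[Transition] = []
    current = initial_minor
    eps = 1e-9
    for i, letter in enumerate(protocol.stage_sequence):
        t0 = i * protocol.stage_duration
        t1 = t0 + protocol.stage_duration
        if letter == "A":
            period = protocol.major_transition_period_awake
            k = 1
            while t0 + k * period < t1 - eps:
                major_idx = (current - 1) // 2
                new_major = (major_idx + 1 + int(rng.integers(3))) % 4
                new_minor = 2 * new_major + 1 + int(rng.integers(2))
                transitions.append(Transition(t0 + k * period, "major", current, new_minor))
                current = new_minor
                k += 1
        elif letter == "B":
            period = protocol.minor_transition_period_sleep
            k = 1
            while t0 + k * period < t1 - eps:
                partner = current + 1 if current % 2 == 1 else current - 1
                transitions.append(Transition(t0 + k * period, "minor", current, partner))
                current = partner
                k += 1
    return transitions


def generate_sleep_protocol(
    protocol: ProtocolSpec,
    noise: NoiseModel,
    rate: float = 50.0,
    seed: int | None = None,
    initial_minor: int = 3,
    orientations: dict[int, dict[str, Rotation]] | None = None,
) -> LabeledRecording:
    """Simulate the staged sleep protocol with per-sample stage/posture truth.

    Per-sample accelerometer noise SD equals the tremor level of the current
    stage; samples inside a transition burst get the burst SD added in
    quadrature and carry no posture truth (label 0).  RNG order: protocol
    timeline draws first, then sensor rendering (see :func:`_render_holds`).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if orientations is None:
        orientations = orientation_table()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    transitions = _protocol_timeline(protocol, rng, initial_minor)

    n_total = int(round(protocol.total_duration * rate))
    n_stage = int(round(protocol.stage_duration * rate))
    stage_truth = np.empty(n_total, dtype=int)
    for i, letter in enumerate(protocol.stage_sequence):
        stage_truth[i * n_stage : (i + 1) * n_stage] = STAGE_CODES[letter]

    # Posture holds between transitions.
    bounds = [0] + [int(round(tr.t * rate)) for tr in transitions] + [n_total]
    minors = [initial_minor] + [tr.minor_after for tr in transitions]
    holds = [(bounds[i], bounds[i + 1], minors[i]) for i in range(len(minors))]
    posture_truth = np.empty(n_total, dtype=int)
    for start, stop, minor in holds:
        posture_truth[start:stop] = minor

    # Burst mask: elevated noise, no posture truth.
    burst = np.zeros(n_total, dtype=bool)
    n_burst = int(round(noise.transition_burst_duration * rate))
    for tr in transitions:
        s = int(round(tr.t * rate))
        burst[s : min(s + n_burst, n_total)] = True
    posture_truth[burst] = 0

    tremor = np.array([noise.stage_tremor_sd[STAGE_NAMES[c]] for c in (1, 2, 3)])
    accel_sd = tremor[stage_truth - 1]
    accel_sd = np.where(burst, np.hypot(accel_sd, noise.transition_burst_sd), accel_sd)
    gyro_sd = np.full(n_total, noise.gyro_noise_sd)
    gyro_sd = np.where(burst, np.hypot(gyro_sd, noise.transition_gyro_sd), gyro_sd)

    streams = _render_holds(rng, rate, n_total, holds, accel_sd, gyro_sd, noise, orientations)
    return LabeledRecording(
        streams=streams,
        rate=rate,
        posture_truth=posture_truth,
        stage_truth=stage_truth,
        transitions=transitions,
    )
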