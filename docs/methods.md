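# Methods

## Scope and model

The package analyses recordings from three body-worn 9-DoF IMUs (trunk, left
forearm, right forearm) for two purposes: recognising which of eight sleeping
postures the wearer holds, and estimating sleep stage (awake / sleep / REM)
from movement. Both tasks assume the wearer is recumbent and that postures
are *static holds* separated by brief movements — the regime of natural
sleep, not of ambulation. No deposited human recordings accompany the
platform, so the package ships a simulator that emulates the study protocols
and serves as the test bed for the analytics; everything downstream of the
simulator operates identically on real CSV streams.

## Coordinate conventions and the posture table

World frame: Z up, Y toward the head of the bed. In the reference pose
(supine, arms parallel) all sensor frames coincide with the world frame, so
supine is the identity orientation and a static sensor reads gravity
(0, 0, −1) g. The eight minor postures are encoded as fixed world→sensor
rotations: the trunk rolls about the body long axis by −90° (right lateral),
0° (supine), +90° (left lateral) or 180° (prone); forearm orientations equal
the trunk's, except that the second member of each major pair carries an
additional 90° rotation about the forearm long axis (right forearm for
posture 2, left for 6, both for 4 and 7). The 90° default mirrors the real
distinction between the paired postures — a 90° shoulder rotation of one
arm — and is configurable (`pair_offset_deg`), which the test suite uses to
confirm that shrinking the offset concentrates classification errors inside
the within-pair blocks of the confusion matrix. The numeric table itself is a
design choice: the postures are defined photographically in the source
protocol, and any orthonormal assignment with these qualitative properties
yields the same analytics behaviour.

## Simulator

Sampling rate defaults to 50 Hz (the platform's rate is unspecified; 50 Hz is
typical for wearable posture work and comfortably resolves 2-s analysis
windows). Accelerometer output is the posture's gravity direction in the
sensor frame plus i.i.d. Gaussian noise; gyroscope output is zero-mean noise
(plus a variance pulse during transitions); magnetometer output is a rotated
unit reference field plus noise, generated for format completeness but unused
by the default features. Noise parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `accel_noise_sd` | 0.05 g | per-axis accel noise during posture passes |
| `orientation_jitter_sd` | 3° | per-hold, per-sensor placement/compliance error |
| `stage_tremor_sd` | REM 0.015 g, sleep 0.07 g, awake 0.16 g | total accel variability per stage |
| `transition_burst_duration` | 2 s | movement burst wrapping each posture change |
| `transition_burst_sd` | 0.3 g | burst accel SD (added in quadrature) |

Orientation jitter is drawn once per hold per sensor (a small random
rotation), modelling imperfect re-enactment of a posture rather than sensor
noise. During protocol segments the stage tremor SD *replaces*
`accel_noise_sd`: it is defined as the total short-time variability of the
stage, inclusive of sensor noise, which makes the activity metric ≈ tremor SD
and places the three stages on the intended sides of the published 0.058 and
0.14 thresholds. Transitions are instantaneous orientation switches wrapped
in a noise burst — the downstream metric is variance, so burst energy, not
trajectory realism, is what matters. A transition falling exactly on a stage
boundary is suppressed to keep truth labels unambiguous; burst samples carry
no posture truth. RNG draw order (timeline first, then per sensor: jitter per
hold, accel, gyro, mag) is fixed so a seed pins the output bit-for-bit.

What the simulator does **not** model: biomechanical movement arcs,
soft-tissue artifacts, sensor drift/bias, heart-rate or respiratory
micro-movement, and real inter-subject behavioural variability. Passing
cohort benchmarks on synthetic subjects therefore demonstrates the
correctness and calibration of the *pipeline* under the stated noise
conditions, not clinical performance on human data — the published human
cohort numbers serve as the benchmarks the synthetic conditions are designed
to meet or exceed.

## Features and posture classification

Features are per-window unit gravity directions (normalized window-mean
acceleration) for the three sensors; windows are 2 s long with 0.5 s step
(≥ 17 training vectors per 10-s calibration hold). Magnetometer heading is
excluded by default: the postures differ in roll/pitch, and heading depends
on bed orientation. No gyro fusion filter is used — holds are static, so
low-pass gravity extraction suffices; fusion is an extension point for
dynamic use. A window whose samples do not share a single posture label
(posture switches, movement bursts) is flagged non-evaluable; a window whose
mean acceleration vanishes (possible when straddling an antipodal switch) is
marked NaN rather than inventing a direction.

Training averages each posture's calibration features and renormalizes;
classification is nearest-template under summed per-sensor angular distance
with ties to the lower index and equal sensor weights (configurable). This
rule was chosen over learned classifiers because it is deterministic, needs
only the calibration pass, and exposes all eight distance scores for audit.
Scoring is per-window with equal weight; accuracy is reported on the 8-class
scale and after the fixed pair collapse onto 4 major postures (collapse can
only merge errors, so 4-class ≥ 8-class on any input).

## Activity metric and staging

Activity per window is the combined coefficient of variation over the nine
accelerometer axes. Each axis contributes SD / (‖sensor window-mean accel‖ +
ε) with ε = 0.01 g, and the contributions are averaged (`combine="sum"` and a
literal per-axis |mean| denominator are available as options). The sensor-
magnitude denominator is the deliberate design choice: axes lying across
gravity have near-zero means, so a per-axis denominator turns the metric into
a function of orientation rather than movement, while normalizing by the
≈ 1 g gravity magnitude yields a clean movement measure on the scale the
published thresholds (0.058, 0.14) assume. ε guards degenerate (free-fall or
flip-straddling) windows.

The nested rule maps activity v to stage 3 (awake) if v > high, 2 (sleep) if
low < v ≤ high, else 1 (REM). A value exactly at a threshold falls to the
lower stage — the published rule leaves equality undefined, and assigning
downward closes the gap deterministically while keeping the rule a monotone
step function. No smoothing is applied by default (pure per-window
thresholding); a median filter is a documented extension, off by default.

Subject-specific thresholds are derived from a labelled slice (the first
occurrence of each stage in the protocol) as midpoints between per-stage
activity levels, where a stage's level is the **median** of its window
activities. The median is used instead of the mean because windows straddling
a 180° posture flip carry extreme CoV values (the window-mean acceleration
passes through zero and the denominator collapses to ε); a single such window
can drag a mean-based midpoint across the bulk of the awake distribution,
while the median is unaffected. For the symmetric distributions used in the
worked examples the two coincide.

Expected residual staging error is structural, not incidental: the protocol
*permits* limb movement every minute during sleep, and those movement bursts
are genuinely high-activity, so a variance-based stager labels them awake
(≈ 21 of 1677 windows in a default run), plus a few windows straddling stage
boundaries. This caps per-window agreement near 98.6% under default
conditions — comfortably above the 97.3% benchmark, and the same error mode
that limits the published system.

## Numerical choices and degenerate inputs

Window statistics use cumulative sums (population SD, exact for the
alternating-sign closed-form test); angular distances clip dot products into
[−1, 1] before arccos; non-unit feature vectors are rejected rather than
silently normalized. Recordings read from CSV are validated for schema,
monotone time and sampling-interval drift (> 1% of the median interval is
rejected, with the offending row named). Stage truth for a window is the
stage of its center sample. Cohort experiments derive per-subject seeds from
one base seed via `numpy.random.SeedSequence`, so a single integer reproduces
an entire cohort.

## Problem sizes

Benchmarks run 10 synthetic subjects for the posture experiment (one
calibration and one randomized test pass each at 50 Hz) and 5 for the staging
experiment (one 14-minute protocol each) — matching the cohort sizes behind
the published per-task results. Each experiment completes in well under a
minute on a laptop core; the sizes are study-design choices, and larger
cohorts only narrow the Monte-Carlo spread of the cohort means.

## Known limitations

- The posture classifier assumes per-subject calibration; cross-subject
  generalization is untested and not claimed.
- The activity thresholds are convention-dependent: with a different window
  length, combination rule or denominator the published constants do not
  transfer, which is why threshold derivation from labelled data is built in.
- The simulator's clean separation of stage tremor levels makes the staging
  task easier than real sleep, where stage-dependent movement distributions
  overlap; derived-threshold agreement on synthetic cohorts is an upper bound.
- No attitude estimation is performed; only gravity direction is used, so
  rotations about the gravity axis are invisible to the classifier.
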