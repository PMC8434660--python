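# Methods

`gaitpath` estimates spatiotemporal gait parameters and center-of-mass sway
from a single RGB-D camera's 25-joint skeletal stream, for subjects walking
straight toward the sensor along a short (~2.7 m) analysis path. This note
documents the model, the numerical choices, the synthetic-data generator and
its ground-truth definition, and the known limitations.

## Coordinate frame and data model

All positions are in the sensor frame: x lateral (+ toward the subject's
left as seen by the sensor), y vertical up, z depth away from the sensor;
origin at the sensor, which is assumed mounted roughly at hip height
(~1 m above the floor) and level. Units are meters and seconds throughout;
the file dialects carry no unit fields by design (a single-unit policy
prevents silent mm/m mix-ups). The joint vocabulary is the fixed 25-name
Kinect-v2 skeleton; missing or untracked joints carry their last-observed
position plus a `not_tracked` flag rather than NaN, so downstream filters
stay total and quality control can still reject frames.

## Preprocessing

The sensor streams at a jittery ~30 FPS. Every coordinate channel is first
resampled onto an exact arithmetic grid at `target_rate_hz` (default 30 Hz)
with a natural cubic spline through the original samples, then low-pass
filtered with a Butterworth design (default 3rd order, 10 Hz cut-off).

* Filtering is zero-phase (forward–backward, reflect padding) by default.
  A one-pass filter would delay every trajectory by its group delay and
  bias all gait-event times in one direction; zero-phase keeps event timing
  unbiased at the cost of squaring the magnitude response. One-pass
  filtering remains available (`zero_phase=False`) for fidelity
  experiments.
* The natural-spline boundary condition fixes the otherwise open choice of
  cubic interpolation behavior at the recording ends.
* The full recording is filtered before windowing; filtering only the short
  analysis window would put the filter's edge transients exactly where the
  first and last gait events occur.

## Analysis window (VGAP)

A whole-body COM proxy — by default the unweighted centroid of SpineBase,
SpineMid, HipLeft, HipRight; optionally a Winter-style segment-mass-weighted
estimate for sensitivity checks — is tracked, and its 3D Euclidean distance
from the sensor defines the window: entry when the distance first drops
strictly below `d_enter` = 4.2 m, exit when it first drops strictly below
`d_exit` = 1.5 m. A straight walk therefore traverses 2.7 m of depth
inside the window. No hysteresis is applied: compliant trials approach the
sensor monotonically, and a re-crossing of the entry threshold flags the
trial non-compliant instead of re-windowing it. Body tracking typically
engages around 4.5 m, so the entry time falls strictly after the first
frames and start-up skeleton artifacts stay outside the window.

## Step segmentation

The core detector works on each ankle's depth series on the uniform,
filtered grid: frame *k* is **stationary** (0) when |z(k) − z(k−1)| is below
the threshold (default 2 cm), else **in movement** (1); the first frame
inherits the second's label. The absolute value is the only symmetric
reading of "difference between consecutive depth values". Ankles are used
rather than foot joints, whose tracking is notoriously unstable. Within
each stationary run the depth is forced to the run's initial value
(stationary hold); run starts are the initial-contact analogs, run ends the
toe-off analogs.

Two practical amendments:

* **Debouncing.** Depth noise of 2–4 mm near the 2 cm threshold produces
  label chatter. Interior runs shorter than `min_run_frames` (default 3,
  ~0.1 s) are merged into their surroundings, shortest first; equal-length
  ties flip a moving run before a stationary one (stationary wins), then
  the leftmost. Runs touching the array edges are exempt. The rule is
  deterministic and is checked frame-for-frame against an independent
  brute-force labeler in the tests.
* **Window clipping.** Events are detected on the whole filtered recording
  and then clipped: a run straddling the window edge contributes an onset
  only if the onset itself lies inside, which avoids truncation bias at the
  edges.

Steps pair each onset with the nearest preceding onset of the opposite leg:
step length = |difference of the two held depths|, step time = interval
between the onsets, and the step belongs to the landing leg. Consecutive
same-leg onsets yield no step and a logged warning. The 2 cm threshold is
defined per frame on the 30 Hz grid; users resampling at other rates must
re-derive it.

## Parameters

Per trial (sides reported separately, relabeled paretic/non-paretic when the
session metadata names a paretic side):

| Parameter | Rule | Unit |
| --- | --- | --- |
| step length | per-step held-depth difference, averaged per landing leg | m |
| stance | stationary time in [onset, next same-leg onset), % of the cycle, averaged | % |
| double support | mean duration of intervals where both ankles are stationary | s |
| mean velocity | per-step length/time, averaged per landing leg | m/s |
| cadence | onsets of both legs inside the window / window duration | steps/min |
| step width | \|mean lateral onset position left − right\| | m |
| ML / V sway | peak-to-peak x / y excursion of the hip midpoint in the window | m |

Notes on the open choices: cadence counts every initial contact inside the
window (pairing contacts into steps would drop the first one and
systematically undercount) and normalizes by the window duration, not the
first-to-last-event span. Double support is a duration in seconds, not a %
of cycle. Step width uses mean onset positions instead of fitted
progression lines — with 2–4 steps per trial a line fit is ill-conditioned.
Velocity averages per-step ratios ("instantaneous speed") rather than
dividing total distance by total time. Sway is computed on the filtered
hip-midpoint series without detrending; compensating a tilted sensor is a
calibration responsibility upstream. Parameters whose preconditions fail
for a side (e.g. no steps) are reported absent, never as zero.

## Synthetic gait generator

The generator emulates exactly the structure the detector assumes, with
known parameters: piecewise ankle depth (constant during stance, cubic
smoothstep advance by one stride during swing — continuous velocity, zero
at both ends, so the per-frame displacement crosses the 2 cm threshold
cleanly mid-swing and stays under it near the contacts, exercising the
debouncing); legs phase-offset by half a cycle with per-side step lengths
and stance fractions on a common cycle time; hip midpoint advancing at the
mean speed with a lateral sinusoid at stride frequency and a vertical one
at step frequency; the remaining joints on rigid offsets from the hip
(knees interpolated, feet riding their ankle). Sensor imperfections:
i.i.d. Gaussian coordinate noise (default σ = 3 mm, the middle of the
sensor's 2–4 mm far-zone depth accuracy band) and Gaussian frame-rate
jitter (default 30 ± 1 Hz). Everything is deterministic under the spec's
seed (NumPy PCG64).

Defaults are the validation cohort's medians: step 0.46 m, cadence
95 steps/min, stance 67.5 %, width 0.19 m, ML sway 0.092 m (amplitude
0.046 m), V sway 0.05 m. Two presets bracket the severity range: a
functional pattern (0.50/0.56 m steps, 99 steps/min, ~62 % stance) and a
severely impaired one (0.15/0.23 m steps, 46 steps/min, ~85 % stance).

What the generator does **not** emulate: arm swing, trunk lean, turning,
occlusion and tracking dropouts, skeleton-fitting artifacts near the field
of view edges, and non-stationary (accelerating/hesitating) gait. Passing
recovery tests on this generator therefore demonstrates the correctness of
the *algorithmic chain*, not robustness to every artifact of real
recordings.

### Threshold-aware ground truth

Expected parameter values are the closed-form output of the stated
measurement rule, not the bare kinematic inputs. Near lift-off and landing
the smoothstep advances less than 2 cm per frame, so the detector — on any
real foot as well — starts stance early and ends it late by margins that
are deterministic functions of stride, swing time, frame rate, threshold
and the low-pass filter. The ground truth computes these margins by
labeling a filtered one-cycle template exactly as the detector does,
averaged over the sampling phase (cycle and frame grid are incommensurate),
and folds them into expected stance, double support, onset times and held
contact depths. Two further deterministic conventions are modeled: measured
durations count frames inclusively (a continuous interval of length L reads
as L + one frame on average), and window entry/exit times snap to the
analysis grid. The expected sway adds the upward bias a peak-to-peak
reading acquires under filtered coordinate noise, evaluated by a small
seeded Monte Carlo integral (no closed form exists for the expected maximum
of signal-plus-correlated-noise).

Ignoring these effects is not an option at 30 Hz: the detection margins
alone are worth up to ~3 percentage points of stance at slow cadences,
larger than the 2 pp recovery tolerance the validation demands.

### Validation grid design

The recovery suite spans step length 0.15–0.6 m, cadence 45–110 steps/min,
stance 60–87 % and noise {0, 3 mm} with a severity-coupled grid (6 levels ×
symmetric/asymmetric × 2 noise levels = 24 conditions) rather than a full
cross product: uncoupled extremes are either unwalkable (0.6 m steps held
87 % of a 110 steps/min cycle) or provably undetectable (0.2 m steps spread
over the long slow swings of a 45 steps/min, 60 % stance gait never move
2 cm per frame — the generator raises a feasibility error for these).
Additionally, the in-window step count is discontinuous in the contact
times: a contact landing within about a frame of a window boundary is
counted or dropped on sub-frame measurement jitter, which moves cadence by
a full count (up to ~15 steps/min for brisk walks). The grid and preset
factories therefore nudge the (otherwise arbitrary) starting depth in
1.1 cm increments until every expected contact clears the window edges by
at least two frames — a deterministic, seed-independent placement rule that
keeps the validation away from a razor edge of the cadence definition
itself.

## Agreement statistics

For validating one measurement system against a reference on paired
per-trial(-and-side) parameter values: Kolmogorov–Smirnov normality gate
(against a normal with the sample's own mean/SD; medians and quartiles are
the appropriate summaries when it fails); paired Wilcoxon signed-rank
(exact null distribution for n ≤ 25 without zeros/ties, otherwise normal
approximation with Pratt zero handling; effect size r = |Z|/√n — the
conventional choice, labeled as such since several definitions circulate);
Spearman rank correlation with average ranks (exact permutation p for
n ≤ 9); ICC(2,1) — two-way random effects, absolute agreement, single
measure, the standard reading of "absolute agreement" for two fixed
systems over subjects — computed from the two-way ANOVA mean squares, with
negative estimates clamped to zero and flagged; Bland–Altman limits of
agreement (mean difference ± 1.96 × sample SD, differences =
candidate − reference so a positive mean difference is overestimation by
the candidate); and the mean percentage error |REF − CUR|/|REF| × 100.
Correlations of parameters against Timed Up and Go times use Spearman; in
impaired gait the expected signs are negative for step length, velocity
and cadence and positive for stance and double support. No
multiple-testing correction is applied (per-parameter p < 0.05), which is
recorded in the report metadata.

## Visualization

The radar chart shows the five parameters that track functional mobility
most closely (step length, stance, double support, velocity, cadence; step
width is excluded as the least reliable), each min-max normalized over a
user-supplied session collection so longitudinal charts share one scale.
Stance and double support are displayed as 1 − normalized value
("performance" orientation): without the inversion a healthier gait could
not enclose an impaired one, since impairment *raises* those two. The step
plot is the overhead x–z view of a trial: window boundaries, sensor mark,
per-leg contact positions, hip-midpoint trace.

## Numerical conventions and degenerate inputs

Strict inequalities at the window thresholds; absolute-value difference in
the detector; ties in debouncing favor stationary; a fully stationary gait
cycle (stance 100 %) is flagged invalid and skipped; zero step time raises
a data error (duplicate onsets); a missing double-support interval returns
0 s with a warning (pathological for walking); constant samples make
normality and correlation undefined (flagged, not silently zeroed); ICC
denominators of zero are flagged degenerate. Coordinates are validated
finite with |z| ≤ 10 m and strictly increasing timestamps at load time.

## Problem sizes used in the shipped validation

The recovery suite analyzes 24 synthetic trials of ~140–830 frames each;
the segmentation oracle check uses 100 random series of up to 200 frames;
the Bland–Altman coverage check uses 1000 replicates of n = 22; Wilcoxon
enumeration oracles use n ≤ 12 (4096 sign patterns) and Spearman
permutation oracles n ≤ 8–9. These sizes make the whole suite run in a few
seconds while keeping every check at full precision.

## Limitations

Single straight approach toward a front-facing sensor only (no multi-pass,
turning, or lateral/rear views); no kinematic angles, moments or powers;
step width is the least reliable parameter of this family of methods (the
lateral axis is the sensor's weakest and onset sets are small); file-level
compatibility with any particular vendor's session format is out of scope —
the CSV/JSON dialects here are self-describing and versioned.
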