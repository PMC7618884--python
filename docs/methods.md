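# Methods

## Model

A skeleton sequence is a `T × 17 × 3` tensor in the Human3.6M joint
convention, with a frame rate and an optional per-frame-per-joint validity
mask. The vertical axis is `z` by default (ground plane = XY); `y`-up
mocap exports are axis-swapped at load time. Coordinates are
unit-agnostic: every output is an angle (deg) or angular rate (deg/s),
invariant to translation, uniform scaling and rotation about the vertical
axis. These invariances are enforced by property tests at 1e-6 absolute
tolerance.

Turning is measured from ground-plane projections of left-minus-right
joint-pair vectors (hip, knee, shoulder). Per frame pair the increment is
the arcsin-of-normalised-cross-product angle between consecutive vectors,
averaged with equal weights over the selected joint pairs; cumulative
angle, angular speed and maximum angular velocity follow as θ = Σθ_t,
ω = θ/d with d = T/fps, and w_max = max θ_t · fps.

### Numerical and convention choices

* **w_max units.** The per-frame maximum increment is divided by the
  frame interval dt = 1/fps, not multiplied by it: multiplying a
  per-frame angle by seconds-per-frame would yield degree-seconds,
  whereas the quantity is a rate and is reported in deg/s everywhere.
* **Unsigned default, signed alternative.** The arcsin form is unsigned,
  aliases per-step angles above 90° (θ_t = 180° − step), and accumulates
  oscillatory motion instead of cancelling it. It is retained as the
  default because it is the method's defining computation; the `signed`
  atan2 mode, which nets out oscillation and carries direction, is used
  internally by the turn detector and offered for robustness studies.
* **Degenerate frames.** A pair vector is degenerate when either joint is
  masked or its norm falls below 1e-9 × the clip's median pair norm.
  Interior gaps carry the last valid vector forward (zero increment,
  logged, counted in `n_skipped_frames`); leading gaps borrow the first
  valid vector. A clip with no valid frame for a requested pair raises.
  Hard failure on single occluded frames would make free-living data
  unusable.
* **Quantisation.** Nearest bin among configured multiples of 45°;
  exact midpoints (e.g. 112.5°) round half up to the larger bin —
  deterministic and documented, since no convention is published. Angles
  beyond the largest bin clamp down to it. Angles below the smallest
  bin's lower edge clamp up by default; `clamp=False` returns a
  sub-threshold flag instead, for workflows whose smallest label is 90°
  and which prefer to discard small turns. Conformance is tested
  exhaustively on a 0.1° grid over [0°, 382.5°].
* **Duration.** d = T/fps for a clip; explicit annotation start/end times
  take precedence when present.

## Turn detection

Published turning datasets were curated manually (pelvis-rotation
initiation to movement completion, ≥ 45° of consecutive hip rotation);
no segmentation algorithm accompanies them. The detector here is this
package's own operationalisation: the unwrapped atan2 heading of the hip
vector gives a signed yaw track; a segment opens when |yaw rate| ≥
`omega_start` (default 25 deg/s), stays open while it remains ≥
`omega_stop` (default 10 deg/s, up to `max_gap_frames` = fps/4
consecutive slow frames), and is kept if its net rotation magnitude is ≥
45°. Detection is hip-only, matching how ground-truth turning was defined
upstream. The defaults are tunables with no published authority; on
noise-free synthetic streams the detector attains recall 1 with < 2°
segment-angle error for injected turns ≥ 55°. Direction is `cw`/`ccw` by
the sign of the net rotation, or `mixed` when both senses exceed 45°
inside one segment. No duration filter is applied.

## Evaluation metrics

* **Accuracy**: percent of quantised predictions matching their bin label.
* **MAE**: mean |continuous prediction − discrete label|; label
  quantisation error (≤ 22.5°) is part of the metric by design.
* **Weighted precision**: per-bin precision weighted by the bin's
  true-label count. Bins with true labels but no predictions contribute
  precision 0 at full weight by default (penalising missed bins; equal to
  scikit-learn's `average="weighted", zero_division=0`); the alternative
  `drop` convention removes them and renormalises. Both are tested; which
  one published tables used is indeterminable.
* **Grouped reports** add an `Avg.` row (unweighted mean of the group
  metric values — the convention used when result tables average across
  rows) and a pooled `overall` row; the two differ whenever group sizes
  differ, and both are reported.
* **Cohen's κ** uses marginal-product expected agreement; the degenerate
  single-identical-category case (p_e = 1) is defined as 1 by convention.

## Cohort statistics

Turns within a subject are correlated, so subjects are the unit of
analysis: per-subject unweighted means first, then a two-tailed
independent-samples t-test on the subject means. The default is
pooled-variance Student's t (df = n_a + n_b − 2) with Welch available by
flag; published group comparisons of this kind do not state which variant
was used, and recomputing from rounded summary statistics reproduces the
mean differences and Cohen's d exactly (−11.10°, d = −0.74; −32.33 deg/s,
d = −0.97 at 12 + 12) but not the printed t statistics (pooled gives
≈ −1.80 and ≈ −2.38 vs printed −1.73 and −2.28) — hence tests pin only
mean difference and d. Cohen's d uses the pooled SD
√(((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2)); reported SDs are across-subject
SDs of per-subject means (ddof = 1). Summary-statistics mode accepts
printed (mean, SD, n) per group so tables can be checked without raw data.

## Synthetic data

The simulator emulates what the estimator consumes — an articulated
17-joint body executing turns with exact ground truth — not
biomechanically realistic gait. The pelvis yaw follows a constant,
trapezoid (25% ramp / 50% cruise / 25% ramp) or sigmoid rate profile;
hips sit ±0.15 units from the pelvis centre perpendicular to the yaw,
knees and ankles below them, shoulders ±0.2 units at thorax height.
Geometry constants (hip width 0.3, shoulder width 0.4, 0.5-unit leg
segments) are arbitrary because all outputs are scale-invariant.

Optional effects:

* **Gait swing**: a yaw oscillation of the leg pairs (amplitude in deg,
  default stride frequency 1.8 Hz) under a sin² envelope so clips begin
  and end at rest — consistent with the initiation-to-completion
  definition of a turning episode, and making the signed-mode net angle
  insensitive to swing.
* **Noise**: i.i.d. Gaussian per coordinate per frame, scaled as a
  fraction of hip width. Real pose-estimator error is temporally and
  spatially correlated; tests on this generator therefore establish
  estimator behaviour under idealised noise only.
* **Shoulder lag**: the shoulder yaw follows the pelvis with a pure time
  delay; zero lag emulates rigid "en bloc" turning. Positive lag degrades
  shoulder-only estimates more than hip-only ones, the directional effect
  behind preferring hip+knee joint sets.
* **Occlusion**: per-frame-per-joint Bernoulli masking (frame 0 kept
  visible so carry-forward is defined).

Cohort simulation draws subject-level means from per-group normal
distributions and scatters individual turns around them. Defaults are a
12 + 12 cohort with group distributions matching a typical early-PD vs
control contrast (turning angle 92.65 ± 13.21 vs 103.75 ± 16.75 deg;
w_max 127.86 ± 29.77 vs 160.19 ± 36.49 deg/s), 58 turns per subject
(≈ 1386 turns / 24 subjects in free-living recordings of comparable
scale), and within-subject SDs of 25° / 35 deg/s chosen as a realistic
free-living spread (no published value exists). Calibration tests show
empirical type-I error within [0.035, 0.065] at nominal 0.05 and unbiased
mean-difference recovery over 500 replicates.

## Known limitations

* The faithful estimator is biased upward under noise (unsigned
  increments cannot cancel); the bias grows with noise SD and fps. This
  is inherent to the published formulation, demonstrated by the noise
  monotonicity tests, and mitigated in practice by the 45° quantisation.
* No modelling of walking-arc turns vs pivot turns, freezing of gait,
  camera projection error, or temporally correlated pose noise.
* The detector's hysteresis defaults were chosen for the synthetic noise
  regime; free-living deployments should tune `omega_start`/`omega_stop`
  against annotated data.
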