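# Methods

This note documents the models, conventions and numerical choices behind
`bowkin`, and what its synthetic validation does and does not establish
about real recordings.

## Kinematic model

**Segment frames.** Each segment's orientation is a right-handed
orthonormal triad built from 3+ markers, Y pointing proximally along the
long axis, X laterally, Z completing the triad:

* *thorax* — Y from the (T8, lower-sternum) midpoint to the (C7,
  upper-sternum) midpoint; Z anterior (toward the sternum midpoints);
* *humerus* — Y from the epicondyle midpoint to the shoulder marker; X
  the lateral component of the lateral→medial epicondyle line;
* *forearm* — Y from the styloid midpoint to the epicondyle midpoint; X
  toward the radial styloid;
* *hand* — Y from the knuckle midpoint (index/little metacarpal heads)
  to the styloid midpoint;
* *bow* — X frog→tip, plane fixed by the mid-bow marker;
* *violin* — X tailpiece→scroll (the string-line direction), plane fixed
  by the two bridge markers, origin at the bridge midpoint.

Markers closer than a relative residual of 1e-8 to collinear raise a
degenerate-geometry error naming the frame. The marker-role map is
configurable because real capture sessions adjust marker placements; the
defaults above are what the synthetic generator emits.

**Joint angles.** Shoulder: intrinsic Y–X′–Y″ of the humerus relative to
the thorax — plane of elevation ("horizontal" AA), elevation (positive
up), internal–external rotation. Elbow and wrist: intrinsic Z–X–Y —
flexion about Z, the middle angle being carrying angle (elbow, discarded)
or radial deviation (wrist), and axial rotation about Y
(pronation–supination at the elbow; discarded at the wrist). All channels
are reported in degrees and unwrapped so no ±180° jumps remain. Within
1e-3° of 0° or 180° elevation the Y–X′–Y″ decomposition is singular; only
the sum (or difference) of the two Y rotations is observable. Those
frames are flagged, and the plane of elevation carries the previous
frame's value (leading gimbal frames, with nothing to carry, place the
whole rotation in the plane-of-elevation channel).

**Bow–string contact.** b(t) is the closest-approach parameter between
the bow axis and the string line, divided by bow length and clipped to
[0, 1]; the clipped fraction is reported as a QC statistic. Frames where
the two lines subtend < 1° carry the previous value and are flagged. No
physical contact detection is attempted (audio is out of scope). The bow
velocity v(t) is the centered finite difference of b times the sampling
rate (one-sided at the ends).

## Pre-processing

Occlusions (blank or exactly-zero coordinate triples in TSV exports;
negative residuals in C3D) are masked explicitly. Gaps of at most
`max_gap` frames are filled per coordinate by a cubic spline fitted to
the marker's observed frames (boundary gaps by the same spline's
extrapolation); longer gaps stay masked. Smoothing is a zero-phase
4th-order Butterworth (2nd-order design run forward–backward), default
cutoff 10 Hz — standard for upper-limb capture. For noise-dominated
recordings a cutoff at the movement bandwidth is more appropriate: the
validation suite uses 6 Hz for the 0.5 Hz bowing task, under which 1 mm
white marker noise leaves every angle channel's RMS error below 0.5°
(axial rotations are the limiting channels, as in real capture).
Time alignment of two streams crops both to the overlapping shared-clock
window at nearest-frame resolution; both streams run at 120 Hz, so no
sub-frame resampling is performed.

## Stroke segmentation

Direction changes are reversals of b(t) passed through a two-sided
hysteresis: an extremum becomes an event only once the bow has travelled
at least `min_excursion` (default 0.05 bow-lengths) on both sides, and
event pairs closer than `min_interval` (default 0.25 s) — quick
back-and-forth blips — are removed pairwise so the surviving events still
alternate. Event times are refined to the linear interpolation of the
bow-velocity zero crossing. The defaults reject tremor-scale ripple at
novice tempi; both are configurable because no detection rule is implied
by the data themselves. Strokes span consecutive events (partial segments
before the first and after the last event are discarded); "down" moves
frog→tip. The upper bow half is the tip half (b > 0.5, the pedagogical
reading), with the boundary assigned to the lower half.

## Metrics

Definitions as in the README. Choices that were genuinely open:

* **Variability (m10–m12).** Across-stroke SD at each of 101
  normalised-time points (n−1 denominator), averaged over time — but
  pooled only within stroke *comparability classes* (direction × extent:
  down/up × full/upper-half/lower-half). Mixing a down-bow with an
  up-bow, or a full with a half bow, measures construction differences,
  not motor variability: an ideal demonstrator would score ~13° instead
  of ~0°. Coordination variability applies the same pooling to the
  circular SD (√(−2 ln R̄), capped by flooring R̄ at 1e-12) of the
  vector-coding coupling angle; steps where a stroke moves in neither
  joint skip that stroke.
* **Timing difference (m13).** Teacher events are matched one-to-one to
  participant events greedily by ascending |Δt| (verified optimal against
  exhaustive assignment on small instances); the metric is the *signed
  sum* of matched differences, capturing cumulative drift over an
  exercise, in seconds.
* **Bow distance (m14).** 100 × RMS of the normalised bow-position
  difference — percent of bow length. The absolute scale of previously
  published values for this quantity is not recoverable from their
  description ("a.u."); only relative and contrast behaviour is
  comparable.
* **SPARC (m15).** Per published definition: magnitude spectrum of the
  zero-padded speed profile (FFT length 2^(⌈log2 n⌉ + 4)), normalised by
  its DC value (which is the spectral maximum for a non-negative speed),
  adaptive cutoff = min(10 Hz, highest frequency still above the 0.05
  normalised-amplitude threshold), negative arc length over the
  above-threshold band with frequency normalised by the band width.
  Computed on |v| per stroke and averaged across strokes: per-stroke
  computation keeps values in the −1.6…−2.2 band characteristic of
  discrete movements, whereas whole-trial SPARC would be far more
  negative.
* **Synchronization (m16/m17).** Relative phase of the participant event
  nearest each teacher-cycle start, 2π(t_p − t_k)/(t_{k+1} − t_k) wrapped
  to [−π, π); strength is the mean resultant length, phase shift the
  circular mean in radians (reported in radians even where prior work
  labels the column "deg" while printing radian-scale values).
* **Undefined values** (degenerate denominators, < 2 strokes, empty event
  trains) are explicit NaN markers, excluded pairwise downstream, never
  imputed.

## Statistical layer

* **Correlations.** Spearman with average ranks for ties and a two-sided
  t-approximation p, pairwise-deleting undefined values; the retained set
  is {p < 0.05/17} ∪ {m3, m10–m13, m17} (the always-include list is
  configurable).
* **ICC.** Two-way random-effects absolute-agreement mean-square
  formulas; ICC(2,1) and ICC(2,k) with McGraw–Wong F-based confidence
  bounds (Satterthwaite df for the single-rater interval, Spearman–Brown
  for the average). Cross-checked against an independent implementation
  in the tests. Note the single ≤ average ordering is only guaranteed for
  non-negative estimates.
* **Contrasts.** The reference analysis style for this design is a
  Bayesian multivariate skew-normal mixed model; `bowkin` deliberately
  replaces it with a participant-level cluster bootstrap of the same
  estimands: resample participants with replacement within group (keeping
  all their exercises and stages), average exercises within participant,
  form group × stage means per replicate, and take the three
  stage-difference contrasts. Estimates are observed contrasts; intervals
  are percentile 95%; `prob` is the bootstrap fraction above zero. With
  12 clusters per group the percentile interval's type-I rate measures
  6% over 200 null simulations (binomially consistent with the nominal
  5%), and a scripted interaction of 2 residual SDs is recovered in sign
  in 50/50 repeats. Absolute posterior interval bounds from the Bayesian
  reference are not comparable and are not targeted.
* **Descriptives.** Even-n medians are the mean of the central order
  statistics; IQR uses linear-interpolation quantiles. Published IQRs
  whose convention is unknown are not used as checks.

## Synthetic data generator

**What it emulates.** The full two-group design: 12 participants per
group × 3 exercises × 3 stages (baseline S1, training S2, recall S3),
five expert raters scoring the 144 S1/S3 videos on the 1–7 scale, and the
haptic group's training stage played under exoskeleton guidance.

**Teacher.** b(t) follows each exercise's stroke plan (8 / 12 / 8 strokes;
full bows span b = 0.05–0.95; the 6-stroke full/half pattern of exercise
2; strings alternating on exercise 3) with a minimum-jerk position
profile per stroke plus a small within-stroke speed modulation
(relative amplitude 0.115, zero at the stroke ends). The modulation is
sized once so the teacher's per-stroke SPARC is ≈ −1.75, the reported
smoothness of a real demonstrator — a pure minimum-jerk bump (≈ −1.5)
is smoother than any human stroke. Elbow FE and shoulder AA derive from b
through a smooth monotone mapping — elbow_fe = 55° + k_e·b²,
shoulder_aa = 5° + k_s·(2b − b²), k_e = 45°, k_s = 64° — which makes the
elbow dominant toward the tip and the shoulder dominant near the frog and
gives every ROM and ratio a closed form. The remaining channels are small
smooth oscillations. The true mapping from bow position to human joint
angles is many-to-one; this one is a modelling convenience, not a claim
about real players.

**Markers.** Emitted by forward kinematics through the same frame
constructions the analysis inverts (thorax fixed; humerus/forearm/hand
composed with the analysis Euler sequences, carrying and hand-axial
angles zero; bow placed so the closest-approach parameter equals b·bow
length). Noise-free streams therefore reproduce the generating angles to
< 1e-6° — the round trip validates the construction/decomposition pair,
and marker noise is added on top when robustness is tested. Default
anthropometry: 300/260/80 mm segments, 740 mm bow, 90/70/80 mm marker
baselines.

**Learner deviations.** Bow trajectory = teacher's, warped in time
(constant lag + i.i.d. per-boundary jitter, monotonicity enforced),
amplitude-scaled about mid-bow, plus zero-mean noise low-passed at 8 Hz;
joint angles follow from the learner's own coordination gains
(`coordination_ratio` = target k_e/k_s) with i.i.d. per-stroke angle
offsets. Baseline/training/recall defaults (amplitude 0.72→0.93, jitter
0.12→0.06 s, lag 0.18→0.06 s, bow noise 0.0015→0.0007, offsets
2.5°→1.6°) are sized once against the reported group summaries — e.g.
bow-noise levels put learner SPARC near the reported −1.90 (baseline) to
−1.79 (recall) — with a log-normal individual skill factor (SD 0.2)
scaling each participant's deviations.

**Haptic guidance.** In the haptic group's training stage, elbow FE and
shoulder AA evolve as a damped second-order tracker of the teacher
trajectory, θ̈ = K(θ_ref − θ) + B(θ̇_ref − θ̇) + θ̈_dev, with the unguided
trajectory's acceleration as disturbance (K = 60 s⁻², B = 14 s⁻¹;
semi-implicit Euler at 120 Hz) — the viscous-elastic force field acting
at exactly those two joints. K = 0 reproduces the unguided learner; the
K → ∞ limit tracks the teacher's joints, and the bow coordinate is
re-derived from the guided joints through the inverse mapping, so bow
fidelity (m14) improves monotonically along a stiffness ladder. An
optional shoulder-overdrive knob was considered and rejected as default
behaviour; guidance side-effects can be emulated by raising the learner's
shoulder gain directly.

**Ratings.** Latent video quality = weighted sum of z-scored metric
ground truths (defaults +1·m2, −1.5·m14) plus per-rater bias
(SD 0.4) and noise (SD 1.6), cut at thresholds ±0.64, ±1.92, ±3.2 into
the 1–7 scale. Noise and thresholds are sized once so the simulated
panel reproduces the reported reliability (ICC(2,1) ≈ 0.71,
ICC(2,5) ≈ 0.92) and a ≈ 3-point baseline-to-recall rating gain.

**Randomness.** One study seed feeds named substreams (participants,
trials, raters) via `numpy.random.SeedSequence.spawn`; equal seeds give
byte-identical tables.

## Validation tolerances and problem sizes

Ground-truth recovery compares the marker-level pipeline against the
generator's trajectory-level values as study means over the full
12-per-group study (24 × 3 × 3 = 216 trials, 2 s strokes at 120 Hz):
m1–m9 and m14 within 2% (the paths share the realised signals up to
marker reconstruction and half-mask discretisation), m15 within 5%,
m10/m11 within 15% and m12 within 30% (SD estimates over ≤ 4 strokes per
comparability class are intrinsically noisy), m13 within 0.4 s and m17
within 0.15 rad (event refinement near minimum-jerk reversals, where the
bow velocity is flat, dominates), m16 within 0.02. Oracle equivalences
(independent SPARC transcription, dense-sampling bow contact, exhaustive
event assignment, independent ICC implementation, analytic von-Mises
resultant) hold to the tolerances stated in the tests. The bootstrap
calibration uses a metric-level null simulator (participant random
intercepts + residual noise) for its 200 + 50 repeats; the marker-level
generator feeds one full null study in the tests — the two agree on the
estimand by construction, and the metric-level path is what makes
repeated-simulation calibration affordable.

## Limitations

* The generator's bow-to-joint mapping, deviation models and rating
  model are stylised: passing recovery tests shows the *pipeline*
  measures what the generator scripted, not that real novices deviate
  this way. Real data add soft-tissue artefact, marker relabelling
  errors, occlusion bursts and non-stationary tempo, none of which are
  emulated beyond white occlusions and additive noise.
* Scapula/clavicle kinematics, inverse dynamics, audio-derived measures
  and string identification are out of scope.
* The statistical layer estimates the same contrasts as the Bayesian
  reference analysis but not its posterior geometry; published absolute
  interval bounds are not reproducible here.
* C3D support covers the POINT section (Intel byte order, float or
  scaled-integer storage) — enough for marker interchange, not a general
  C3D implementation.
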