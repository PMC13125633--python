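"""Synthetic teacher-learner studies with known ground truth.

The generator emulates the haptic violin-training study the pipeline is
built for: a teacher demonstrates three bowing exercises; learners in
two groups (AV control, AVE haptic) imitate them at baseline (S1),
training (S2) and recall (S3), and five experts rate the S1/S3 videos
on a 1-7 scale.

* Teacher bow trajectories follow the exercise stroke plans with
  minimum-jerk position profiles per stroke, plus a small secondary
  speed modulation so the per-stroke speed spectrum matches the
  smoothness (SPARC) band of a real demonstrator rather than an ideal
  point-to-point reach.
* Elbow FE and shoulder AA are derived from the bow coordinate by a
  documented smooth mapping (elbow-dominant toward the tip, shoulder-
  dominant near the frog); the remaining angle channels are small
  smooth oscillations.  Markers are emitted by forward kinematics at
  120 Hz through the same segment-frame constructions the analysis
  inverts, so noise-free marker streams reproduce the generating angles
  exactly.
* Learner deviation knobs: bow-excursion amplitude scale, constant lag
  plus per-stroke timing jitter, additive smoothed bow noise, a target
  elbow-to-shoulder coordination ratio, and across-stroke angle
  offsets.  When haptic guidance is active the elbow and shoulder
  trajectories evolve as a damped second-order tracker of the teacher
  trajectory (the exoskeleton's viscous-elastic force field acting at
  those two joints), and the bow coordinate is re-derived from the
  guided joints.
* Expert ratings arise from a latent quality score (a weighted sum of
  z-scored metric ground truths) plus rater bias and noise, cut into
  the ordinal 1-7 scale.

Every random draw flows from a single study seed through named
substreams, and every trial's generative parameters and metric ground
truths are logged alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from . import metrics as met
from .errors import ParameterError
from .kinematics import (
    BowTrace,
    DEFAULT_MARKER_MAP,
    JointAngleSeries,
    bow_trace,
    bow_velocity,
    build_frames,
    joint_angle_series,
)
from .mocap_io import MarkerFrameSeries, TrialMeta
from .strokes import Stroke

__all__ = [
    "RATE",
    "Anthropometry",
    "ExerciseScript",
    "ParticipantProfile",
    "GuidanceParams",
    "RatingModel",
    "TeacherTrial",
    "ParticipantTrial",
    "StudyResult",
    "script_for",
    "generate_teacher",
    "generate_participant",
    "forward_markers",
    "analyze_trial",
    "simulate_study",
    "simulate_metric_table",
    "default_study_profiles",
    "DEFAULT_RATING_MODEL",
]

RATE = 120.0  # Hz, the study's capture rate

# bow-to-joint mapping: elbow_fe = ELBOW0 + k_e * b**2 (slope grows toward
# the tip), shoulder_aa = SHOULDER0 + k_s * (2b - b**2) (slope grows toward
# the frog).  Gains sized so a full bow uses ~40 deg of elbow FE and
# ~58 deg of shoulder AA, the order of magnitude of adult novice bowing.
ELBOW0 = 55.0
SHOULDER0 = 5.0
K_ELBOW = 45.0
K_SHOULDER = 64.0

_B_FULL = (0.05, 0.95)  # full-bow excursion leaves margin at frog and tip


@dataclass(frozen=True)
class Anthropometry:
    """Segment lengths and marker offsets (mm) of the simulated player."""

    upper_arm: float = 300.0
    forearm: float = 260.0
    hand: float = 80.0
    bow_length: float = 740.0
    elbow_width: float = 90.0
    wrist_width: float = 70.0
    hand_width: float = 80.0


@dataclass(frozen=True)
class ExerciseScript:
    """Stroke plan of one exercise.

    ``stroke_plan`` is an ordered list of (extent, direction, string)
    with extent in {"full", "half-upper", "half-lower"}, direction in
    {"down", "up"} (down = frog to tip) and string in {"G", "D"}.
    ``tempo`` is the duration of one stroke in seconds.
    """

    exercise_id: int
    stroke_plan: tuple[tuple[str, str, str], ...]
    tempo: float = 2.0
    repeats: int = 1

    def __post_init__(self):
        dirs = [d for _, d, _ in self.stroke_plan]
        if any(a == b for a, b in zip(dirs, dirs[1:])):
            raise ParameterError("stroke directions must alternate")
        if self.tempo <= 0:
            raise ParameterError("tempo must be positive")

    @property
    def n_strokes(self) -> int:
        return len(self.stroke_plan)

    @property
    def duration(self) -> float:
        return self.n_strokes * self.tempo

    def b_endpoints(self) -> np.ndarray:
        """Bow coordinate at stroke boundaries, length n_strokes + 1."""
        lo, hi = _B_FULL
        mid = 0.5
        pts = []
        for extent, direction, _ in self.stroke_plan:
            if extent == "full":
                a, b = lo, hi
            elif extent == "half-upper":
                a, b = mid, hi
            elif extent == "half-lower":
                a, b = lo, mid
            else:
                raise ParameterError(f"unknown extent {extent!r}")
            start, end = (a, b) if direction == "down" else (b, a)
            if pts and abs(pts[-1] - start) > 1e-9:
                raise ParameterError("stroke plan is not continuous in b")
            if not pts:
                pts.append(start)
            pts.append(end)
        return np.array(pts)

    def event_times(self) -> np.ndarray:
        """Stroke boundary times including the trial endpoints."""
        return np.arange(self.n_strokes + 1) * self.tempo


_EX2_PATTERN = (
    ("full", "down"), ("half-upper", "up"), ("half-upper", "down"),
    ("full", "up"), ("half-lower", "down"), ("half-lower", "up"),
)


def script_for(exercise_id: int, tempo: float = 2.0, repeats: int | None = None) -> ExerciseScript:
    """Stroke plan of exercise 1, 2 or 3.

    Exercise 1: full bows down and up on the G string (4 pairs, 8
    strokes).  Exercise 2: two repeats of the six-stroke full/half
    pattern (full down, half up, half down, full up, half down, half
    up; 12 strokes).  Exercise 3: full bows down and up alternating
    between the G and D strings (8 strokes).
    """
    if exercise_id == 1:
        repeats = 4 if repeats is None else repeats
        plan = tuple(
            (ext, d, "G") for _ in range(repeats) for ext, d in (("full", "down"), ("full", "up"))
        )
    elif exercise_id == 2:
        repeats = 2 if repeats is None else repeats
        plan = tuple((ext, d, "G") for _ in range(repeats) for ext, d in _EX2_PATTERN)
    elif exercise_id == 3:
        repeats = 4 if repeats is None else repeats
        plan = tuple(
            (ext, d, "GD"[k % 2])
            for _ in range(repeats)
            for k, (ext, d) in enumerate((("full", "down"), ("full", "up")))
        )
    else:
        raise ParameterError(f"unknown exercise id {exercise_id!r}")
    return ExerciseScript(exercise_id, plan, tempo=tempo, repeats=repeats)


# ---------------------------------------------------------------------------
# Trajectory synthesis
# ---------------------------------------------------------------------------

#: relative amplitude of the secondary within-stroke speed modulation;
#: sized once so the teacher's per-stroke bow-speed SPARC sits in the
#: -2.2..-1.6 band of real demonstrators (see docs/methods.md)
_SPEED_MODULATION = 0.115


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _stroke_shape(tau: np.ndarray) -> np.ndarray:
    """Normalised within-stroke position profile: minimum jerk plus a
    small zero-mean modulation that vanishes at both ends."""
    return _minimum_jerk(tau) + _SPEED_MODULATION * np.sin(2 * np.pi * tau) * (tau * (1 - tau)) * 4


def teacher_bow_coordinate(script: ExerciseScript, rate: float = RATE) -> np.ndarray:
    """b(t) following the stroke plan, sampled at ``rate``."""
    n = int(round(script.duration * rate))
    t = np.arange(n) / rate
    ends = script.b_endpoints()
    k = np.minimum((t / script.tempo).astype(int), script.n_strokes - 1)
    tau = t / script.tempo - k
    b0, b1 = ends[k], ends[k + 1]
    return b0 + (b1 - b0) * _stroke_shape(tau)


def angles_from_bow(
    b: np.ndarray,
    t: np.ndarray,
    k_elbow: float = K_ELBOW,
    k_shoulder: float = K_SHOULDER,
) -> JointAngleSeries:
    """Joint angles from the bow coordinate via the documented mapping."""
    elbow_fe = ELBOW0 + k_elbow * b**2
    shoulder_aa = SHOULDER0 + k_shoulder * (2 * b - b**2)
    rate = 1.0 / (t[1] - t[0]) if len(t) > 1 else RATE
    return JointAngleSeries(
        rate=rate,
        shoulder_aa=shoulder_aa,
        shoulder_e=42.0 + 3.0 * np.sin(2 * np.pi * 0.40 * t),
        shoulder_ie=12.0 + 2.0 * np.sin(2 * np.pi * 0.30 * t + 1.0),
        elbow_fe=elbow_fe,
        elbow_ps=20.0 + 4.0 * np.sin(2 * np.pi * 0.35 * t + 0.5),
        wrist_fe=5.0 + 3.0 * np.sin(2 * np.pi * 0.45 * t + 2.0),
        wrist_aa=-2.0 + 2.0 * np.sin(2 * np.pi * 0.25 * t),
    )


def bow_from_angles(
    elbow_fe: np.ndarray,
    shoulder_aa: np.ndarray,
    k_elbow: float = K_ELBOW,
    k_shoulder: float = K_SHOULDER,
) -> np.ndarray:
    """Inverse of :func:`angles_from_bow`, averaged over the two joints."""
    b_e = np.sqrt(np.clip((elbow_fe - ELBOW0) / k_elbow, 0.0, 1.0))
    b_s = 1.0 - np.sqrt(np.clip(1.0 - (shoulder_aa - SHOULDER0) / k_shoulder, 0.0, 1.0))
    return 0.5 * (b_e + b_s)


# fixed lab geometry of the simulated scene (mm)
_THORAX_ORIGIN = np.array([0.0, 1400.0, 0.0])
_SHOULDER_OFFSET = np.array([180.0, 50.0, 0.0])
_BRIDGE_POINT = np.array([350.0, 1250.0, 350.0])
_STRING_DIR = np.array([-0.8, -0.15, 0.6]) / np.linalg.norm([-0.8, -0.15, 0.6])
_STRING_NORMAL = np.cross(_STRING_DIR, [0.0, 1.0, 0.0])
_STRING_NORMAL /= np.linalg.norm(_STRING_NORMAL)
_BOW_DIR = 0.75 * _STRING_NORMAL + 0.25 * np.cross(_STRING_DIR, _STRING_NORMAL) + 0.1 * _STRING_DIR
_BOW_DIR /= np.linalg.norm(_BOW_DIR)
_BOW_NORMAL = np.cross(_BOW_DIR, _STRING_DIR)
_BOW_NORMAL /= np.linalg.norm(_BOW_NORMAL)


def forward_markers(
    angles: JointAngleSeries,
    b: np.ndarray,
    anthro: Anthropometry = Anthropometry(),
) -> MarkerFrameSeries:
    """Emit the default marker set by forward kinematics.

    The thorax is fixed at the lab origin; the humerus, forearm and hand
    frames are composed from the joint angles with the same Euler
    sequences the analysis decomposes (carrying and hand-axial angles
    zero), and markers are placed at the local offsets the segment-frame
    constructions invert exactly.  Bow markers are placed so the
    closest-approach parameter of the bow axis to the string line equals
    ``b`` times the bow length.
    """
    n = angles.n_frames
    if len(b) != n:
        raise ParameterError("bow coordinate and angle series must be equally long")
    r_th = np.broadcast_to(np.eye(3), (n, 3, 3))
    sho = _THORAX_ORIGIN + _SHOULDER_OFFSET

    eul = np.stack([angles.shoulder_aa, angles.shoulder_e, angles.shoulder_ie], axis=1)
    r_hum = Rotation.from_euler("YXY", eul, degrees=True).as_matrix()
    eul = np.stack([angles.elbow_fe, np.zeros(n), angles.elbow_ps], axis=1)
    r_fa = r_hum @ Rotation.from_euler("ZXY", eul, degrees=True).as_matrix()
    eul = np.stack([angles.wrist_fe, angles.wrist_aa, np.zeros(n)], axis=1)
    r_hand = r_fa @ Rotation.from_euler("ZXY", eul, degrees=True).as_matrix()

    down = np.array([0.0, -1.0, 0.0])
    lat = np.array([1.0, 0.0, 0.0])
    elbow = sho + anthro.upper_arm * (r_hum @ down)
    wrist = elbow + anthro.forearm * (r_fa @ down)
    knuckle = wrist + anthro.hand * (r_hand @ down)

    markers: dict[str, np.ndarray] = {}
    mm = DEFAULT_MARKER_MAP
    markers[mm["c7"]] = np.broadcast_to(_THORAX_ORIGIN + [0.0, 80.0, -60.0], (n, 3))
    markers[mm["t8"]] = np.broadcast_to(_THORAX_ORIGIN + [0.0, -120.0, -60.0], (n, 3))
    markers[mm["sternum_top"]] = np.broadcast_to(_THORAX_ORIGIN + [0.0, 80.0, 60.0], (n, 3))
    markers[mm["sternum_bottom"]] = np.broadcast_to(_THORAX_ORIGIN + [0.0, -120.0, 60.0], (n, 3))
    markers[mm["r_shoulder"]] = np.broadcast_to(sho, (n, 3))
    markers[mm["r_elbow_lat"]] = elbow + 0.5 * anthro.elbow_width * (r_hum @ lat)
    markers[mm["r_elbow_med"]] = elbow - 0.5 * anthro.elbow_width * (r_hum @ lat)
    markers[mm["r_wrist_rad"]] = wrist + 0.5 * anthro.wrist_width * (r_fa @ lat)
    markers[mm["r_wrist_uln"]] = wrist - 0.5 * anthro.wrist_width * (r_fa @ lat)
    markers[mm["r_hand_2"]] = knuckle + 0.5 * anthro.hand_width * (r_hand @ lat)
    markers[mm["r_hand_5"]] = knuckle - 0.5 * anthro.hand_width * (r_hand @ lat)

    markers[mm["violin_scroll"]] = np.broadcast_to(_BRIDGE_POINT + 330.0 * _STRING_DIR, (n, 3))
    markers[mm["violin_tailpiece"]] = np.broadcast_to(_BRIDGE_POINT - 120.0 * _STRING_DIR, (n, 3))
    markers[mm["violin_bridge_l"]] = np.broadcast_to(
        _BRIDGE_POINT + 25.0 * _STRING_NORMAL, (n, 3))
    markers[mm["violin_bridge_r"]] = np.broadcast_to(
        _BRIDGE_POINT - 25.0 * _STRING_NORMAL, (n, 3))

    frog = (
        _BRIDGE_POINT
        + 2.0 * _BOW_NORMAL
        - (np.asarray(b)[:, None] * anthro.bow_length) * _BOW_DIR
    )
    markers[mm["bow_frog"]] = frog
    markers[mm["bow_tip"]] = frog + anthro.bow_length * _BOW_DIR
    markers[mm["bow_mid"]] = frog + 0.5 * anthro.bow_length * _BOW_DIR + 15.0 * _BOW_NORMAL

    labels = list(markers)
    positions = np.stack([np.asarray(markers[lab], dtype=float) for lab in labels], axis=1)
    return MarkerFrameSeries(labels, positions, angles.rate)


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


@dataclass
class TeacherTrial:
    """A teacher demonstration: internal trajectories plus markers."""

    script: ExerciseScript
    angles: JointAngleSeries
    trace: BowTrace
    markers: MarkerFrameSeries
    event_times: np.ndarray  # stroke boundaries incl. endpoints
    anthropometry: Anthropometry = Anthropometry()

    @property
    def interior_events(self) -> np.ndarray:
        return self.event_times[1:-1]


@dataclass(frozen=True)
class GuidanceParams:
    """Viscous-elastic haptic field acting on elbow FE and shoulder AA:
    torque-equivalent acceleration stiffness * angle error + damping *
    velocity error toward the reference trajectory."""

    stiffness: float = 60.0  # 1/s^2-equivalent
    damping: float = 14.0  # 1/s

    def __post_init__(self):
        if self.stiffness < 0 or self.damping < 0:
            raise ParameterError("stiffness and damping must be >= 0")


@dataclass(frozen=True)
class ParticipantProfile:
    """Deviation knobs of one simulated learner.

    amplitude_scale shrinks the bow excursion about mid-bow; lag and
    timing_jitter_sd (s) displace stroke boundaries; smoothness_noise_sd
    (bow-lengths) adds low-pass-filtered bow noise; coordination_ratio
    sets the target elbow-FE-to-shoulder-AA gain ratio (teacher:
    K_ELBOW / K_SHOULDER); profile_noise_sd (deg) draws per-stroke angle
    offsets; guidance, when set, turns the haptic field on.
    """

    amplitude_scale: float = 1.0
    timing_jitter_sd: float = 0.0
    lag: float = 0.0
    smoothness_noise_sd: float = 0.0
    coordination_ratio: float = K_ELBOW / K_SHOULDER
    profile_noise_sd: float = 0.0
    guidance: GuidanceParams | None = None

    def __post_init__(self):
        if self.amplitude_scale <= 0:
            raise ParameterError("amplitude_scale must be positive")
        for name in ("timing_jitter_sd", "smoothness_noise_sd", "profile_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.coordination_ratio <= 0:
            raise ParameterError("coordination_ratio must be positive")

    def scaled(self, factor: float) -> "ParticipantProfile":
        """Deviations scaled by an individual skill factor (1 = nominal)."""
        return replace(
            self,
            amplitude_scale=1.0 - (1.0 - self.amplitude_scale) * factor,
            timing_jitter_sd=self.timing_jitter_sd * factor,
            lag=self.lag * factor,
            smoothness_noise_sd=self.smoothness_noise_sd * factor,
            profile_noise_sd=self.profile_noise_sd * factor,
        )


@dataclass
class ParticipantTrial:
    """A simulated learner trial with its generative ground truth."""

    profile: ParticipantProfile
    angles: JointAngleSeries
    trace: BowTrace
    markers: MarkerFrameSeries
    event_times: np.ndarray  # realised stroke boundaries incl. endpoints
    teacher: TeacherTrial
    ground_truth: dict[str, float] = field(default_factory=dict)


def generate_teacher(
    script: ExerciseScript,
    anthropometry: Anthropometry = Anthropometry(),
    seed: int = 0,
    rate: float = RATE,
) -> TeacherTrial:
    """Teacher trajectories and markers for one exercise."""
    b = teacher_bow_coordinate(script, rate)
    t = np.arange(len(b)) / rate
    angles = angles_from_bow(b, t)
    markers = forward_markers(angles, b, anthropometry)
    trace = BowTrace(rate=rate, b=b, bow_length=anthropometry.bow_length)
    return TeacherTrial(script, angles, trace, markers, script.event_times(), anthropometry)


def _smoothed_noise(n: int, rate: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise low-passed at 8 Hz and rescaled to the target SD."""
    if sd == 0 or n < 20:
        return np.zeros(n)
    white = rng.standard_normal(n)
    bb, aa = butter(2, 8.0 / (rate / 2))
    colored = filtfilt(bb, aa, white)
    s = colored.std()
    return sd * colored / s if s > 0 else np.zeros(n)


def _true_strokes(event_times: np.ndarray, rate: float, b: np.ndarray) -> list[Stroke]:
    """Strokes from known boundary times (incl. endpoints), with real
    direction and bow-coordinate range so comparability grouping works."""
    out = []
    n = len(b)
    for t0, t1 in zip(event_times[:-1], event_times[1:]):
        i0 = max(0, int(np.ceil(t0 * rate - 1e-9)))
        i1 = min(n, int(np.ceil(t1 * rate - 1e-9)))
        if i1 - i0 >= 2:
            seg = b[i0:i1]
            direction = "down" if seg[-1] >= seg[0] else "up"
            out.append(Stroke(i0, i1, direction, float(seg.min()), float(seg.max())))
    return out


def generate_participant(
    teacher: TeacherTrial,
    profile: ParticipantProfile,
    seed: int = 0,
) -> ParticipantTrial:
    """One learner trial derived from a teacher demonstration.

    The learner's bow trajectory is the teacher's, warped in time by the
    lagged and jittered stroke boundaries, amplitude-scaled about
    mid-bow, with additive smoothed noise; joint angles follow from the
    learner's own coordination gains plus per-stroke offsets; with
    guidance on, elbow and shoulder instead evolve as damped trackers of
    the teacher's trajectories and the bow coordinate is re-derived from
    the guided joints.  All realised deviation values are recorded in
    ``ground_truth``.
    """
    rng = np.random.default_rng(seed)
    rate = teacher.trace.rate
    b_t = teacher.trace.b
    n = len(b_t)
    t_grid = np.arange(n) / rate

    # realised stroke boundaries: lag + iid jitter, kept monotone
    ev_t = teacher.event_times
    jitter = rng.normal(0.0, profile.timing_jitter_sd, size=len(ev_t))
    ev_p = ev_t + profile.lag + jitter
    min_gap = 0.15 * teacher.script.tempo
    for i in range(1, len(ev_p)):
        ev_p[i] = max(ev_p[i], ev_p[i - 1] + min_gap)

    # time warp: participant time -> teacher time, linear between boundaries
    tau = np.interp(t_grid, ev_p, ev_t)
    b_warp = np.interp(tau, t_grid, b_t)
    b_p = 0.5 + profile.amplitude_scale * (b_warp - 0.5)
    b_p = np.clip(b_p + _smoothed_noise(n, rate, profile.smoothness_noise_sd, rng), 0.0, 1.0)

    k_elbow = profile.coordination_ratio * K_SHOULDER
    k_shoulder = K_SHOULDER
    angles = angles_from_bow(b_p, t_grid, k_elbow, k_shoulder)

    # per-stroke angle offsets (constant within a stroke)
    n_strokes = teacher.script.n_strokes
    off_e = rng.normal(0.0, profile.profile_noise_sd, size=n_strokes)
    off_s = rng.normal(0.0, profile.profile_noise_sd, size=n_strokes)
    stroke_of = np.clip(np.searchsorted(ev_p[1:-1], t_grid, side="right"), 0, n_strokes - 1)
    angles.elbow_fe = angles.elbow_fe + off_e[stroke_of]
    angles.shoulder_aa = angles.shoulder_aa + off_s[stroke_of]

    if profile.guidance is not None:
        for name, ref in (("elbow_fe", teacher.angles.elbow_fe),
                          ("shoulder_aa", teacher.angles.shoulder_aa)):
            setattr(angles, name,
                    _track(getattr(angles, name), ref, rate, profile.guidance))
        b_p = np.clip(
            bow_from_angles(angles.elbow_fe, angles.shoulder_aa, k_elbow, k_shoulder),
            0.0, 1.0)

    markers = forward_markers(angles, b_p, teacher.anthropometry)
    trace = BowTrace(rate=rate, b=b_p, bow_length=teacher.anthropometry.bow_length)
    trial = ParticipantTrial(profile, angles, trace, markers, ev_p, teacher)
    trial.ground_truth = _ground_truth(trial)
    return trial


def _track(dev: np.ndarray, ref: np.ndarray, rate: float, g: GuidanceParams) -> np.ndarray:
    """Damped second-order tracking of ``ref`` with the unguided
    trajectory's acceleration as disturbance input; stiffness 0 returns
    the unguided trajectory, large stiffness converges to the reference."""
    dt = 1.0 / rate
    acc_dev = np.gradient(np.gradient(dev) / dt) / dt
    theta = np.empty_like(dev)
    theta[0] = dev[0]
    vel = (dev[1] - dev[0]) / dt if len(dev) > 1 else 0.0
    ref_vel = np.gradient(ref) / dt
    for i in range(1, len(dev)):
        acc = (g.stiffness * (ref[i - 1] - theta[i - 1])
               + g.damping * (ref_vel[i - 1] - vel)
               + acc_dev[i - 1])
        vel = vel + acc * dt
        theta[i] = theta[i - 1] + vel * dt
    return theta


def expected_spatial(
    amplitude_scale: float,
    k_elbow: float = K_ELBOW,
    k_shoulder: float = K_SHOULDER,
) -> dict[str, float]:
    """Closed-form spatial metrics m1-m9 of a noise-free learner.

    With the bow excursion scaled about mid-bow, b spans
    [0.5 - s, 0.5 + s] with s = amplitude_scale * 0.45, and the mapping
    algebra gives every ROM in closed form (elbow ~ b^2, shoulder ~
    2b - b^2).
    """
    s = amplitude_scale * (_B_FULL[1] - _B_FULL[0]) / 2.0
    b_lo, b_hi = 0.5 - s, 0.5 + s
    f_e = lambda b: b**2
    f_s = lambda b: 2 * b - b**2
    out = {"m1": b_hi - b_lo,
           "m2": k_elbow * (f_e(b_hi) - f_e(b_lo)),
           "m3": k_shoulder * (f_s(b_hi) - f_s(b_lo))}
    if b_hi > 0.5:
        re_u = k_elbow * (f_e(b_hi) - f_e(0.5))
        rs_u = k_shoulder * (f_s(b_hi) - f_s(0.5))
        rb_u = b_hi - 0.5
        out |= {"m4": re_u / rs_u, "m6": rs_u / rb_u, "m8": re_u / rb_u}
    if b_lo < 0.5:
        re_l = k_elbow * (f_e(0.5) - f_e(b_lo))
        rs_l = k_shoulder * (f_s(0.5) - f_s(b_lo))
        rb_l = 0.5 - b_lo
        out |= {"m5": re_l / rs_l, "m7": rs_l / rb_l, "m9": re_l / rb_l}
    return out


def _ground_truth(trial: ParticipantTrial) -> dict[str, float]:
    """Scripted generative metric values of one trial.

    Analytic where the deviation model admits a closed form (spatial
    block without guidance, timing sums, circular statistics of the
    realised boundaries); otherwise evaluated on the generator's own
    trajectory-level signals with the true stroke boundaries, so a
    marker-level reanalysis isolates the IO / frame / angle / stroke
    recovery.
    """
    teacher = trial.teacher
    rate = trial.trace.rate
    n = trial.trace.n_frames
    gt: dict[str, float] = {}

    # spatial block on the realised internal signals: with bow noise and
    # per-stroke offsets the ROMs exceed the noise-free closed forms of
    # expected_spatial (which zero-noise tests check exactly)
    gt.update(met.spatial_block(trial.angles, trial.trace))

    strokes = _true_strokes(trial.event_times, rate, trial.trace.b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gt["m10"] = met.grouped_variability(trial.angles.elbow_fe, strokes)
        gt["m11"] = met.grouped_variability(trial.angles.shoulder_aa, strokes)
        gt["m12"] = met.grouped_coordination_variability(
            trial.angles.elbow_fe, trial.angles.shoulder_aa, strokes)

    ev_p = trial.event_times[1:-1]
    ev_t = teacher.interior_events
    gt["m13"] = float(np.sum(ev_p - ev_t))
    gt["m14"] = met.euclidean_distance(trial.trace.b, teacher.trace.b)
    gt["m15"] = met.sparc_per_stroke(trial.trace.v, strokes, rate)
    gt["m16"], gt["m17"] = met.synchronization(ev_p, ev_t)
    return gt


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------


def analyze_trial(
    markers: MarkerFrameSeries,
    teacher_markers: MarkerFrameSeries,
    marker_map: dict[str, str] | None = None,
    **kwargs,
) -> met.MetricVector:
    """Marker-level analysis of one trial: frames, angles, bow trace and
    all 17 metrics, for participant and teacher marker streams on a
    common clock."""
    out = []
    for series in (markers, teacher_markers):
        frames = build_frames(series, marker_map)
        angles = joint_angle_series(frames, series.rate)
        trace = bow_trace(series, marker_map)
        out.append((angles, trace))
    return met.compute_all(out[0], out[1], **kwargs)


@dataclass(frozen=True)
class RatingModel:
    """Simulated expert panel.

    The latent quality of a video is a weighted sum of z-scored metric
    ground truths; each rater adds a persistent bias and per-video
    noise, and the latent score is cut into the ordinal 1-7 scale at
    ``thresholds``.  ``noise_sd`` and ``bias_sd`` are sized so the
    panel's ICC(2,1) reproduces the reliability reported for real expert
    panels on this task (~0.7).
    """

    weights: tuple[tuple[str, float], ...] = (("m2", 1.0), ("m14", -1.5))
    noise_sd: float = 1.6
    bias_sd: float = 0.4
    thresholds: tuple[float, ...] = (-3.2, -1.92, -0.64, 0.64, 1.92, 3.2)
    n_raters: int = 5

    def __post_init__(self):
        if list(self.thresholds) != sorted(self.thresholds):
            raise ParameterError("thresholds must be strictly increasing")
        if len(set(self.thresholds)) != len(self.thresholds):
            raise ParameterError("thresholds must be strictly increasing")

    def rate_videos(self, truth: pd.DataFrame, rng: np.random.Generator):
        """Ordinal scores (n_raters x n_videos) and the latent qualities.

        ``truth`` has one row per video with the ground-truth metric
        columns used by ``weights``.
        """
        latent = np.zeros(len(truth))
        for mid, w in self.weights:
            col = truth[mid].to_numpy(dtype=float)
            sd = np.nanstd(col)
            if sd > 0:
                latent = latent + w * (col - np.nanmean(col)) / sd
        bias = rng.normal(0.0, self.bias_sd, size=self.n_raters)
        noisy = (latent[None, :] + bias[:, None]
                 + rng.normal(0.0, self.noise_sd, size=(self.n_raters, len(truth))))
        scores = 1 + np.searchsorted(np.asarray(self.thresholds), noisy).astype(float)
        return scores, latent


DEFAULT_RATING_MODEL = RatingModel()


def default_study_profiles() -> dict[tuple[str, str], ParticipantProfile]:
    """Nominal deviation profiles per (group, stage).

    Both groups start equally unpractised at baseline; during training
    the AVE group plays under the haptic field while AV improves only
    mildly; at recall both groups have learned, AVE more, mirroring the
    direction of the study's findings (larger baseline-to-recall gains
    in bow fidelity and elbow ROM under haptic training).
    """
    baseline = ParticipantProfile(
        amplitude_scale=0.72, timing_jitter_sd=0.12, lag=0.18,
        smoothness_noise_sd=0.0015, coordination_ratio=0.55, profile_noise_sd=2.5)
    training = ParticipantProfile(
        amplitude_scale=0.80, timing_jitter_sd=0.10, lag=0.14,
        smoothness_noise_sd=0.0012, coordination_ratio=0.60, profile_noise_sd=2.2)
    recall_av = ParticipantProfile(
        amplitude_scale=0.85, timing_jitter_sd=0.08, lag=0.10,
        smoothness_noise_sd=0.0010, coordination_ratio=0.64, profile_noise_sd=2.0)
    recall_ave = ParticipantProfile(
        amplitude_scale=0.93, timing_jitter_sd=0.06, lag=0.06,
        smoothness_noise_sd=0.0007, coordination_ratio=0.68, profile_noise_sd=1.6)
    return {
        ("AV", "S1"): baseline,
        ("AVE", "S1"): baseline,
        ("AV", "S2"): training,
        ("AVE", "S2"): replace(training, guidance=GuidanceParams()),
        ("AV", "S3"): recall_av,
        ("AVE", "S3"): recall_ave,
    }


@dataclass
class StudyResult:
    """Output of :func:`simulate_study`."""

    metric_table: pd.DataFrame  # participant, group, exercise, stage, metric, value
    ratings: "object"  # stats.RatingMatrix
    ground_truth: pd.DataFrame  # same keys, metric, truth
    seed: int


def simulate_study(
    n_per_group: int = 12,
    profiles_by_group_stage: dict[tuple[str, str], ParticipantProfile] | None = None,
    rating_model: RatingModel | None = None,
    seed: int = 0,
    tempo: float = 2.0,
    repeats: int | None = None,
    skill_spread: float = 0.2,
    marker_sink=None,
) -> StudyResult:
    """A full factorial synthetic study.

    ``n_per_group`` participants per group x 3 exercises x 3 stages;
    the AVE training stage is generated with guidance on.  Metrics are
    recovered through the marker-level analysis path; expert ratings are
    produced for the S1/S3 videos by the rating model.  ``skill_spread``
    is the SD of the log-normal individual factor scaling each
    participant's deviations.  ``marker_sink(meta, markers)``, if given,
    receives every generated marker stream (used by the CLI to
    materialise a study directory).
    """
    from .stats import RatingMatrix  # local import to avoid a cycle

    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    profiles = profiles_by_group_stage or default_study_profiles()
    rating_model = rating_model or DEFAULT_RATING_MODEL
    root = np.random.SeedSequence(seed)
    ss_participants, ss_trials, ss_raters = root.spawn(3)
    part_rng = np.random.default_rng(ss_participants)

    teachers = {ex: generate_teacher(script_for(ex, tempo=tempo, repeats=repeats))
                for ex in (1, 2, 3)}

    groups = ["AVE"] * n_per_group + ["AV"] * n_per_group
    skill = np.exp(part_rng.normal(0.0, skill_spread, size=2 * n_per_group))
    trial_seeds = iter(np.random.default_rng(ss_trials).integers(0, 2**31, size=10**6))

    metric_rows, truth_rows = [], []
    for pid in range(1, 2 * n_per_group + 1):
        group = groups[pid - 1]
        for ex in (1, 2, 3):
            teacher = teachers[ex]
            for stage in ("S1", "S2", "S3"):
                profile = profiles[(group, stage)].scaled(skill[pid - 1])
                trial = generate_participant(teacher, profile, seed=int(next(trial_seeds)))
                meta = TrialMeta(pid, group, ex, stage)
                if marker_sink is not None:
                    marker_sink(meta, trial.markers)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mv = analyze_trial(trial.markers, teacher.markers)
                base = {"participant": pid, "group": group,
                        "exercise": ex, "stage": stage}
                for mid, val in mv.as_dict().items():
                    metric_rows.append(base | {"metric": mid, "value": val})
                for mid, val in trial.ground_truth.items():
                    truth_rows.append(base | {"metric": mid, "truth": val})

    metric_table = pd.DataFrame(metric_rows)
    ground_truth = pd.DataFrame(truth_rows)

    # expert panel on the S1/S3 videos
    rated = ground_truth[ground_truth["stage"].isin(["S1", "S3"])]
    wide = rated.pivot_table(
        index=["participant", "group", "exercise", "stage"],
        columns="metric", values="truth").reset_index()
    rater_rng = np.random.default_rng(ss_raters)
    scores, _ = rating_model.rate_videos(wide, rater_rng)
    video_ids = [
        f"P{int(r.participant):02d}_{r.group}_E{int(r.exercise)}_{r.stage}"
        for r in wide.itertuples()
    ]
    meta = wide[["participant", "group", "exercise", "stage"]].copy()
    meta.index = pd.Index(video_ids, name="video_id")
    ratings = RatingMatrix(
        raters=[f"R{i + 1}" for i in range(rating_model.n_raters)],
        videos=video_ids,
        scores=scores,
        video_meta=meta,
    )
    return StudyResult(metric_table, ratings, ground_truth, seed)


def simulate_metric_table(
    n_per_group: int = 12,
    interaction: float = 0.0,
    sd_participant: float = 1.0,
    sd_resid: float = 0.5,
    seed: int = 0,
    metric: str = "m14",
) -> pd.DataFrame:
    """Metric-level study table for calibrating the contrast bootstrap.

    Draws one metric directly from a mixed model — participant random
    intercepts plus residual noise per exercise — with no group or stage
    main effects and an S3 improvement in AVE of size ``interaction``
    (so the baseline-recall difference-in-differences contrast equals
    ``interaction``).  Orders of magnitude faster than a marker-level
    study; used for repeated-simulation calibration of type-I behaviour
    and effect recovery.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for group in ("AVE", "AV"):
        for _ in range(n_per_group):
            pid += 1
            u = rng.normal(0.0, sd_participant)
            for ex in (1, 2, 3):
                for stage in ("S1", "S2", "S3"):
                    mu = 0.0
                    if group == "AVE" and stage == "S3":
                        mu -= interaction  # AVE improves (value drops) more
                    rows.append({
                        "participant": pid, "group": group, "exercise": ex,
                        "stage": stage, "metric": metric,
                        "value": mu + u + rng.normal(0.0, sd_resid),
                    })
    return pd.DataFrame(rows)
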