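"""The 17 per-trial performance metrics.

Given a participant's joint angles and bow trace plus the teacher's
reference, one :class:`MetricVector` is computed per trial:

* m1-m9 (spatial): bow range, ROM of elbow FE and shoulder AA, and the
  six interjoint / joint-bow ROM ratios restricted to the upper (tip,
  b > 0.5) and lower bow halves;
* m10-m12 (spatial variability): mean across normalised time of the
  across-stroke SD of elbow FE and shoulder AA profiles, and the mean
  circular SD of the elbow-shoulder vector-coding coupling angle;
* m13 (temporal): signed sum of matched direction-change time
  differences, participant minus teacher;
* m14-m17 (spatiotemporal): percent-of-bow-length RMS distance between
  bow traces, spectral arc length (SPARC) of the per-stroke bow speed,
  and the synchronisation strength / phase shift of participant events
  within teacher stroke cycles.

An undefined metric (degenerate denominator, too few strokes, empty
event list) is an explicit NaN marker, excluded pairwise from any
statistic downstream, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.fft import rfft, rfftfreq

from .errors import AlignmentError, ParameterError
from .kinematics import BowTrace, JointAngleSeries
from .mocap_io import TrialMeta
from .strokes import (
    Stroke,
    detect_direction_changes,
    group_strokes,
    half_masks,
    normalize_profiles,
    segment,
)

__all__ = [
    "MetricVector",
    "SparcParams",
    "METRIC_IDS",
    "rom",
    "spatial_block",
    "variability",
    "coordination_variability",
    "grouped_variability",
    "grouped_coordination_variability",
    "timing_difference",
    "match_events",
    "euclidean_distance",
    "sparc",
    "synchronization",
    "compute_all",
]

UNDEFINED = float("nan")

METRIC_IDS = tuple(f"m{i}" for i in range(1, 18))


@dataclass
class MetricVector:
    """The 17 named performance metrics of one trial (NaN = undefined)."""

    m1: float = UNDEFINED   # bow range used (bow-length fraction)
    m2: float = UNDEFINED   # ROM elbow FE (deg)
    m3: float = UNDEFINED   # ROM shoulder AA (deg)
    m4: float = UNDEFINED   # elbow/shoulder ROM ratio, upper half
    m5: float = UNDEFINED   # elbow/shoulder ROM ratio, lower half
    m6: float = UNDEFINED   # shoulder ROM / bow portion, upper half
    m7: float = UNDEFINED   # shoulder ROM / bow portion, lower half
    m8: float = UNDEFINED   # elbow ROM / bow portion, upper half
    m9: float = UNDEFINED   # elbow ROM / bow portion, lower half
    m10: float = UNDEFINED  # elbow FE profile variability (deg)
    m11: float = UNDEFINED  # shoulder AA profile variability (deg)
    m12: float = UNDEFINED  # coordination (coupling-angle) variability (deg)
    m13: float = UNDEFINED  # summed signed timing difference (s)
    m14: float = UNDEFINED  # bow-position RMS distance (percent of bow length)
    m15: float = UNDEFINED  # SPARC smoothness (dimensionless, negative)
    m16: float = UNDEFINED  # synchronisation strength, mean resultant length [0,1]
    m17: float = UNDEFINED  # phase shift, circular mean (rad, [-pi, pi))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def defined(self) -> dict[str, bool]:
        return {k: bool(np.isfinite(v)) for k, v in self.as_dict().items()}


@dataclass(frozen=True)
class SparcParams:
    """Spectral-arc-length parameters: maximum cutoff (Hz), normalised
    amplitude threshold for the adaptive cutoff, and zero-padding level
    (FFT length 2**(ceil(log2 n) + pad_level))."""

    f_max: float = 10.0
    amp_threshold: float = 0.05
    pad_level: int = 4

    def __post_init__(self):
        if not 0 < self.amp_threshold < 1:
            raise ParameterError("amp_threshold must lie in (0, 1)")
        if self.f_max <= 0:
            raise ParameterError("f_max must be positive")
        if self.pad_level < 0:
            raise ParameterError("pad_level must be >= 0")


# ---------------------------------------------------------------------------
# Spatial
# ---------------------------------------------------------------------------


def rom(channel: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Range of motion: max - min over unmasked frames (NaN if < 2 samples)."""
    x = np.asarray(channel, dtype=float)
    if mask is not None:
        x = x[np.asarray(mask, dtype=bool)]
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return UNDEFINED
    return float(x.max() - x.min())


_MIN_DENOM = 1e-6


def _ratio(num: float, den: float) -> float:
    if not np.isfinite(num) or not np.isfinite(den) or den < _MIN_DENOM:
        return UNDEFINED
    return num / den


def spatial_block(
    angles: JointAngleSeries,
    trace: BowTrace,
    masks: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[str, float]:
    """Metrics m1-m9 from the whole-exercise and per-half ROMs."""
    upper, lower = half_masks(trace) if masks is None else masks
    b, elbow, shoulder = trace.b, angles.elbow_fe, angles.shoulder_aa
    rb_u, rb_l = rom(b, upper), rom(b, lower)
    re_u, re_l = rom(elbow, upper), rom(elbow, lower)
    rs_u, rs_l = rom(shoulder, upper), rom(shoulder, lower)
    return {
        "m1": rom(b),
        "m2": rom(elbow),
        "m3": rom(shoulder),
        "m4": _ratio(re_u, rs_u),
        "m5": _ratio(re_l, rs_l),
        "m6": _ratio(rs_u, rb_u),
        "m7": _ratio(rs_l, rb_l),
        "m8": _ratio(re_u, rb_u),
        "m9": _ratio(re_l, rb_l),
    }


def variability(profiles: list[np.ndarray]) -> float:
    """Mean over normalised time of the across-stroke sample SD (ddof 1)."""
    if len(profiles) < 2:
        return UNDEFINED
    stack = np.vstack(profiles)
    return float(np.std(stack, axis=0, ddof=1).mean())


#: mean resultant lengths below this are treated as zero; the circular SD
#: is capped at sqrt(-2 ln cap), the documented finite stand-in for the
#: unbounded uniform-distribution limit
_RBAR_FLOOR = 1e-12


def circular_sd_deg(angles_rad: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln Rbar), returned in degrees."""
    z = np.exp(1j * np.asarray(angles_rad, dtype=float))
    rbar = max(abs(z.mean()), _RBAR_FLOOR)
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def coordination_variability(
    elbow_profiles: list[np.ndarray],
    shoulder_profiles: list[np.ndarray],
) -> float:
    """Vector-coding coordination variability between elbow FE and shoulder AA.

    Per stroke and per adjacent normalised-time step the coupling angle
    is ``atan2(d shoulder_aa, d elbow_fe)``; at each step the circular SD
    across strokes is taken (steps where a stroke shows no motion in
    either joint skip that stroke) and the metric is the mean over steps.
    """
    if len(elbow_profiles) != len(shoulder_profiles):
        raise ParameterError("elbow and shoulder profile lists must be matched")
    if len(elbow_profiles) < 2:
        return UNDEFINED
    de = np.diff(np.vstack(elbow_profiles), axis=1)
    ds = np.diff(np.vstack(shoulder_profiles), axis=1)
    moving = (de != 0) | (ds != 0)
    gamma = np.arctan2(ds, de)
    sds = []
    for j in range(gamma.shape[1]):
        sel = moving[:, j]
        if sel.sum() < 2:
            continue
        sds.append(circular_sd_deg(gamma[sel, j]))
    if not sds:
        return UNDEFINED
    return float(np.mean(sds))


def grouped_variability(
    channel: np.ndarray,
    strokes: list[Stroke],
    n_points: int = 101,
) -> float:
    """Across-stroke profile variability pooled within comparability
    classes (direction x bow extent), averaged over classes with >= 2
    strokes.  Down- and up-bows, or full and half bows, are never mixed:
    their profiles differ by construction, not by motor variability."""
    values = []
    for group in group_strokes(strokes).values():
        if len(group) < 2:
            continue
        profiles = normalize_profiles(channel, group, n_points)
        v = variability(profiles)
        if np.isfinite(v):
            values.append(v)
    if not values:
        return UNDEFINED
    return float(np.mean(values))


def grouped_coordination_variability(
    elbow: np.ndarray,
    shoulder: np.ndarray,
    strokes: list[Stroke],
    n_points: int = 101,
) -> float:
    """Vector-coding coordination variability pooled within stroke
    comparability classes, averaged over classes."""
    values = []
    for group in group_strokes(strokes).values():
        if len(group) < 2:
            continue
        pe = normalize_profiles(elbow, group, n_points)
        ps = normalize_profiles(shoulder, group, n_points)
        v = coordination_variability(pe, ps)
        if np.isfinite(v):
            values.append(v)
    if not values:
        return UNDEFINED
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Temporal
# ---------------------------------------------------------------------------


def match_events(
    events_p: np.ndarray, events_t: np.ndarray
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of participant to teacher events by
    ascending absolute time difference.  Returns (teacher_idx,
    participant_idx) pairs."""
    events_p = np.asarray(events_p, dtype=float)
    events_t = np.asarray(events_t, dtype=float)
    pairs = [
        (abs(tp - tt), k, j)
        for k, tt in enumerate(events_t)
        for j, tp in enumerate(events_p)
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    matched = []
    for _, k, j in pairs:
        if k in used_t or j in used_p:
            continue
        used_t.add(k)
        used_p.add(j)
        matched.append((k, j))
    matched.sort()
    return matched


def timing_difference(events_p: np.ndarray, events_t: np.ndarray) -> float:
    """Summed signed (participant - teacher) time difference over
    greedily matched event pairs; captures cumulative drift over the
    exercise.  NaN when either train is empty."""
    events_p = np.asarray(events_p, dtype=float)
    events_t = np.asarray(events_t, dtype=float)
    if len(events_p) == 0 or len(events_t) == 0:
        return UNDEFINED
    if np.any(np.diff(events_p) < 0) or np.any(np.diff(events_t) < 0):
        raise ParameterError("event lists must be sorted")
    matched = match_events(events_p, events_t)
    return float(sum(events_p[j] - events_t[k] for k, j in matched))


# ---------------------------------------------------------------------------
# Spatiotemporal
# ---------------------------------------------------------------------------


def euclidean_distance(b_p: np.ndarray, b_t: np.ndarray) -> float:
    """100 x RMS of the normalised bow-position difference (percent of
    bow length)."""
    b_p = np.asarray(b_p, dtype=float)
    b_t = np.asarray(b_t, dtype=float)
    if b_p.shape != b_t.shape:
        raise AlignmentError("bow traces must be aligned and of equal length")
    return float(100.0 * np.sqrt(np.mean((b_p - b_t) ** 2)))


def sparc(
    speed: np.ndarray, rate: float, params: SparcParams = SparcParams()
) -> float:
    """Spectral arc length of one movement's speed profile.

    Negative arc length of the magnitude spectrum normalised by its DC
    value, over the adaptive band [0, f_c] with f_c = min(f_max, highest
    frequency whose normalised amplitude still reaches amp_threshold),
    the frequency axis normalised by the selected cutoff.  Closer to 0 is
    smoother; amplitude scaling leaves the value unchanged.
    """
    speed = np.asarray(speed, dtype=float)
    if len(speed) < 8:
        return UNDEFINED
    if not np.any(speed != 0):
        return UNDEFINED
    n_fft = int(2 ** (np.ceil(np.log2(len(speed))) + params.pad_level))
    mag = np.abs(rfft(speed, n_fft))
    freqs = rfftfreq(n_fft, 1.0 / rate)
    mag = mag / mag[0]
    band = freqs <= params.f_max
    f_sel, m_sel = freqs[band], mag[band]
    above = np.flatnonzero(m_sel >= params.amp_threshold)
    lo, hi = above[0], above[-1]  # above is never empty: DC bin is 1
    f_sel, m_sel = f_sel[lo : hi + 1], m_sel[lo : hi + 1]
    if len(f_sel) < 2:
        return 0.0
    f_span = f_sel[-1] - f_sel[0]
    return float(-np.sum(np.hypot(np.diff(f_sel) / f_span, np.diff(m_sel))))


def sparc_per_stroke(
    v: np.ndarray,
    strokes_list: list[Stroke],
    rate: float,
    params: SparcParams = SparcParams(),
) -> float:
    """Trial-level SPARC: mean of per-stroke values on the bow speed
    magnitude (strokes shorter than 8 frames are skipped)."""
    values = [
        sparc(np.abs(v[s.i_start : s.i_end]), rate, params)
        for s in strokes_list
        if s.n_frames >= 8
    ]
    values = [x for x in values if np.isfinite(x)]
    if not values:
        return UNDEFINED
    return float(np.mean(values))


def synchronization(
    events_p: np.ndarray, events_t: np.ndarray
) -> tuple[float, float]:
    """Event-based synchronisation of participant to teacher cycles.

    For each teacher inter-event interval [t_k, t_{k+1}) the participant
    event nearest to t_k defines the relative phase
    ``2 pi (t_p - t_k) / (t_{k+1} - t_k)`` wrapped to [-pi, pi).  Returns
    (strength, phase): the mean resultant length of the phases and their
    circular mean.  NaN markers when fewer than 2 intervals exist.
    """
    events_p = np.asarray(events_p, dtype=float)
    events_t = np.asarray(events_t, dtype=float)
    if len(events_t) < 3 or len(events_p) == 0:
        return UNDEFINED, UNDEFINED
    phases = []
    for t0, t1 in zip(events_t[:-1], events_t[1:]):
        if t1 <= t0:
            continue
        tp = events_p[np.argmin(np.abs(events_p - t0))]
        phi = 2.0 * np.pi * (tp - t0) / (t1 - t0)
        phases.append(np.angle(np.exp(1j * phi)))  # wrap to [-pi, pi)
    if len(phases) < 2:
        return UNDEFINED, UNDEFINED
    z = np.exp(1j * np.asarray(phases)).mean()
    return float(abs(z)), float(np.angle(z))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def compute_all(
    participant: tuple[JointAngleSeries, BowTrace],
    teacher: tuple[JointAngleSeries, BowTrace],
    meta: TrialMeta | None = None,
    *,
    sparc_params: SparcParams = SparcParams(),
    min_excursion: float = 0.05,
    min_interval: float = 0.25,
    n_points: int = 101,
) -> MetricVector:
    """All 17 metrics for one aligned participant/teacher trial.

    Sub-operation NaN markers propagate; spatial metrics are computed
    even when no strokes are detectable.
    """
    angles_p, trace_p = participant
    angles_t, trace_t = teacher
    if trace_p.n_frames != trace_t.n_frames:
        raise AlignmentError("participant and teacher traces must be aligned")

    out = MetricVector()
    for key, val in spatial_block(angles_p, trace_p).items():
        setattr(out, key, val)

    events_p = detect_direction_changes(trace_p, min_excursion, min_interval)
    events_t = detect_direction_changes(trace_t, min_excursion, min_interval)
    strokes_p = segment(trace_p, events_p)

    out.m10 = grouped_variability(angles_p.elbow_fe, strokes_p, n_points)
    out.m11 = grouped_variability(angles_p.shoulder_aa, strokes_p, n_points)
    out.m12 = grouped_coordination_variability(
        angles_p.elbow_fe, angles_p.shoulder_aa, strokes_p, n_points)

    out.m13 = timing_difference(events_p, events_t)
    out.m14 = euclidean_distance(trace_p.b, trace_t.b)
    out.m15 = sparc_per_stroke(trace_p.v, strokes_p, trace_p.rate, sparc_params)
    out.m16, out.m17 = synchronization(events_p, events_t)
    return out
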