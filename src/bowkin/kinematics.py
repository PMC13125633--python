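"""Segment coordinate frames, ISB joint angles and the bow-string contact.

Segment frames are right-handed orthonormal triads built from 3+ markers
per segment.  The conventions follow the International Society of
Biomechanics recommendations for the upper limb:

* shoulder — orientation of the humerus relative to the thorax,
  decomposed with the intrinsic Y-X'-Y'' sequence: plane of elevation
  ("horizontal" abduction-adduction, AA), elevation (E, positive upward)
  and internal-external axial rotation (IE, internal positive);
* elbow — intrinsic Z-X-Y: flexion-extension (FE, 0 deg at full
  extension), carrying angle (discarded), pronation-supination (PS,
  pronation positive);
* wrist — intrinsic Z-X-Y: flexion-extension (flexion positive) and
  radial-ulnar deviation (AA, radial positive); axial rotation discarded.

Within each segment frame the Y axis points proximally along the segment
long axis, X points laterally (right) and Z completes the right-handed
triad.  All angles are in degrees, unwrapped per channel so no +-180 deg
jumps remain between adjacent frames.

The bow-string contact coordinate ``b`` is the parameter of the point of
closest approach between the bow long axis (frog -> tip line) and the
string line (the violin long axis through the bridge midpoint), divided
by bow length: 0 at the frog, 1 at the tip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, DegenerateGeometryError, ParameterError
from .mocap_io import MarkerFrameSeries

__all__ = [
    "DEFAULT_MARKER_MAP",
    "SEGMENT_ROLES",
    "SegmentFrame",
    "JointAngleSeries",
    "BowTrace",
    "build_frames",
    "shoulder_angles",
    "elbow_angles",
    "wrist_angles",
    "joint_angle_series",
    "bow_trace",
    "write_joint_angles_tsv",
]

#: Default mapping from anatomical role to marker label.  The study's
#: marker set follows the Qualisys Animation Marker Set with unspecified
#: adjustments, so the map is configurable; these labels are the
#: package's documented defaults (and the ones the synthetic generator
#: emits).
DEFAULT_MARKER_MAP: dict[str, str] = {
    "c7": "C7",
    "t8": "T8",
    "sternum_top": "STRN_TOP",
    "sternum_bottom": "STRN_BOT",
    "r_shoulder": "RSHO",
    "r_elbow_lat": "RELB_LAT",
    "r_elbow_med": "RELB_MED",
    "r_wrist_rad": "RWRI_RAD",
    "r_wrist_uln": "RWRI_ULN",
    "r_hand_2": "RHND2",
    "r_hand_5": "RHND5",
    "bow_frog": "BOW_FROG",
    "bow_mid": "BOW_MID",
    "bow_tip": "BOW_TIP",
    "violin_scroll": "VIO_SCROLL",
    "violin_bridge_l": "VIO_BRL",
    "violin_bridge_r": "VIO_BRR",
    "violin_tailpiece": "VIO_TAIL",
}

#: Roles each segment frame is constructed from.
SEGMENT_ROLES: dict[str, tuple[str, ...]] = {
    "thorax": ("c7", "t8", "sternum_top", "sternum_bottom"),
    "humerus": ("r_shoulder", "r_elbow_lat", "r_elbow_med"),
    "forearm": ("r_elbow_lat", "r_elbow_med", "r_wrist_rad", "r_wrist_uln"),
    "hand": ("r_wrist_rad", "r_wrist_uln", "r_hand_2", "r_hand_5"),
    "bow": ("bow_frog", "bow_mid", "bow_tip"),
    "violin": ("violin_scroll", "violin_bridge_l", "violin_bridge_r", "violin_tailpiece"),
}

_COLLINEAR_TOL = 1e-8  # relative residual below which markers count as collinear
_GIMBAL_TOL_DEG = 1e-3


@dataclass
class SegmentFrame:
    """Per-frame pose of one rigid segment.

    ``origins`` has shape (n_frames, 3) in mm; ``rotations`` has shape
    (n_frames, 3, 3) with the frame's X, Y, Z axes as columns.  Every
    rotation is orthonormal with determinant +1.
    """

    origins: np.ndarray
    rotations: np.ndarray

    def __post_init__(self):
        self.origins = np.atleast_2d(np.asarray(self.origins, dtype=float))
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.rotations.ndim == 2:
            self.rotations = self.rotations[None]
        rtr = np.einsum("fij,fik->fjk", self.rotations, self.rotations)
        if not np.allclose(rtr, np.eye(3), atol=1e-9):
            raise ParameterError("segment axes are not orthonormal")
        if not np.allclose(np.linalg.det(self.rotations), 1.0, atol=1e-9):
            raise ParameterError("segment axes are not right-handed")

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]


@dataclass
class JointAngleSeries:
    """Per-frame anatomical angles of the right bowing arm, in degrees."""

    rate: float
    shoulder_aa: np.ndarray
    shoulder_e: np.ndarray
    shoulder_ie: np.ndarray
    elbow_fe: np.ndarray
    elbow_ps: np.ndarray
    wrist_fe: np.ndarray
    wrist_aa: np.ndarray
    gimbal: np.ndarray = None  # type: ignore[assignment]

    CHANNELS = ("shoulder_aa", "shoulder_e", "shoulder_ie",
                "elbow_fe", "elbow_ps", "wrist_fe", "wrist_aa")

    def __post_init__(self):
        n = len(self.shoulder_aa)
        for name in self.CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ParameterError("all angle channels must have equal length")
            setattr(self, name, arr)
        if self.gimbal is None:
            self.gimbal = np.zeros(n, dtype=bool)
        if self.rate <= 0:
            raise ParameterError("rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.shoulder_aa)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.CHANNELS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class BowTrace:
    """Normalised bow-string contact coordinate over time.

    ``b`` runs from 0 (frog) to 1 (tip) after clipping; ``v`` is its
    centered finite difference times the sampling rate (1/s).
    ``clip_fraction`` and ``parallel_flags`` are QC outputs: the fraction
    of frames clipped into [0, 1], and the frames where bow and string
    were near-parallel so ``b`` was carried over from the previous frame.
    """

    rate: float
    b: np.ndarray
    v: np.ndarray = None  # type: ignore[assignment]
    bow_length: float = float("nan")
    clip_fraction: float = 0.0
    parallel_flags: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.v is None:
            self.v = bow_velocity(self.b, self.rate)
        self.v = np.asarray(self.v, dtype=float)
        if self.parallel_flags is None:
            self.parallel_flags = np.zeros(len(self.b), dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.b)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


def bow_velocity(b: np.ndarray, rate: float) -> np.ndarray:
    """Centered finite difference of ``b`` times the sampling rate."""
    if len(b) < 2:
        return np.zeros_like(b)
    return np.gradient(np.asarray(b, dtype=float)) * rate


# ---------------------------------------------------------------------------
# Frame construction
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    bad = np.flatnonzero(norm.ravel() < 1e-12)
    if bad.size:
        raise DegenerateGeometryError(f"zero-length {what} direction", frame=int(bad[0]))
    return v / norm


def _orthogonal_frame(y_raw: np.ndarray, x_hint: np.ndarray, segment: str) -> np.ndarray:
    """Right-handed rotation matrices with Y along ``y_raw`` and X the
    component of ``x_hint`` orthogonal to Y.  Raises on collinearity."""
    y = _unit(y_raw, f"{segment} long-axis")
    x_rej = x_hint - np.sum(x_hint * y, axis=-1, keepdims=True) * y
    scale = np.linalg.norm(x_hint, axis=-1)
    resid = np.linalg.norm(x_rej, axis=-1)
    bad = np.flatnonzero(resid < _COLLINEAR_TOL * np.maximum(scale, 1e-12))
    if bad.size:
        raise DegenerateGeometryError(
            f"collinear markers for segment {segment!r}", frame=int(bad[0])
        )
    x = x_rej / resid[..., None]
    z = np.cross(x, y)
    return np.stack([x, y, z], axis=-1)


def _resolve(series: MarkerFrameSeries, marker_map: dict[str, str], role: str) -> np.ndarray:
    if role not in marker_map:
        raise ConfigurationError(f"marker map is missing role {role!r}")
    label = marker_map[role]
    if label not in series.labels:
        raise ConfigurationError(f"marker {label!r} (role {role!r}) not in series")
    return series.marker(label)


def build_frames(
    series: MarkerFrameSeries,
    marker_map: dict[str, str] | None = None,
    segments: tuple[str, ...] = ("thorax", "humerus", "forearm", "hand", "bow", "violin"),
) -> dict[str, SegmentFrame]:
    """Construct per-frame segment coordinate frames from markers.

    Constructions (all Y proximal / along the long axis, X lateral):

    * thorax — Y from the mid-point of (T8, lower sternum) to the
      mid-point of (C7, upper sternum); Z anterior, toward the sternum
      mid-point; origin at the C7/upper-sternum mid-point.
    * humerus — Y from the elbow epicondyle mid-point up to the shoulder
      marker; X along the lateral->medial epicondyle line's lateral
      component; origin at the shoulder.
    * forearm — Y from the wrist styloid mid-point up to the epicondyle
      mid-point; X along the radial styloid direction; origin at the
      epicondyle mid-point.
    * hand — Y from the knuckle mid-point up to the styloid mid-point;
      X along the index->little knuckle lateral direction; origin at the
      styloid mid-point.
    * bow — X from frog to tip; the mid-bow marker fixes the plane.
    * violin — X from tailpiece to scroll (the string-line direction);
      the bridge markers fix the plane; origin at the bridge mid-point.
    """
    marker_map = dict(DEFAULT_MARKER_MAP if marker_map is None else marker_map)
    if series.occluded.any():
        warnings.warn("series still contains occluded samples; frames there are unreliable")
    get = lambda role: _resolve(series, marker_map, role)
    out: dict[str, SegmentFrame] = {}
    for segment in segments:
        if segment == "thorax":
            c7, t8 = get("c7"), get("t8")
            st, sb = get("sternum_top"), get("sternum_bottom")
            top, bot = 0.5 * (c7 + st), 0.5 * (t8 + sb)
            y_raw = top - bot
            anterior = 0.5 * (st + sb) - 0.5 * (c7 + t8)
            y = _unit(y_raw, "thorax long-axis")
            z_rej = anterior - np.sum(anterior * y, axis=-1, keepdims=True) * y
            resid = np.linalg.norm(z_rej, axis=-1)
            bad = np.flatnonzero(resid < _COLLINEAR_TOL * np.maximum(
                np.linalg.norm(anterior, axis=-1), 1e-12))
            if bad.size:
                raise DegenerateGeometryError(
                    "collinear markers for segment 'thorax'", frame=int(bad[0]))
            z = z_rej / resid[..., None]
            x = np.cross(y, z)
            out[segment] = SegmentFrame(top, np.stack([x, y, z], axis=-1))
        elif segment == "humerus":
            sho = get("r_shoulder")
            elb = 0.5 * (get("r_elbow_lat") + get("r_elbow_med"))
            lat = get("r_elbow_lat") - get("r_elbow_med")
            out[segment] = SegmentFrame(sho, _orthogonal_frame(sho - elb, lat, segment))
        elif segment == "forearm":
            elb = 0.5 * (get("r_elbow_lat") + get("r_elbow_med"))
            wri = 0.5 * (get("r_wrist_rad") + get("r_wrist_uln"))
            rad = get("r_wrist_rad") - get("r_wrist_uln")
            out[segment] = SegmentFrame(elb, _orthogonal_frame(elb - wri, rad, segment))
        elif segment == "hand":
            wri = 0.5 * (get("r_wrist_rad") + get("r_wrist_uln"))
            knu = 0.5 * (get("r_hand_2") + get("r_hand_5"))
            rad = get("r_hand_2") - get("r_hand_5")
            out[segment] = SegmentFrame(wri, _orthogonal_frame(wri - knu, rad, segment))
        elif segment == "bow":
            frog, tip, mid = get("bow_frog"), get("bow_tip"), get("bow_mid")
            x = _unit(tip - frog, "bow long-axis")
            hint = mid - frog
            y_rej = hint - np.sum(hint * x, axis=-1, keepdims=True) * x
            resid = np.linalg.norm(y_rej, axis=-1)
            bad = np.flatnonzero(resid < _COLLINEAR_TOL * np.maximum(
                np.linalg.norm(hint, axis=-1), 1e-12))
            if bad.size:
                raise DegenerateGeometryError(
                    "collinear markers for segment 'bow'", frame=int(bad[0]))
            y = y_rej / resid[..., None]
            out[segment] = SegmentFrame(frog, np.stack([x, y, np.cross(x, y)], axis=-1))
        elif segment == "violin":
            scroll, tail = get("violin_scroll"), get("violin_tailpiece")
            brl, brr = get("violin_bridge_l"), get("violin_bridge_r")
            x = _unit(scroll - tail, "violin long-axis")
            hint = brl - brr
            y_rej = hint - np.sum(hint * x, axis=-1, keepdims=True) * x
            resid = np.linalg.norm(y_rej, axis=-1)
            bad = np.flatnonzero(resid < _COLLINEAR_TOL * np.maximum(
                np.linalg.norm(hint, axis=-1), 1e-12))
            if bad.size:
                raise DegenerateGeometryError(
                    "collinear markers for segment 'violin'", frame=int(bad[0]))
            y = y_rej / resid[..., None]
            out[segment] = SegmentFrame(
                0.5 * (brl + brr), np.stack([x, y, np.cross(x, y)], axis=-1))
        else:
            raise ConfigurationError(f"unknown segment {segment!r}")
    return out


# ---------------------------------------------------------------------------
# Joint angles
# ---------------------------------------------------------------------------


def _relative(proximal: SegmentFrame, distal: SegmentFrame) -> np.ndarray:
    return np.einsum("fji,fjk->fik", proximal.rotations, distal.rotations)


def shoulder_angles(thorax: SegmentFrame, humerus: SegmentFrame):
    """Y-X'-Y'' decomposition of the humerus relative to the thorax.

    Returns ``(aa, e, ie, gimbal)`` arrays in degrees: plane of elevation
    (horizontal AA), elevation (positive upward) and axial rotation
    (internal positive), plus a boolean mask of gimbal-proximal frames
    (elevation within 1e-3 deg of 0 or 180) where AA is resolved by
    carrying the previous frame's value.
    """
    rel = _relative(thorax, humerus)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy gimbal-lock warning; handled below
        ang = Rotation.from_matrix(rel).as_euler("YXY", degrees=True)
    aa, e, ie = ang[:, 0].copy(), ang[:, 1].copy(), ang[:, 2].copy()
    gimbal = (np.abs(e) < _GIMBAL_TOL_DEG) | (np.abs(np.abs(e) - 180.0) < _GIMBAL_TOL_DEG)
    if gimbal.any():
        # in gimbal lock only aa+ie (e=0) or aa-ie (e=180) is observable;
        # keep continuity by carrying the previous frame's aa (leading
        # gimbal frames, with nothing to carry, put the whole rotation in aa)
        total = aa + np.where(np.abs(e) < 90.0, ie, -ie)
        for i in np.flatnonzero(gimbal):
            prev_aa = aa[i - 1] if i > 0 and not gimbal[i - 1] else (
                aa[i - 1] if i > 0 else total[i])
            aa[i] = prev_aa
            ie[i] = (total[i] - prev_aa) if np.abs(e[i]) < 90.0 else (prev_aa - total[i])
    aa, ie = _unwrap_deg(aa), _unwrap_deg(ie)
    return aa, e, ie, gimbal


def elbow_angles(humerus: SegmentFrame, forearm: SegmentFrame):
    """Z-X-Y decomposition of the forearm relative to the humerus.

    Returns ``(fe, ps)`` in degrees: flexion-extension (0 at full
    extension) and pronation-supination (pronation positive).  The middle
    (carrying) angle is discarded.
    """
    rel = _relative(humerus, forearm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ang = Rotation.from_matrix(rel).as_euler("ZXY", degrees=True)
    return _unwrap_deg(ang[:, 0]), _unwrap_deg(ang[:, 2])


def wrist_angles(forearm: SegmentFrame, hand: SegmentFrame):
    """Z-X-Y decomposition of the hand relative to the forearm.

    Returns ``(fe, aa)`` in degrees: flexion (positive) and radial
    deviation (positive).  The axial angle is discarded.
    """
    rel = _relative(forearm, hand)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ang = Rotation.from_matrix(rel).as_euler("ZXY", degrees=True)
    return _unwrap_deg(ang[:, 0]), _unwrap_deg(ang[:, 1])


def _unwrap_deg(x: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(np.asarray(x, dtype=float))))


def joint_angle_series(frames: dict[str, SegmentFrame], rate: float) -> JointAngleSeries:
    """All seven angle channels from a segment-frame set."""
    aa, e, ie, gimbal = shoulder_angles(frames["thorax"], frames["humerus"])
    fe, ps = elbow_angles(frames["humerus"], frames["forearm"])
    wfe, waa = wrist_angles(frames["forearm"], frames["hand"])
    return JointAngleSeries(rate, aa, e, ie, fe, ps, wfe, waa, gimbal)


# ---------------------------------------------------------------------------
# Bow-string contact
# ---------------------------------------------------------------------------


def bow_trace(
    series: MarkerFrameSeries,
    marker_map: dict[str, str] | None = None,
    min_angle_deg: float = 1.0,
) -> BowTrace:
    """Normalised bow-string contact coordinate from bow and violin markers.

    Per frame, the bow axis is the frog->tip line and the string line is
    the violin long axis through the bridge mid-point; ``b`` is the
    closest-approach parameter along the bow axis divided by bow length,
    clipped to [0, 1].  Frames where the two lines subtend less than
    ``min_angle_deg`` carry the previous frame's value and are flagged.
    """
    marker_map = dict(DEFAULT_MARKER_MAP if marker_map is None else marker_map)
    frog = _resolve(series, marker_map, "bow_frog")
    tip = _resolve(series, marker_map, "bow_tip")
    brl = _resolve(series, marker_map, "violin_bridge_l")
    brr = _resolve(series, marker_map, "violin_bridge_r")
    scroll = _resolve(series, marker_map, "violin_scroll")
    tail = _resolve(series, marker_map, "violin_tailpiece")

    lengths = np.linalg.norm(tip - frog, axis=-1)
    bow_length = float(np.median(lengths))
    u = _unit(tip - frog, "bow long-axis")
    d = _unit(scroll - tail, "violin long-axis")
    p0 = 0.5 * (brl + brr)

    w0 = frog - p0
    b_dot = np.sum(u * d, axis=-1)
    denom = 1.0 - b_dot**2
    sin_min = np.sin(np.radians(min_angle_deg))
    parallel = denom < sin_min**2
    d0 = np.sum(u * w0, axis=-1)
    e0 = np.sum(d * w0, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (b_dot * e0 - d0) / denom
    b = s / lengths
    # carry over previous value where geometry is degenerate
    for i in np.flatnonzero(parallel):
        b[i] = b[i - 1] if i > 0 else 0.5
    clipped = (b < 0) | (b > 1)
    b = np.clip(b, 0.0, 1.0)
    return BowTrace(
        rate=series.rate,
        b=b,
        bow_length=bow_length,
        clip_fraction=float(np.mean(clipped)),
        parallel_flags=parallel,
    )


def write_joint_angles_tsv(angles: JointAngleSeries, path) -> None:
    """Tidy tab-separated export: frame, time_s, channel, value_deg."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frame\ttime_s\tchannel\tvalue_deg\n")
        for name in JointAngleSeries.CHANNELS:
            values = angles.channel(name)
            for i, val in enumerate(values):
                fh.write(f"{i}\t{i / angles.rate:.6f}\t{name}\t{val:.6f}\n")
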