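"""Reading, writing, cleaning and time-aligning marker trajectory data.

The pipeline's raw input is optical motion capture: time series of labelled
3-D marker positions, here stored in millimetres at a fixed sampling rate
(120 Hz in the study setup this package models).  Two on-disk formats are
supported: a Qualisys-style tab-separated export and the binary C3D
container.  Occluded samples (markers hidden from the cameras) are carried
as an explicit boolean mask; short occlusion gaps can be spline-filled and
the cleaned signals low-pass filtered before any kinematic computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from . import _c3d
from .errors import AlignmentError, FormatError, ParameterError, ParseError

__all__ = [
    "MarkerFrameSeries",
    "TrialMeta",
    "read_marker_tsv",
    "write_marker_tsv",
    "read_c3d",
    "write_c3d",
    "fill_gaps",
    "lowpass",
    "align_pair",
]

GROUPS = ("AV", "AVE")
STAGES = ("S1", "S2", "S3")
EXERCISES = (1, 2, 3)


@dataclass
class MarkerFrameSeries:
    """Labelled 3-D marker positions over time.

    Attributes
    ----------
    labels : list of str
        Marker names, in file/column order.
    positions : ndarray, shape (n_frames, n_markers, 3)
        Coordinates in millimetres.  Entries flagged in ``occluded`` are
        NaN; everything else is finite.
    rate : float
        Sampling frequency in Hz.
    occluded : ndarray of bool, shape (n_frames, n_markers)
        True where the marker was not observed.
    start_time : float
        Offset of frame 0 on the shared (post-hoc synchronised) clock,
        in seconds.  Frame ``i`` is at ``start_time + i / rate``.
    """

    labels: list[str]
    positions: np.ndarray
    rate: float
    occluded: np.ndarray = None  # type: ignore[assignment]
    start_time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ParameterError("positions must have shape (n_frames, n_markers, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise ParameterError("positions second axis must match number of labels")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.occluded is None:
            self.occluded = np.zeros(self.positions.shape[:2], dtype=bool)
        self.occluded = np.asarray(self.occluded, dtype=bool)
        if self.occluded.shape != self.positions.shape[:2]:
            raise ParameterError("occluded mask must have shape (n_frames, n_markers)")
        bad = ~np.isfinite(self.positions).all(axis=2) & ~self.occluded
        if bad.any():
            raise ParameterError("non-finite positions outside the occlusion mask")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    def times(self) -> np.ndarray:
        """Frame timestamps on the shared clock, in seconds."""
        return self.start_time + np.arange(self.n_frames) / self.rate

    def marker(self, label: str) -> np.ndarray:
        """Positions of one marker, shape (n_frames, 3)."""
        try:
            j = self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not in series") from None
        return self.positions[:, j, :]


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one recorded trial in the two-group, three-stage design."""

    participant_id: int
    group: str  # "AV" (control) or "AVE" (haptic)
    exercise: int  # 1, 2 or 3
    stage: str  # "S1" baseline, "S2" training, "S3" recall

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}")
        if self.exercise not in EXERCISES:
            raise ParameterError(f"exercise must be one of {EXERCISES}")
        if self.stage not in STAGES:
            raise ParameterError(f"stage must be one of {STAGES}")

    @property
    def key(self) -> str:
        return f"P{self.participant_id:02d}_{self.group}_E{self.exercise}_{self.stage}"


# ---------------------------------------------------------------------------
# Qualisys-style TSV
# ---------------------------------------------------------------------------

_HEADER_FIELDS = ("NO_OF_FRAMES", "FREQUENCY", "MARKER_NAMES")


def read_marker_tsv(path) -> MarkerFrameSeries:
    """Read a Qualisys-style tab-separated marker export.

    The header declares ``NO_OF_FRAMES``, ``FREQUENCY`` and
    ``MARKER_NAMES`` (one name per column triple); an optional
    ``START_TIME`` line carries the shared-clock offset.  Each subsequent
    row holds X, Y, Z in millimetres for every marker.  A blank coordinate
    triple, or the sentinel ``0 0 0`` (real markers never sit exactly at
    the origin of the calibrated volume), marks the sample occluded.
    """
    header: dict[str, list[str]] = {}
    rows: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split("\t")
        key = parts[0].strip()
        if key and key.upper() == key and not _is_number(key):
            header[key] = [p.strip() for p in parts[1:]]
            i += 1
        else:
            break
    rows = lines[i:]
    first_data_line = i + 1  # 1-based line number of the first data row

    for fieldname in _HEADER_FIELDS:
        if fieldname not in header:
            raise FormatError(f"missing header field {fieldname}")
    try:
        n_frames = int(header["NO_OF_FRAMES"][0])
        rate = float(header["FREQUENCY"][0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed header value: {exc}") from exc
    labels = [x for x in header["MARKER_NAMES"] if x]
    if not labels:
        raise FormatError("MARKER_NAMES declares no markers")
    start_time = float(header.get("START_TIME", ["0"])[0] or 0.0)

    n_cols = 3 * len(labels)
    positions = np.full((n_frames, len(labels), 3), np.nan)
    occluded = np.zeros((n_frames, len(labels)), dtype=bool)
    data_rows = [r for r in rows if r.strip() != ""]
    if len(data_rows) != n_frames:
        raise FormatError(
            f"NO_OF_FRAMES declares {n_frames} frames but file has {len(data_rows)} data rows"
        )
    for k, row in enumerate(data_rows):
        parts = row.split("\t")
        if len(parts) != n_cols:
            raise ParseError(
                f"expected {n_cols} columns, found {len(parts)}",
                line=first_data_line + k,
            )
        for m in range(len(labels)):
            triple = parts[3 * m : 3 * m + 3]
            if all(p.strip() == "" for p in triple):
                occluded[k, m] = True
                continue
            try:
                xyz = [float(p) for p in triple]
            except ValueError:
                raise ParseError(
                    f"non-numeric coordinate for marker {labels[m]!r}",
                    line=first_data_line + k,
                ) from None
            if xyz == [0.0, 0.0, 0.0]:
                occluded[k, m] = True
            else:
                positions[k, m] = xyz
    return MarkerFrameSeries(labels, positions, rate, occluded, start_time)


def write_marker_tsv(series: MarkerFrameSeries, path) -> None:
    """Write a series in the Qualisys-style TSV layout read by
    :func:`read_marker_tsv`.  Occluded samples are written as blank triples."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"NO_OF_FRAMES\t{series.n_frames}\n")
        fh.write(f"FREQUENCY\t{series.rate:.6f}\n")
        fh.write(f"START_TIME\t{series.start_time:.6f}\n")
        fh.write("MARKER_NAMES\t" + "\t".join(series.labels) + "\n")
        for k in range(series.n_frames):
            cells = []
            for m in range(series.n_markers):
                if series.occluded[k, m]:
                    cells += ["", "", ""]
                else:
                    cells += [f"{c:.6f}" for c in series.positions[k, m]]
            fh.write("\t".join(cells) + "\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# C3D
# ---------------------------------------------------------------------------


def read_c3d(path) -> MarkerFrameSeries:
    """Read marker trajectories from a C3D container.

    POINT data are mapped to millimetres (converted if ``POINT:UNITS`` is
    ``m``); samples with a negative residual are flagged occluded.
    """
    try:
        raw = _c3d.read(path)
    except _c3d.C3DError as exc:
        raise FormatError(str(exc)) from exc
    positions = raw.points.copy()
    if raw.units.strip().lower() == "m":
        positions = positions * 1000.0
    occluded = raw.residuals < 0
    positions[occluded] = np.nan
    return MarkerFrameSeries(list(raw.labels), positions, raw.rate, occluded, 0.0)


def write_c3d(series: MarkerFrameSeries, path) -> None:
    """Write a series as a float-format C3D file (units mm)."""
    residuals = np.where(series.occluded, -1.0, 0.0)
    positions = np.where(series.occluded[..., None], 0.0, series.positions)
    _c3d.write(path, list(series.labels), positions, residuals, series.rate, units="mm")


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def fill_gaps(series: MarkerFrameSeries, max_gap: int) -> MarkerFrameSeries:
    """Fill short occlusion gaps by cubic-spline interpolation.

    Occluded runs of length <= ``max_gap`` frames are replaced, per
    coordinate, by a cubic spline fitted to the marker's observed frames
    and unflagged; longer runs are left occluded.  Runs touching the
    sequence edge are filled by the same spline's boundary extrapolation,
    subject to the same length limit.  Non-occluded samples are never
    modified.
    """
    if max_gap < 0:
        raise ParameterError("max_gap must be >= 0")
    positions = series.positions.copy()
    occluded = series.occluded.copy()
    t = np.arange(series.n_frames)
    for m in range(series.n_markers):
        occ = series.occluded[:, m]
        if not occ.any():
            continue
        if occ.all():
            warnings.warn(
                f"marker {series.labels[m]!r} occluded for the entire trial; left untouched"
            )
            continue
        valid = ~occ
        if max_gap == 0 or valid.sum() < 2:
            continue
        spline = CubicSpline(t[valid], positions[valid, m, :], axis=0, extrapolate=True)
        for start, stop in _runs(occ):
            if stop - start <= max_gap:
                positions[start:stop, m, :] = spline(t[start:stop])
                occluded[start:stop, m] = False
    return replace(series, positions=positions, occluded=occluded)


def _runs(mask: np.ndarray):
    """Yield (start, stop) half-open index ranges of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def lowpass(series: MarkerFrameSeries, cutoff: float = 10.0) -> MarkerFrameSeries:
    """Zero-phase 4th-order Butterworth low-pass, applied per coordinate.

    Implemented as a 2nd-order design run forward and backward
    (``filtfilt``), the standard zero-phase 4th-order filter of upper-limb
    motion capture.  DC is preserved exactly.  All occlusions must have
    been filled (or the marker dropped) first.
    """
    if not 0 < cutoff < series.rate / 2:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist) = (0, {series.rate / 2} Hz)"
        )
    if series.occluded.any():
        raise ParameterError("lowpass requires a gap-free series; run fill_gaps first")
    b, a = butter(2, cutoff / (series.rate / 2))
    flat = series.positions.reshape(series.n_frames, -1)
    smoothed = filtfilt(b, a, flat, axis=0).reshape(series.positions.shape)
    return replace(series, positions=smoothed)


def align_pair(
    a: MarkerFrameSeries, b: MarkerFrameSeries
) -> tuple[MarkerFrameSeries, MarkerFrameSeries]:
    """Crop two equal-rate series to their overlapping shared-clock window.

    Both inputs carry ``start_time`` on the same post-hoc synchronised
    clock.  Alignment is nearest-frame (no sub-frame resampling): frame
    ``i`` of each output corresponds to the same clock time within half a
    frame.
    """
    if abs(a.rate - b.rate) > 1e-9:
        raise AlignmentError(f"rates differ: {a.rate} vs {b.rate} Hz")
    rate = a.rate
    t0 = max(a.start_time, b.start_time)
    t1 = min(a.start_time + a.n_frames / rate, b.start_time + b.n_frames / rate)
    n = int(round((t1 - t0) * rate))
    if n <= 0:
        raise AlignmentError("series do not overlap in time")
    out = []
    for s in (a, b):
        i0 = int(round((t0 - s.start_time) * rate))
        out.append(
            replace(
                s,
                positions=s.positions[i0 : i0 + n],
                occluded=s.occluded[i0 : i0 + n],
                start_time=s.start_time + i0 / rate,
            )
        )
    return out[0], out[1]
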