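"""Minimal C3D container support (POINT section only).

Covers what the pipeline needs from the standard: little-endian (Intel)
files, the POINT group's USED / FRAMES / RATE / SCALE / DATA_START /
UNITS / LABELS parameters, and 3-D point data in floating-point or
scaled-integer form with per-sample residuals.  Analog channels, event
sections and non-Intel processor types are out of scope.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np


class C3DError(Exception):
    pass


@dataclass
class RawC3D:
    labels: list[str]
    points: np.ndarray  # (n_frames, n_points, 3)
    residuals: np.ndarray  # (n_frames, n_points)
    rate: float
    units: str


_BLOCK = 512
_INTEL = 84


def read(path) -> RawC3D:
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 2 * _BLOCK:
        raise C3DError("file too short to be a C3D container")
    param_block, magic = data[0], data[1]
    if magic != 0x50:
        raise C3DError("not a C3D file (bad magic byte)")
    header = struct.unpack_from("<13H", data, 2)
    n_points_hdr = header[0]
    first_frame, last_frame = header[2], header[3]

    params = _read_params(data, param_block)
    point = params.get("POINT")
    if not point:
        raise C3DError("no POINT parameter group")
    n_used = int(_scalar(point, "USED", n_points_hdr))
    if n_used == 0:
        raise C3DError("POINT section declares zero markers")
    n_frames = int(_scalar(point, "FRAMES", last_frame - first_frame + 1))
    rate = float(_scalar(point, "RATE", 0.0))
    if rate <= 0:
        raise C3DError("POINT:RATE missing or non-positive")
    scale = float(_scalar(point, "SCALE", -1.0))
    data_start_block = int(_scalar(point, "DATA_START", header[7]))
    units = point.get("UNITS", "mm")
    if isinstance(units, np.ndarray):
        units = "".join(map(str, units.ravel()))
    units = str(units).strip()
    labels = point.get("LABELS")
    if labels is None:
        labels = [f"M{i + 1:03d}" for i in range(n_used)]
    else:
        labels = [str(x).strip() for x in np.atleast_1d(labels)][:n_used]

    offset = (data_start_block - 1) * _BLOCK
    itemsize, dtype_str = (4, "<f4") if scale < 0 else (2, "<i2")
    need = n_frames * n_used * 4 * itemsize
    if len(data) < offset + need:
        raise C3DError("truncated point data section")
    raw = np.frombuffer(data, dtype=dtype_str, count=n_frames * n_used * 4, offset=offset)
    raw = raw.reshape(n_frames, n_used, 4).astype(float)
    points = raw[:, :, :3]
    residuals = raw[:, :, 3]
    if scale >= 0:
        points = points * scale
    return RawC3D(labels, points, residuals, rate, units)


def _scalar(group: dict, name: str, default):
    val = group.get(name, default)
    arr = np.atleast_1d(np.asarray(val))
    return arr.ravel()[0]


def _read_params(data: bytes, param_block: int) -> dict:
    base = (param_block - 1) * _BLOCK
    proc = data[base + 3]
    if proc not in (0, _INTEL):
        raise C3DError(f"unsupported processor type {proc} (only Intel handled)")
    groups_by_id: dict[int, str] = {}
    entries = []  # (is_group, group_id, name, payload-parser info)
    pos = base + 4
    while pos < len(data):
        n_char = struct.unpack_from("<b", data, pos)[0]
        if n_char == 0:
            break
        group_id = struct.unpack_from("<b", data, pos + 1)[0]
        name = data[pos + 2 : pos + 2 + abs(n_char)].decode("ascii", "replace")
        off_pos = pos + 2 + abs(n_char)
        offset = struct.unpack_from("<h", data, off_pos)[0]
        if group_id < 0:  # group definition
            groups_by_id[-group_id] = name.upper()
        else:
            p = off_pos + 2
            dtype = struct.unpack_from("<b", data, p)[0]
            ndims = data[p + 1]
            dims = list(data[p + 2 : p + 2 + ndims])
            entries.append((group_id, name.upper(), dtype, dims, p + 2 + ndims))
        if offset <= 0:
            break
        pos = off_pos + offset
    params: dict[str, dict] = {}
    for group_id, name, dtype, dims, dpos in entries:
        gname = groups_by_id.get(group_id, f"GROUP{group_id}")
        params.setdefault(gname, {})[name] = _decode_value(data, dtype, dims, dpos)
    return params


def _decode_value(data: bytes, dtype: int, dims: list[int], pos: int):
    count = int(np.prod(dims)) if dims else 1
    if dtype == -1:  # characters
        if len(dims) <= 1:
            n = dims[0] if dims else 0
            return data[pos : pos + n].decode("ascii", "replace")
        width, n_items = dims[0], int(np.prod(dims[1:]))
        out = []
        for i in range(n_items):
            out.append(
                data[pos + i * width : pos + (i + 1) * width].decode("ascii", "replace").strip()
            )
        return out
    if dtype == 1:
        return np.frombuffer(data, dtype="<i1", count=count, offset=pos).reshape(dims or (1,))
    if dtype == 2:
        return np.frombuffer(data, dtype="<i2", count=count, offset=pos).reshape(dims or (1,))
    if dtype == 4:
        return np.frombuffer(data, dtype="<f4", count=count, offset=pos).reshape(dims or (1,))
    raise C3DError(f"unknown parameter data type {dtype}")


# ---------------------------------------------------------------------------
# Writer (float storage)
# ---------------------------------------------------------------------------


def _param_bytes(name: str, group_id: int, dtype: int, dims: list[int], payload: bytes) -> bytes:
    head = struct.pack("<bb", len(name), group_id) + name.encode("ascii")
    body = struct.pack("<bb", dtype, len(dims)) + bytes(dims) + payload + b"\x00"
    offset = 2 + len(body)
    return head + struct.pack("<h", offset) + body


def _group_bytes(name: str, group_id: int) -> bytes:
    head = struct.pack("<bb", len(name), -group_id) + name.encode("ascii")
    body = b"\x00"
    return head + struct.pack("<h", 2 + len(body)) + body


def write(path, labels: list[str], points: np.ndarray, residuals: np.ndarray,
          rate: float, units: str = "mm") -> None:
    points = np.asarray(points, dtype=np.float32)
    residuals = np.asarray(residuals, dtype=np.float32)
    n_frames, n_points = points.shape[:2]
    label_width = max([4] + [len(x) for x in labels])
    label_payload = b"".join(x.ljust(label_width).encode("ascii") for x in labels)

    gid = 1
    body = _group_bytes("POINT", gid)
    body += _param_bytes("USED", gid, 2, [], struct.pack("<h", n_points))
    body += _param_bytes("FRAMES", gid, 2, [], struct.pack("<h", n_frames))
    body += _param_bytes("RATE", gid, 4, [], struct.pack("<f", rate))
    body += _param_bytes("SCALE", gid, 4, [], struct.pack("<f", -1.0))
    body += _param_bytes("UNITS", gid, -1, [len(units)], units.encode("ascii"))
    body += _param_bytes("LABELS", gid, -1, [label_width, n_points], label_payload)
    ds_placeholder = _param_bytes("DATA_START", gid, 2, [], struct.pack("<h", 0))

    n_param_bytes = 4 + len(body) + len(ds_placeholder) + 1
    n_param_blocks = -(-n_param_bytes // _BLOCK)
    data_start_block = 2 + n_param_blocks
    body += _param_bytes("DATA_START", gid, 2, [], struct.pack("<h", data_start_block))

    param_section = struct.pack("<BBBB", 1, 0x50, n_param_blocks, _INTEL) + body + b"\x00"
    param_section = param_section.ljust(n_param_blocks * _BLOCK, b"\x00")

    header = bytearray(_BLOCK)
    header[0] = 2  # first parameter block
    header[1] = 0x50
    struct.pack_into("<13H", header, 2,
                     n_points, 0, 1, n_frames, 0,
                     0, 0,  # placeholder for scale float
                     data_start_block, 0,
                     0, 0,  # placeholder for rate float
                     0, 0)
    struct.pack_into("<f", header, 12, -1.0)  # 3D scale factor (words 7-8)
    struct.pack_into("<f", header, 20, rate)  # frame rate (words 11-12)

    frames = np.concatenate([points, residuals[..., None]], axis=2).astype("<f4")
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(param_section)
        fh.write(frames.tobytes())
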