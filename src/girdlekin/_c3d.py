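"""Minimal C3D (binary motion-capture standard) reader/writer.

Supports the subset of the standard this pipeline produces and consumes:
Intel (little-endian) processor type, 3D point data stored as float32 with
per-sample residuals (negative residual = invalid/occluded), no analog
channels.  Integer-scaled point data is also read.  Parameter parsing is
generic, so files from other software load as long as they are Intel-typed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

_BLOCK = 512
_PROC_INTEL = 84


class C3DError(ValueError):
    """Malformed or unsupported C3D content."""


@dataclass
class C3DContent:
    labels: list[str]
    rate: float
    points: np.ndarray  # (n_frames, n_points, 3)
    valid: np.ndarray  # (n_frames, n_points) bool
    units: str = "mm"


# --------------------------------------------------------------- reading


def _read_params(raw: bytes, start: int) -> dict[str, dict[str, object]]:
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    if len(raw) < start + 4:
        raise C3DError("truncated parameter section")
    proc = raw[start + 3]
    if proc != _PROC_INTEL:
        raise C3DError(f"unsupported processor type {proc} (only Intel/84)")
    groups: dict[int, str] = {}
    params: dict[int, list[tuple[str, object]]] = {}
    pos = start + 4
    while pos < len(raw):
        nlen = struct.unpack_from("<b", raw, pos)[0]
        gid = struct.unpack_from("<b", raw, pos + 1)[0]
        if nlen == 0 or gid == 0:
            break
        name = raw[pos + 2 : pos + 2 + abs(nlen)].decode("ascii", "replace")
        p = pos + 2 + abs(nlen)
        offset = struct.unpack_from("<h", raw, p)[0]
        next_pos = p + offset if offset > 0 else len(raw)
        if gid < 0:  # group record
            groups[-gid] = name
        else:
            etype = struct.unpack_from("<b", raw, p + 2)[0]
            ndims = raw[p + 3]
            dims = list(raw[p + 4 : p + 4 + ndims])
            dpos = p + 4 + ndims
            count = int(np.prod(dims)) if dims else 1
            if etype == -1:  # characters
                data = raw[dpos : dpos + count]
                if len(dims) >= 2:
                    w = dims[0]
                    value = [
                        data[i * w : (i + 1) * w].decode("ascii", "replace").strip()
                        for i in range(count // w)
                    ]
                else:
                    value = data.decode("ascii", "replace").strip()
            elif etype == 1:
                value = np.frombuffer(raw, np.int8, count, dpos).reshape(dims[::-1] or (1,))
            elif etype == 2:
                value = np.frombuffer(raw, "<i2", count, dpos).reshape(dims[::-1] or (1,))
            elif etype == 4:
                value = np.frombuffer(raw, "<f4", count, dpos).reshape(dims[::-1] or (1,))
            else:
                raise C3DError(f"unknown parameter element type {etype}")
            params.setdefault(gid, []).append((name, value))
        if offset <= 0:
            break
        pos = next_pos
    out: dict[str, dict[str, object]] = {}
    for gid, gname in groups.items():
        out[gname] = dict(params.get(gid, []))
    return out


def _scalar(v) -> float:
    return float(np.asarray(v).ravel()[0])


def read(path) -> C3DContent:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _BLOCK:
        raise C3DError("file shorter than one C3D block")
    param_block = raw[0]
    if raw[1] != 0x50:
        raise C3DError("missing C3D magic byte")
    n_points = struct.unpack_from("<H", raw, 2)[0]
    first_frame = struct.unpack_from("<H", raw, 6)[0]
    last_frame = struct.unpack_from("<H", raw, 8)[0]
    hdr_scale = struct.unpack_from("<f", raw, 12)[0]
    hdr_data_block = struct.unpack_from("<H", raw, 16)[0]
    hdr_rate = struct.unpack_from("<f", raw, 20)[0]

    groups = _read_params(raw, (param_block - 1) * _BLOCK)
    point = groups.get("POINT", {})
    if "USED" in point:
        n_points = int(_scalar(point["USED"]))
    if n_points == 0:
        raise C3DError("file declares zero markers")
    n_frames = last_frame - first_frame + 1
    if "FRAMES" in point:
        pf = int(_scalar(point["FRAMES"]))
        if pf > 0:
            n_frames = pf
    scale = _scalar(point["SCALE"]) if "SCALE" in point else hdr_scale
    rate = _scalar(point["RATE"]) if "RATE" in point else hdr_rate
    if rate <= 0:
        raise C3DError(f"non-positive sample rate {rate}")
    data_block = int(_scalar(point["DATA_START"])) if "DATA_START" in point else hdr_data_block
    labels = point.get("LABELS") or [f"M{i + 1}" for i in range(n_points)]
    labels = list(labels)[:n_points]
    if len(labels) < n_points:
        labels += [f"M{i + 1}" for i in range(len(labels), n_points)]
    units = point.get("UNITS", "mm")
    if isinstance(units, list):
        units = units[0] if units else "mm"

    offset = (data_block - 1) * _BLOCK
    count = n_frames * n_points * 4
    if scale < 0:
        data = np.frombuffer(raw, "<f4", count, offset).reshape(n_frames, n_points, 4)
        xyz = data[:, :, :3].astype(float)
        resid = data[:, :, 3].astype(float)
    else:
        data = np.frombuffer(raw, "<i2", count, offset).reshape(n_frames, n_points, 4)
        xyz = data[:, :, :3].astype(float) * scale
        resid = data[:, :, 3].astype(float)
    valid = resid >= 0
    xyz = xyz.copy()
    xyz[~valid] = np.nan
    return C3DContent(labels=labels, rate=float(rate), points=xyz, valid=valid, units=str(units))


# --------------------------------------------------------------- writing


def _param_record(name: str, gid: int, etype: int, dims: list[int], payload: bytes) -> bytes:
    head = struct.pack("<bb", len(name), gid) + name.encode("ascii")
    body = struct.pack("<bb", etype, len(dims)) + bytes(dims) + payload + b"\x00"
    offset = 2 + len(body)
    return head + struct.pack("<h", offset) + body


def _group_record(name: str, gid: int) -> bytes:
    head = struct.pack("<bb", len(name), -gid) + name.encode("ascii")
    body = b"\x00"
    offset = 2 + len(body)
    return head + struct.pack("<h", offset) + body


def write(path, content: C3DContent) -> None:
    points = np.asarray(content.points, dtype=float)
    n_frames, n_points, _ = points.shape
    if n_frames > 65535:
        raise C3DError("writer supports at most 65535 frames")
    labels = list(content.labels)
    if len(labels) != n_points:
        raise C3DError("label count does not match point count")
    valid = np.asarray(content.valid, dtype=bool)

    lab_w = max(4, max((len(l) for l in labels), default=4))
    lab_payload = b"".join(l.encode("ascii").ljust(lab_w) for l in labels)
    units = content.units.encode("ascii")

    records = [
        _group_record("POINT", 1),
        _param_record("USED", 1, 2, [], struct.pack("<h", n_points)),
        _param_record("FRAMES", 1, 2, [], struct.pack("<h", n_frames)),
        _param_record("SCALE", 1, 4, [], struct.pack("<f", -1.0)),
        _param_record("RATE", 1, 4, [], struct.pack("<f", content.rate)),
        _param_record("LABELS", 1, -1, [lab_w, n_points], lab_payload),
        _param_record("UNITS", 1, -1, [len(units)], units),
    ]
    # DATA_START is patched in after the parameter section size is known
    param_body = b"".join(records) + struct.pack("<bb", 0, 0)
    n_param_blocks = -(-(
        4 + len(param_body) + len(_param_record("DATA_START", 1, 2, [], b"\x00\x00"))
    ) // _BLOCK)
    data_block = 2 + n_param_blocks
    records.append(_param_record("DATA_START", 1, 2, [], struct.pack("<h", data_block)))
    param_body = b"".join(records) + struct.pack("<bb", 0, 0)
    param_section = struct.pack("<bbBB", 1, 0x50, n_param_blocks, _PROC_INTEL) + param_body
    param_section = param_section.ljust(n_param_blocks * _BLOCK, b"\x00")

    header = bytearray(_BLOCK)
    struct.pack_into("<BB", header, 0, 2, 0x50)
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, 0)  # analog per frame
    struct.pack_into("<H", header, 6, 1)  # first frame
    struct.pack_into("<H", header, 8, n_frames)
    struct.pack_into("<f", header, 12, -1.0)
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 0)  # analog samples per frame
    struct.pack_into("<f", header, 20, content.rate)

    data = np.zeros((n_frames, n_points, 4), dtype="<f4")
    safe = np.where(np.isfinite(points), points, 0.0)
    data[:, :, :3] = safe
    data[:, :, 3] = np.where(valid, 0.0, -1.0)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(param_section)
        fh.write(data.tobytes())
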