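"""Minimal C3D motion-capture file support.

Covers the common Intel (little-endian) dialect used by optical capture
pipelines: 3D POINT data in floating-point or scaled-integer storage, marker
labels, rate and units metadata.  Analog channels are ignored on read and not
written.  Coordinates are normalised to millimetres; samples whose residual
word is negative are flagged missing.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError, UnitError
from .trial import MarkerTrial

__all__ = ["read_c3d", "write_c3d"]

_BLOCK = 512
_PROC_INTEL = 84


def _pad_block(b: bytearray) -> bytes:
    if len(b) % _BLOCK:
        b += b"\x00" * (_BLOCK - len(b) % _BLOCK)
    return bytes(b)


def _param_record(group_id: int, name: str, ptype: int, dims: list, data: bytes) -> bytes:
    rec = bytearray()
    rec += struct.pack("bb", len(name), group_id)
    rec += name.encode("ascii")
    body = struct.pack("b", ptype) + struct.pack("B", len(dims))
    body += bytes(dims) + data + b"\x00"  # zero-length description
    rec += struct.pack("<h", 2 + len(body))
    rec += body
    return bytes(rec)


def _group_record(group_id: int, name: str) -> bytes:
    rec = bytearray()
    rec += struct.pack("bb", len(name), -group_id)
    rec += name.encode("ascii")
    rec += struct.pack("<h", 3)  # offset word + desc_len byte + empty desc
    rec += b"\x00"
    return bytes(rec)


def write_c3d(trial: MarkerTrial, path) -> None:
    """Write a trial as a floating-point Intel C3D file (units mm)."""
    n_frames, n_markers = trial.n_frames, trial.n_markers
    labels = [m[:30] for m in trial.marker_names]
    width = max(4, max((len(s) for s in labels), default=4))
    label_data = b"".join(s.ljust(width).encode("ascii") for s in labels)

    pid = 1  # single group: POINT

    def _build_params(data_start_block: int) -> bytearray:
        p = bytearray()
        p += struct.pack("BBBB", 2, 0x50, 0, _PROC_INTEL)  # block count set below
        p += _group_record(pid, "POINT")
        p += _param_record(pid, "USED", 2, [], struct.pack("<h", n_markers))
        p += _param_record(pid, "FRAMES", 2, [], struct.pack("<h", n_frames))
        p += _param_record(pid, "DATA_START", 2, [], struct.pack("<h", data_start_block))
        p += _param_record(pid, "SCALE", 4, [], struct.pack("<f", -1.0))
        p += _param_record(pid, "RATE", 4, [], struct.pack("<f", trial.rate))
        p += _param_record(pid, "UNITS", -1, [2], b"mm")
        p += _param_record(pid, "LABELS", -1, [width, n_markers], label_data)
        p += struct.pack("bbh", 0, 0, 0)  # terminator
        p[2] = (len(p) + _BLOCK - 1) // _BLOCK
        return p

    # two passes: DATA_START depends on the (fixed) parameter-section length
    n_param_blocks = _build_params(0)[2]
    data_start_block = 2 + n_param_blocks
    params_full = _build_params(data_start_block)

    header = bytearray(_BLOCK)
    struct.pack_into("BB", header, 0, 2, 0x50)
    struct.pack_into("<h", header, 2, n_markers)
    struct.pack_into("<h", header, 4, 0)  # analog per frame
    struct.pack_into("<h", header, 6, 1)  # first frame
    struct.pack_into("<h", header, 8, n_frames)
    struct.pack_into("<h", header, 10, 0)  # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)  # negative scale -> float data
    struct.pack_into("<h", header, 16, data_start_block)
    struct.pack_into("<h", header, 18, 0)
    struct.pack_into("<f", header, 20, trial.rate)

    frames = np.zeros((n_frames, n_markers, 4), dtype="<f4")
    data = np.nan_to_num(trial.data, nan=0.0)
    frames[:, :, :3] = data
    frames[:, :, 3] = np.where(trial.missing, -1.0, 0.0)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(_pad_block(bytearray(params_full)))
        fh.write(_pad_block(bytearray(frames.tobytes())))


def _read_params(buf: bytes, start: int):
    """Walk the parameter section; return {group: {param: value}}."""
    if len(buf) < start + 4:
        raise FormatError("truncated C3D parameter section")
    proc = buf[start + 3]
    if proc != _PROC_INTEL:
        raise FormatError(f"unsupported C3D processor type {proc} (only Intel/{_PROC_INTEL})")
    pos = start + 4
    groups_by_id: dict = {}
    params_by_gid: dict = {}
    while pos + 2 <= len(buf):
        nchar, gid = struct.unpack_from("bb", buf, pos)
        if nchar == 0 or gid == 0:
            break
        name = buf[pos + 2: pos + 2 + abs(nchar)].decode("ascii", "replace").strip().upper()
        off_pos = pos + 2 + abs(nchar)
        (offset,) = struct.unpack_from("<h", buf, off_pos)
        if gid < 0:
            groups_by_id[-gid] = name
        else:
            ptype = struct.unpack_from("b", buf, off_pos + 2)[0]
            ndims = buf[off_pos + 3]
            dims = list(buf[off_pos + 4: off_pos + 4 + ndims])
            count = int(np.prod(dims)) if dims else 1
            dpos = off_pos + 4 + ndims
            if ptype == -1:
                raw = buf[dpos: dpos + count]
                if len(dims) <= 1:
                    value = raw.decode("ascii", "replace")
                else:
                    w = dims[0]
                    value = [raw[i * w:(i + 1) * w].decode("ascii", "replace") for i in range(dims[1])]
            elif ptype in (1, 2, 4):
                fmt = {1: "b", 2: "<h", 4: "<f"}[ptype]
                size = {1: 1, 2: 2, 4: 4}[ptype]
                value = [struct.unpack_from(fmt, buf, dpos + i * size)[0] for i in range(count)]
                if not dims:
                    value = value[0]
            else:
                value = None
            params_by_gid.setdefault(gid, {})[name] = value
        if offset <= 0:
            break
        pos = off_pos + offset
    out: dict = {}
    for gid, pdict in params_by_gid.items():
        out[groups_by_id.get(gid, f"G{gid}")] = pdict
    return out


def read_c3d(path) -> MarkerTrial:
    """Read POINT data from a C3D file into a :class:`MarkerTrial` (mm)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 2 * _BLOCK or buf[1] != 0x50:
        raise FormatError(f"{path}: not a C3D file")
    param_block = buf[0]
    n_markers_hdr, = struct.unpack_from("<h", buf, 2)
    first_frame, = struct.unpack_from("<h", buf, 6)
    last_frame, = struct.unpack_from("<h", buf, 8)
    scale_hdr, = struct.unpack_from("<f", buf, 12)
    data_block_hdr, = struct.unpack_from("<h", buf, 16)
    rate_hdr, = struct.unpack_from("<f", buf, 20)

    groups = _read_params(buf, (param_block - 1) * _BLOCK)
    point = groups.get("POINT", {})

    def _scalar(name, default):
        v = point.get(name, default)
        return v[0] if isinstance(v, list) and v else v

    n_markers = int(_scalar("USED", n_markers_hdr))
    n_frames = int(_scalar("FRAMES", last_frame - first_frame + 1))
    scale = float(_scalar("SCALE", scale_hdr))
    rate = float(_scalar("RATE", rate_hdr))
    data_block = int(_scalar("DATA_START", data_block_hdr))
    units = _scalar("UNITS", "mm")
    if isinstance(units, list):
        units = units[0]
    units = str(units).strip().lower()
    if units in ("mm", ""):
        unit_scale = 1.0
    elif units == "m":
        unit_scale = 1000.0
    elif units == "cm":
        unit_scale = 10.0
    else:
        raise UnitError(f"unsupported POINT:UNITS {units!r}")

    labels = point.get("LABELS", None)
    if isinstance(labels, list):
        names = [s.strip() or f"M{i+1}" for i, s in enumerate(labels[:n_markers])]
    else:
        names = []
    while len(names) < n_markers:
        names.append(f"M{len(names)+1}")

    start = (data_block - 1) * _BLOCK
    if scale < 0:  # floating-point storage
        need = n_frames * n_markers * 4 * 4
        if len(buf) < start + need:
            raise FormatError("truncated C3D data section")
        raw = np.frombuffer(buf, dtype="<f4", count=n_frames * n_markers * 4, offset=start)
        raw = raw.reshape(n_frames, n_markers, 4).astype(float)
        coords = raw[:, :, :3]
        residual = raw[:, :, 3]
    else:  # scaled 16-bit integer storage
        need = n_frames * n_markers * 4 * 2
        if len(buf) < start + need:
            raise FormatError("truncated C3D data section")
        raw = np.frombuffer(buf, dtype="<i2", count=n_frames * n_markers * 4, offset=start)
        raw = raw.reshape(n_frames, n_markers, 4).astype(float)
        coords = raw[:, :, :3] * scale
        residual = raw[:, :, 3]
    missing = residual < 0
    coords = coords * unit_scale
    coords = coords.copy()
    coords[missing] = np.nan
    return MarkerTrial(marker_names=names, data=coords, rate=rate, missing=missing)
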