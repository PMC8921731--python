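"""TRC marker-trajectory text format (read/write).

The tab-separated TRC layout used by marker-based IK tools: a four-line
header (file type, column metadata, values, marker names + XYZ sub-headers)
followed by one row per frame.  Missing samples are blank fields.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError
from .trial import MarkerTrial

__all__ = ["read_trc", "write_trc"]


def write_trc(trial: MarkerTrial, path) -> None:
    names = trial.marker_names
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{trial.rate:g}\t{trial.rate:g}\t{trial.n_frames}\t{len(names)}\tmm\t"
                 f"{trial.rate:g}\t1\t{trial.n_frames}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\n")
        subs = "".join(f"\tX{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names)))
        fh.write("\t" + subs + "\n")
        time = trial.time
        for f in range(trial.n_frames):
            cells = [str(f + 1), f"{time[f]:.6f}"]
            for m in range(trial.n_markers):
                if trial.missing[f, m]:
                    cells += ["", "", ""]
                else:
                    cells += [f"{v:.8f}" for v in trial.data[f, m]]
            fh.write("\t".join(cells) + "\n")


def read_trc(path) -> MarkerTrial:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{path}: not a TRC file")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    try:
        rate = float(meta["DataRate"])
        n_frames = int(meta["NumFrames"])
        n_markers = int(meta["NumMarkers"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed TRC header ({exc})") from exc
    units = meta.get("Units", "mm").strip().lower()
    unit_scale = {"mm": 1.0, "m": 1000.0, "cm": 10.0}.get(units)
    if unit_scale is None:
        raise FormatError(f"{path}: unsupported units {units!r}")
    names = [c for c in lines[3].split("\t")[2:] if c.strip()]
    if len(names) != n_markers:
        raise FormatError(f"{path}: header declares {n_markers} markers, found {len(names)} names")
    data = np.full((n_frames, n_markers, 3), np.nan)
    t0 = 0.0
    rows = [ln for ln in lines[5:] if ln.strip()]
    if len(rows) < n_frames:
        raise FormatError(f"{path}: expected {n_frames} data rows, found {len(rows)}")
    for f in range(n_frames):
        cells = rows[f].split("\t")
        if f == 0 and len(cells) > 1 and cells[1]:
            t0 = float(cells[1])
        for m in range(n_markers):
            trio = cells[2 + 3 * m: 5 + 3 * m]
            if len(trio) == 3 and all(c.strip() for c in trio):
                data[f, m] = [float(c) for c in trio]
    return MarkerTrial(marker_names=names, data=data * unit_scale, rate=rate, t0=t0)
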