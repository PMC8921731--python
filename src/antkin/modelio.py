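"""Model definition I/O: a versioned YAML schema for kinematic models.

Schema (version 1)::

    antkin_model: 1
    segments:
      - name: thorax
        parent: ground
        joint:
          name: base
          type: free6            # free6 | ball3 | hinge1 | locked0
          frame_in_parent: {origin: [x, y, z], rotation: [[...], ...]}
          frame_in_child:  {origin: [0, 0, 0], rotation: identity}   # optional
          rom_deg: {flexion: [-80, 80], ...}                         # optional
          geometry: {kind: ball, center: [...], ...}                 # optional
        markers: {th_a: [x, y, z], ...}

Origins and marker positions are millimetres; ROM limits degrees.
"""

from __future__ import annotations

import numpy as np
import yaml

from .errors import FormatError
from .geometry import FrameDef
from .model import JointSpec, KinematicModel, SegmentSpec, assemble_model

__all__ = ["load_model", "save_model", "model_to_dict", "model_from_dict"]

SCHEMA_KEY = "antkin_model"
SCHEMA_VERSION = 1


def _frame_to_dict(f: FrameDef) -> dict:
    return {"origin": [float(v) for v in f.origin],
            "rotation": [[float(v) for v in row] for row in f.rotation]}


def _frame_from_dict(d) -> FrameDef:
    if d is None or d == "identity":
        return FrameDef()
    rot = d.get("rotation", "identity")
    return FrameDef(origin=np.asarray(d.get("origin", [0.0, 0.0, 0.0]), dtype=float),
                    rotation=np.eye(3) if rot == "identity" else np.asarray(rot, dtype=float))


def _geometry_to_dict(g) -> dict:
    out = {}
    for k, v in g.items():
        out[k] = [float(x) for x in np.atleast_1d(v)] if isinstance(
            v, (np.ndarray, list, tuple)) else v
    return out


def model_to_dict(model: KinematicModel) -> dict:
    segs = []
    for s in model.segments:
        j = {"name": s.joint.name, "type": s.joint.joint_type,
             "frame_in_parent": _frame_to_dict(s.joint.frame_in_parent),
             "frame_in_child": _frame_to_dict(s.joint.frame_in_child)}
        if s.joint.rom_limits:
            j["rom_deg"] = {k: [float(v[0]), float(v[1])] for k, v in s.joint.rom_limits.items()}
        if s.joint.geometry:
            j["geometry"] = _geometry_to_dict(s.joint.geometry)
        segs.append({"name": s.name, "parent": s.parent, "joint": j,
                     "markers": {k: [float(x) for x in v] for k, v in s.markers.items()}})
    return {SCHEMA_KEY: SCHEMA_VERSION, "segments": segs}


def model_from_dict(doc: dict) -> KinematicModel:
    if not isinstance(doc, dict) or doc.get(SCHEMA_KEY) != SCHEMA_VERSION:
        raise FormatError(f"not a version-{SCHEMA_VERSION} model document "
                          f"(missing '{SCHEMA_KEY}: {SCHEMA_VERSION}')")
    segments = []
    for sd in doc["segments"]:
        jd = sd["joint"]
        geometry = jd.get("geometry")
        if geometry is not None:
            geometry = {k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
                        for k, v in geometry.items()}
        joint = JointSpec(
            name=jd["name"], joint_type=jd["type"],
            frame_in_parent=_frame_from_dict(jd.get("frame_in_parent")),
            frame_in_child=_frame_from_dict(jd.get("frame_in_child")),
            rom_limits={k: tuple(v) for k, v in jd.get("rom_deg", {}).items()},
            geometry=geometry)
        segments.append(SegmentSpec(name=sd["name"], parent=sd["parent"], joint=joint,
                                    markers=sd.get("markers", {})))
    return assemble_model(segments)


def save_model(model: KinematicModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> KinematicModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)
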