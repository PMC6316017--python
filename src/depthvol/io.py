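"""Depth image and point cloud I/O.

Depth maps are stored as 16-bit grayscale PNG with pixel value = depth in
millimetres (0 = invalid), alongside a JSON sidecar holding the intrinsics
and pose.  Point clouds round-trip through PLY via trimesh.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import trimesh

from .geometry import DepthImage, Intrinsics, PointCloud, RigidPose

MM_PER_M = 1000.0


def write_depth_png(path: str | Path, depth: DepthImage) -> None:
    """Write a depth image as 16-bit PNG (millimetre quantization)."""
    mm = np.round(depth.values * MM_PER_M)
    if np.any(mm > np.iinfo(np.uint16).max):
        raise ValueError("depth exceeds the 65.535 m range of 16-bit mm PNG")
    iio.imwrite(Path(path), mm.astype(np.uint16))


def read_depth_png(path: str | Path) -> DepthImage:
    mm = np.asarray(iio.imread(Path(path)))
    if mm.ndim != 2:
        raise ValueError("expected a single-channel depth PNG")
    return DepthImage(mm.astype(np.float64) / MM_PER_M)


def write_camera_json(
    path: str | Path, k: Intrinsics, pose: RigidPose, extra: dict | None = None
) -> None:
    payload = {
        "fx": k.fx,
        "fy": k.fy,
        "cx": k.cx,
        "cy": k.cy,
        "width": k.width,
        "height": k.height,
        "R": [float(x) for x in pose.R.ravel()],
        "T": [float(x) for x in pose.T],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_camera_json(path: str | Path) -> tuple[Intrinsics, RigidPose, dict]:
    payload = json.loads(Path(path).read_text())
    k = Intrinsics(
        fx=payload["fx"],
        fy=payload["fy"],
        cx=payload["cx"],
        cy=payload["cy"],
        width=payload["width"],
        height=payload["height"],
    )
    pose = RigidPose(np.array(payload["R"]).reshape(3, 3), np.array(payload["T"]))
    rest = {k_: v for k_, v in payload.items() if k_ not in
            {"fx", "fy", "cx", "cy", "width", "height", "R", "T"}}
    return k, pose, rest


def write_ply(path: str | Path, cloud: PointCloud) -> None:
    trimesh.PointCloud(cloud.points).export(str(path))


def read_ply(path: str | Path, frame: str = "world") -> PointCloud:
    loaded = trimesh.load(str(path))
    return PointCloud(np.asarray(loaded.vertices), frame)
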