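"""Pinhole camera geometry for two-view depth fusion.

The world frame is the frame of the *initial* camera: right-handed, camera
looking along +Z, image u/x to the right, v/y down.  A second camera that
observes the object from the exactly opposite direction is modelled as a
180-degree rotation about the initial camera's vertical (y) axis plus a
translation ``T``; for an object centred at distance ``d`` on the optical
axis the true translation is approximately ``(0, 0, 2d)``.

Poses follow the computer-vision convention ``p_cam = R @ p_world + T``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "Intrinsics",
    "DepthImage",
    "RigidPose",
    "PointCloud",
    "rotation_about_y",
    "back_project",
    "project",
    "register_to_world",
]

#: Frame labels used by :class:`PointCloud`.
FRAME_INITIAL = "initial-camera"
FRAME_OPPOSITE = "opposite-camera"
FRAME_WORLD = "world"


@dataclasses.dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsic parameters (pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 intrinsic matrix K."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def scaled(self, factor: float) -> "Intrinsics":
        """Intrinsics for an image resized by ``factor`` (same field of view)."""
        return Intrinsics(
            fx=self.fx * factor,
            fy=self.fy * factor,
            cx=(self.cx + 0.5) * factor - 0.5,
            cy=(self.cy + 0.5) * factor - 0.5,
            width=int(round(self.width * factor)),
            height=int(round(self.height * factor)),
        )


#: Default camera: a typical structured-light depth camera at VGA resolution.
DEFAULT_INTRINSICS = Intrinsics(fx=570.0, fy=570.0, cx=319.5, cy=239.5, width=640, height=480)


@dataclasses.dataclass
class DepthImage:
    """A metric depth map: ``values[v, u]`` in metres, 0 marks invalid pixels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("depth image must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("depth values must be finite")
        if np.any(self.values < 0):
            raise ValueError("depth values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values > 0

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.values))

    def matches(self, k: Intrinsics) -> bool:
        return self.values.shape == (k.height, k.width)


@dataclasses.dataclass(frozen=True)
class RigidPose:
    """Rigid camera pose: ``p_cam = R @ p_world + T``."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", np.asarray(self.R, dtype=np.float64).reshape(3, 3))
        object.__setattr__(self, "T", np.asarray(self.T, dtype=np.float64).reshape(3))
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-9):
            raise ValueError("R must be orthonormal")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-9):
            raise ValueError("R must be a proper rotation (det = +1)")

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        return points @ self.R.T + self.T

    def camera_to_world(self, points: np.ndarray) -> np.ndarray:
        return (points - self.T) @ self.R

    def compose_relative(self, other: "RigidPose") -> "RigidPose":
        """Pose of ``other`` expressed relative to this camera's frame.

        Returns (R_rel, T_rel) with ``p_other = R_rel @ p_self + T_rel``.
        """
        r_rel = other.R @ self.R.T
        t_rel = other.T - r_rel @ self.T
        return RigidPose(r_rel, t_rel)


@dataclasses.dataclass
class PointCloud:
    """Unordered 3-D points (metres) tagged with the frame they live in."""

    points: np.ndarray
    frame: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if not self.frame:
            raise ValueError("frame label must be set")

    def __len__(self) -> int:
        return len(self.points)

    def translated(self, t: np.ndarray) -> "PointCloud":
        return PointCloud(self.points + np.asarray(t, dtype=np.float64), self.frame)


def rotation_about_y(theta_degrees: float) -> np.ndarray:
    """Rotation matrix about the y axis.

    Sign convention: ``Ry(t) = [[cos t, 0, sin t], [0, 1, 0], [-sin t, 0, cos t]]``,
    so ``rotation_about_y(180)`` is exactly ``diag(-1, 1, -1)``.
    """
    if not np.isfinite(theta_degrees):
        raise ValueError("theta must be finite")
    t = np.deg2rad(theta_degrees)
    c, s = np.cos(t), np.sin(t)
    r = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    # exact entries at multiples of 90 degrees
    r[np.abs(r) < 1e-15] = 0.0
    r[np.abs(r - 1) < 1e-15] = 1.0
    r[np.abs(r + 1) < 1e-15] = -1.0
    return r


def back_project(
    depth: DepthImage, k: Intrinsics, mask: np.ndarray | None = None
) -> PointCloud:
    """Lift a depth image into a camera-frame point cloud.

    Each valid pixel (u, v) with depth Z maps to ``Z * K^-1 @ [u, v, 1]``;
    the produced point's Z coordinate equals the pixel's depth exactly.
    """
    if not depth.matches(k):
        raise ValueError(
            f"depth shape {depth.shape} does not match intrinsics "
            f"({k.height}, {k.width})"
        )
    valid = depth.valid_mask
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != depth.shape:
            raise ValueError("mask shape must match the depth image")
        valid = valid & mask
    v, u = np.nonzero(valid)
    z = depth.values[v, u]
    x = z * (u - k.cx) / k.fx
    y = z * (v - k.cy) / k.fy
    return PointCloud(np.column_stack([x, y, z]), FRAME_INITIAL)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Nearest-integer rounding with ties away from zero (np.round ties to even)."""
    return np.trunc(x + np.copysign(0.5, x)).astype(np.int64)


def project(cloud: PointCloud, k: Intrinsics) -> DepthImage:
    """Project a camera-frame cloud into a depth image with a z-buffer.

    Points behind the camera or outside the frame are dropped; when several
    points land on one pixel the nearest (smallest Z) survives.
    """
    pts = cloud.points
    out = np.zeros((k.height, k.width))
    front = pts[:, 2] > 0
    pts = pts[front]
    if len(pts) == 0:
        return DepthImage(out)
    u = _round_half_away(k.fx * pts[:, 0] / pts[:, 2] + k.cx)
    v = _round_half_away(k.fy * pts[:, 1] / pts[:, 2] + k.cy)
    inside = (u >= 0) & (u < k.width) & (v >= 0) & (v < k.height)
    u, v, z = u[inside], v[inside], pts[inside, 2]
    # z-buffer: sort decreasing z so the nearest point writes last
    order = np.argsort(-z)
    out[v[order], u[order]] = z[order]
    return DepthImage(out)


def register_to_world(cloud: PointCloud, pose: RigidPose) -> PointCloud:
    """Map a camera-frame cloud into the world frame: ``p_w = R^-1 (p_c - T)``."""
    return PointCloud(pose.camera_to_world(cloud.points), FRAME_WORLD)
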