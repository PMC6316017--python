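"""Synthetic depth-pair rendering of analytic primitives.

This module generates the study data: watertight primitive meshes with
closed-form volumes, camera pose pairs sampled from the training ranges
(azimuthal rotation, elevation rotation, height adjustment and centre
shifting), and noiseless depth renders of each view via a perspective-correct
z-buffer rasterizer.  The initial and opposite cameras differ by an exact
180-degree rotation about the initial camera's vertical axis plus a
translation, so every rendered pair carries its ground-truth inter-camera
translation.

Scene convention: the object sits at the origin of a right-handed scene frame
with +Y up; a camera at polar angle ``elevation`` and ``azimuth`` about +Y
looks at the origin from distance ``height`` and may then be shifted in its
own image plane (centre shifting).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import trimesh

from .geometry import DepthImage, Intrinsics, PointCloud, RigidPose, rotation_about_y
from . import io as dvio

__all__ = [
    "PrimitiveSpec",
    "ViewConfig",
    "RenderSample",
    "make_primitive",
    "default_catalogue",
    "sample_pose_pair",
    "render_depth",
    "render_sample",
    "build_dataset",
    "holdout_split",
]

CM3_PER_M3 = 1e6


@dataclasses.dataclass(frozen=True)
class PrimitiveSpec:
    """An analytic test object: shape kind plus size parameters in centimetres.

    Supported kinds and parameters:

    - ``cube``: ``edge``
    - ``sphere``: ``radius``
    - ``cylinder``: ``radius``, ``height``
    - ``ellipsoid``: ``a``, ``b``, ``c`` (semi-axes)
    - ``capsule``: ``radius``, ``length`` (cylindrical segment)
    - ``bent_capsule``: ``radius``, ``bend_radius``, ``angle_deg`` — a tube of
      radius ``radius`` swept along a circular arc, capped with hemispheres
      (a banana-like shape; volume by Pappus: pi r^2 * arc length + sphere).
    """

    kind: str
    params: dict

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.params.values()):
            raise ValueError("all size parameters must be positive")
        if self.kind == "bent_capsule" and self.params["bend_radius"] < self.params["radius"]:
            raise ValueError("bend radius must be at least the tube radius")
        self.analytic_volume  # validates the kind

    @property
    def analytic_volume(self) -> float:
        """Closed-form volume in cm^3."""
        p = self.params
        if self.kind == "cube":
            return p["edge"] ** 3
        if self.kind == "sphere":
            return 4.0 / 3.0 * math.pi * p["radius"] ** 3
        if self.kind == "cylinder":
            return math.pi * p["radius"] ** 2 * p["height"]
        if self.kind == "ellipsoid":
            return 4.0 / 3.0 * math.pi * p["a"] * p["b"] * p["c"]
        if self.kind == "capsule":
            return (
                math.pi * p["radius"] ** 2 * p["length"]
                + 4.0 / 3.0 * math.pi * p["radius"] ** 3
            )
        if self.kind == "bent_capsule":
            arc = p["bend_radius"] * math.radians(p["angle_deg"])
            return math.pi * p["radius"] ** 2 * arc + 4.0 / 3.0 * math.pi * p["radius"] ** 3
        raise ValueError(f"unknown primitive kind {self.kind!r}")


def default_catalogue() -> dict[str, PrimitiveSpec]:
    """The four-primitive evaluation suite (sizes on the scale of the
    household objects the method targets, ~100-200 cm^3)."""
    return {
        "cube": PrimitiveSpec("cube", {"edge": 5.7}),
        "sphere": PrimitiveSpec("sphere", {"radius": 3.65}),
        "cylinder": PrimitiveSpec("cylinder", {"radius": 3.0, "height": 5.0}),
        "capsule": PrimitiveSpec("capsule", {"radius": 2.5, "length": 6.0}),
    }


def _bent_capsule_mesh(r: float, rb: float, angle_deg: float, resolution: int) -> trimesh.Trimesh:
    """Bent capsule by marching cubes on the signed distance to a circular arc."""
    from skimage.measure import marching_cubes

    half = math.radians(angle_deg) / 2.0
    pitch = r / (5.0 * resolution)
    pad = r + 3 * pitch
    lo = np.array([-rb - pad, -rb - pad, -r - pad])
    hi = np.array([rb + pad, rb + pad, r + pad])
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1
    ax = [lo[i] + pitch * np.arange(shape[i]) for i in range(3)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    alpha = np.clip(np.arctan2(y, x), -half, half)
    near = np.stack([rb * np.cos(alpha), rb * np.sin(alpha), np.zeros_like(alpha)])
    d = np.sqrt((x - near[0]) ** 2 + (y - near[1]) ** 2 + z**2) - r
    verts, faces, _, _ = marching_cubes(d, level=0.0, spacing=(pitch, pitch, pitch))
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=True)
    mesh.fix_normals()
    return mesh


def make_primitive(spec: PrimitiveSpec, mesh_resolution: int = 2) -> tuple[trimesh.Trimesh, float]:
    """Build a watertight triangle mesh (metres) for ``spec``.

    Returns ``(mesh, analytic_volume_cm3)``.  The mesh volume converges to the
    analytic volume as ``mesh_resolution`` grows (the cube is exact at any
    resolution).
    """
    if mesh_resolution < 1:
        raise ValueError("mesh_resolution must be >= 1")
    p = {k: v * 0.01 for k, v in spec.params.items()}  # cm -> m
    if spec.kind == "cube":
        mesh = trimesh.creation.box(extents=[p["edge"]] * 3)
    elif spec.kind == "sphere":
        mesh = trimesh.creation.icosphere(subdivisions=2 + mesh_resolution, radius=p["radius"])
    elif spec.kind == "ellipsoid":
        mesh = trimesh.creation.icosphere(subdivisions=2 + mesh_resolution, radius=1.0)
        mesh.apply_scale([p["a"], p["b"], p["c"]])
    elif spec.kind == "cylinder":
        mesh = trimesh.creation.cylinder(radius=p["radius"], height=p["height"],
                                         sections=32 * 2**mesh_resolution)
    elif spec.kind == "capsule":
        n = 16 * 2**mesh_resolution
        mesh = trimesh.creation.capsule(radius=p["radius"], height=p["length"], count=[n, n])
        # trimesh builds the capsule along +z starting at the origin; centre it
        mesh.apply_translation([0, 0, -p["length"] / 2.0])
    elif spec.kind == "bent_capsule":
        mesh = _bent_capsule_mesh(p["radius"], p["bend_radius"],
                                  spec.params["angle_deg"], mesh_resolution)
    else:
        raise ValueError(f"unknown primitive kind {spec.kind!r}")
    mesh.apply_translation(-mesh.center_mass)
    return mesh, spec.analytic_volume


# ---------------------------------------------------------------------------
# pose sampling


def _range(lo: float, hi: float) -> tuple[float, float]:
    return (float(lo), float(hi))


@dataclasses.dataclass(frozen=True)
class ViewConfig:
    """Uniform sampling ranges for the camera pose pair.

    Defaults are the training ranges of the rendered dataset: azimuth 0-360
    deg, initial elevation (polar angle) 90-270 deg, initial height (camera
    distance) 0.5-0.6 m, centre shift +/-0.1 m in both image-plane axes; the
    opposite camera is at elevation + 180 deg (270-450 deg) on the far side at
    a signed height of -0.5 to -0.6 m, i.e. the mirrored position at the same
    distance range, with its own centre shift draw.
    """

    azimuth: tuple[float, float] = (0.0, 360.0)
    elevation: tuple[float, float] = (90.0, 270.0)
    height: tuple[float, float] = (0.5, 0.6)
    shift_x: tuple[float, float] = (-0.1, 0.1)
    shift_y: tuple[float, float] = (-0.1, 0.1)
    opposite_height: tuple[float, float] = (-0.6, -0.5)
    opposite_shift_x: tuple[float, float] = (-0.1, 0.1)
    opposite_shift_y: tuple[float, float] = (-0.1, 0.1)

    @property
    def opposite_elevation(self) -> tuple[float, float]:
        return (self.elevation[0] + 180.0, self.elevation[1] + 180.0)

    def centered(self) -> "ViewConfig":
        """Zero-shift variant (object centred in both views)."""
        z = (0.0, 0.0)
        return dataclasses.replace(self, shift_x=z, shift_y=z,
                                   opposite_shift_x=z, opposite_shift_y=z)


def _draw(rng: np.random.Generator, lo_hi: tuple[float, float], name: str) -> float:
    lo, hi = lo_hi
    if lo > hi:
        raise ValueError(f"degenerate range for {name}: min {lo} > max {hi}")
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _look_at_origin(position: np.ndarray) -> np.ndarray:
    """Rotation rows (camera axes in scene coords) for a camera at ``position``
    looking at the origin, image v-axis pointing as far down (-Y) as possible."""
    z_c = -position / np.linalg.norm(position)
    down = np.array([0.0, -1.0, 0.0])
    y_c = down - np.dot(down, z_c) * z_c
    n = np.linalg.norm(y_c)
    if n < 1e-8:  # looking straight up/down the scene vertical
        y_c = np.array([1.0, 0.0, 0.0]) - z_c[0] * z_c
        n = np.linalg.norm(y_c)
    y_c /= n
    x_c = np.cross(y_c, z_c)
    return np.stack([x_c, y_c, z_c])


def sample_pose_pair(
    rng: np.random.Generator, config: ViewConfig | None = None
) -> tuple[RigidPose, RigidPose, np.ndarray, dict]:
    """Draw an initial/opposite camera pose pair.

    Returns ``(initial_pose, opposite_pose, t_gt, params)`` where the poses are
    scene-frame (``p_cam = R @ p_scene + T``), the opposite orientation is
    exactly ``Ry(180) @ R_initial``, and ``t_gt`` is the translation that maps
    initial-camera coordinates to opposite-camera coordinates under that
    180-degree model (``p_opp = Ry(180) @ p_init + t_gt``).
    """
    config = config or ViewConfig()
    az = _draw(rng, config.azimuth, "azimuth")
    el = _draw(rng, config.elevation, "elevation")
    h_i = _draw(rng, config.height, "height")
    sx_i = _draw(rng, config.shift_x, "shift_x")
    sy_i = _draw(rng, config.shift_y, "shift_y")
    h_o = abs(_draw(rng, config.opposite_height, "opposite_height"))
    sx_o = _draw(rng, config.opposite_shift_x, "opposite_shift_x")
    sy_o = _draw(rng, config.opposite_shift_y, "opposite_shift_y")

    a, e = math.radians(az), math.radians(el)
    direction = np.array([math.sin(e) * math.cos(a), math.cos(e), math.sin(e) * math.sin(a)])

    r_init = _look_at_origin(direction * h_i)
    p_init = h_i * direction + sx_i * r_init[0] + sy_i * r_init[1]
    initial = RigidPose(r_init, -r_init @ p_init)

    ry180 = rotation_about_y(180.0)
    r_opp = ry180 @ r_init
    p_opp = -h_o * direction + sx_o * r_opp[0] + sy_o * r_opp[1]
    opposite = RigidPose(r_opp, -r_opp @ p_opp)

    t_gt = opposite.T - ry180 @ initial.T
    params = {
        "azimuth": az, "elevation": el, "height": h_i,
        "shift_x": sx_i, "shift_y": sy_i,
        "opposite_height": h_o, "opposite_shift_x": sx_o, "opposite_shift_y": sy_o,
    }
    return initial, opposite, t_gt, params


# ---------------------------------------------------------------------------
# rasterization


def render_depth(mesh: trimesh.Trimesh, pose: RigidPose, k: Intrinsics) -> DepthImage:
    """Render the first-surface depth of ``mesh`` seen by a camera at ``pose``.

    Perspective-correct z-buffer rasterization: each pixel covered by a
    projected triangle receives the interpolated 1/z depth of the nearest
    surface; pixels with no hit are 0.  Deterministic.
    """
    zbuf = np.full((k.height, k.width), np.inf)
    if mesh is None or len(mesh.faces) == 0:
        return DepthImage(np.zeros((k.height, k.width)))
    tris = pose.world_to_camera(np.asarray(mesh.vertices))[np.asarray(mesh.faces)]
    z = tris[:, :, 2]
    keep = z.min(axis=1) > 1e-6  # drop triangles at/behind the camera
    tris = tris[keep]
    if len(tris) == 0:
        return DepthImage(np.zeros((k.height, k.width)))
    u = k.fx * tris[:, :, 0] / tris[:, :, 2] + k.cx
    v = k.fy * tris[:, :, 1] / tris[:, :, 2] + k.cy
    inv_z = 1.0 / tris[:, :, 2]

    u0 = np.clip(np.floor(u.min(axis=1)), 0, k.width - 1).astype(int)
    u1 = np.clip(np.ceil(u.max(axis=1)), 0, k.width - 1).astype(int)
    v0 = np.clip(np.floor(v.min(axis=1)), 0, k.height - 1).astype(int)
    v1 = np.clip(np.ceil(v.max(axis=1)), 0, k.height - 1).astype(int)
    offscreen = (u.max(axis=1) < 0) | (u.min(axis=1) > k.width - 1) \
        | (v.max(axis=1) < 0) | (v.min(axis=1) > k.height - 1)

    for i in range(len(tris)):
        if offscreen[i]:
            continue
        ua, ub, uc = u[i]
        va, vb, vc = v[i]
        area = (ub - ua) * (vc - va) - (uc - ua) * (vb - va)
        if abs(area) < 1e-12:
            continue
        gu, gv = np.meshgrid(
            np.arange(u0[i], u1[i] + 1), np.arange(v0[i], v1[i] + 1)
        )
        w0 = ((ub - gu) * (vc - gv) - (uc - gu) * (vb - gv)) / area
        w1 = ((uc - gu) * (va - gv) - (ua - gu) * (vc - gv)) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= -1e-12) & (w1 >= -1e-12) & (w2 >= -1e-12)
        if not inside.any():
            continue
        depth = 1.0 / (w0 * inv_z[i, 0] + w1 * inv_z[i, 1] + w2 * inv_z[i, 2])
        patch = zbuf[v0[i]:v1[i] + 1, u0[i]:u1[i] + 1]
        np.minimum(patch, np.where(inside, depth, np.inf), out=patch)

    zbuf[~np.isfinite(zbuf)] = 0.0
    return DepthImage(zbuf)


# ---------------------------------------------------------------------------
# dataset assembly


@dataclasses.dataclass
class RenderSample:
    """One rendered training/evaluation pair with its ground truth."""

    initial: DepthImage
    opposite: DepthImage
    t_gt: np.ndarray
    initial_pose: RigidPose
    opposite_pose: RigidPose
    params: dict
    object_id: str
    seed: int


def render_sample(
    mesh: trimesh.Trimesh,
    seed: int,
    config: ViewConfig | None = None,
    k: Intrinsics | None = None,
    object_id: str = "",
) -> RenderSample:
    """Sample one pose pair and render both depth views (reproducible from seed)."""
    from .geometry import DEFAULT_INTRINSICS

    k = k or DEFAULT_INTRINSICS
    rng = np.random.default_rng(seed)
    initial, opposite, t_gt, params = sample_pose_pair(rng, config)
    return RenderSample(
        initial=render_depth(mesh, initial, k),
        opposite=render_depth(mesh, opposite, k),
        t_gt=t_gt,
        initial_pose=initial,
        opposite_pose=opposite,
        params=params,
        object_id=object_id,
        seed=seed,
    )


def build_dataset(
    meshes: dict[str, trimesh.Trimesh],
    n_pairs_per_object: int,
    seed: int,
    out_dir: str | Path,
    config: ViewConfig | None = None,
    k: Intrinsics | None = None,
) -> list[dict]:
    """Render and write ``n`` pose-pair samples per object.

    Layout: ``<out_dir>/<object>/<trial>_{init,opp}.png`` plus
    ``<trial>.json`` holding the camera and ground-truth translation; the
    returned index (also written as ``index.jsonl``) lists every sample.
    Rebuilding with the same seed is byte-identical.
    """
    from .geometry import DEFAULT_INTRINSICS

    if n_pairs_per_object < 1:
        raise ValueError("n_pairs_per_object must be >= 1")
    k = k or DEFAULT_INTRINSICS
    out_dir = Path(out_dir)
    index: list[dict] = []
    for obj_i, (name, mesh) in enumerate(sorted(meshes.items())):
        obj_dir = out_dir / name
        obj_dir.mkdir(parents=True, exist_ok=True)
        for trial in range(n_pairs_per_object):
            sample_seed = int(
                np.random.SeedSequence([seed, obj_i, trial]).generate_state(1)[0] % (2**31)
            )
            s = render_sample(mesh, sample_seed, config, k, object_id=name)
            init_png = obj_dir / f"{trial:05d}_init.png"
            opp_png = obj_dir / f"{trial:05d}_opp.png"
            meta = obj_dir / f"{trial:05d}.json"
            dvio.write_depth_png(init_png, s.initial)
            dvio.write_depth_png(opp_png, s.opposite)
            dvio.write_camera_json(
                meta, k, s.initial_pose,
                extra={
                    "t_gt": [float(x) for x in s.t_gt],
                    "opposite_R": [float(x) for x in s.opposite_pose.R.ravel()],
                    "opposite_T": [float(x) for x in s.opposite_pose.T],
                    "params": s.params,
                    "object": name,
                    "seed": s.seed,
                },
            )
            index.append({
                "object": name, "trial": trial, "seed": s.seed,
                "init": str(init_png.relative_to(out_dir)),
                "opp": str(opp_png.relative_to(out_dir)),
                "meta": str(meta.relative_to(out_dir)),
            })
    with open(out_dir / "index.jsonl", "w") as fh:
        for row in index:
            fh.write(json.dumps(row, sort_keys=True) + "\n")
    return index


def holdout_split(
    index: list, fractions: tuple[float, float, float] = (0.7, 0.1, 0.2), seed: int = 0
) -> tuple[list, list, list]:
    """Shuffle and partition into (train, validation, test).

    Floor allocation for validation and test; the remainder goes to train, so
    e.g. 28,571 samples at (0.7, 0.1, 0.2) split as 20,000 / 2,857 / 5,714.
    """
    if len(index) == 0:
        raise ValueError("cannot split an empty index")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(index)
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(math.floor(fractions[1] * n))
    n_test = int(math.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    pick = lambda idx: [index[i] for i in idx]  # noqa: E731
    return (
        pick(order[:n_train]),
        pick(order[n_train:n_train + n_val]),
        pick(order[n_train + n_val:]),
    )
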