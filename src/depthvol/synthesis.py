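"""Opposite-view depth synthesis: loss, models, training, and an oracle.

The learning task: given the depth image of an object seen from one viewing
angle, predict the depth image seen from the exactly opposite angle, plus
the inter-camera translation.  The training cost is an unnormalized sum of
squared depth residuals over all pixels plus a weighted squared error on the
translation:

    L = sum_{u,v} (d_pred(u,v) - d_true(u,v))^2 + lambda * ||t_pred - t_true||^2

with ``lambda = 1e-3`` by default.

Two encoder-decoder variants are provided (see :mod:`depthvol.nn`): a naive
convolutional encoder-decoder emitting only the depth image, and the
inception variant that first runs two inception blocks (parallel 3/5/7
kernels concatenated) and adds a second head emitting the translation.

:func:`oracle_synthesize` replaces a trained network with the renderer plus
controlled Gaussian noise, so the downstream completion and volumetry stages
can be exercised (and their sensitivity to prediction error measured)
without any training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import DepthImage, Intrinsics, RigidPose, rotation_about_y
from .render import render_depth

__all__ = [
    "SynthConfig",
    "Prediction",
    "synthesis_loss",
    "oracle_synthesize",
    "mirror_pose",
    "build_model",
    "train",
    "evaluate_loss",
    "render_training_pairs",
    "save_model",
    "load_model",
]


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Model/training configuration for the view-synthesis network."""

    height: int = 64
    width: int = 64
    latent: int = 128
    base_channels: int = 8
    inception_kernels: tuple[int, ...] = (3, 5, 7)
    lam: float = 1e-3  # translation regularization weight
    iterations: int = 600
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    normalize_pixels: bool = False  # mean-per-pixel loss toggle (off: raw sum)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.height % 16 or self.width % 16:
            raise ValueError("resolution must be divisible by the 4-stage "
                             "encoder's downsampling factor (16)")


@dataclasses.dataclass
class Prediction:
    """An opposite-view prediction: depth image plus translation (metres)."""

    depth: DepthImage
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)


def synthesis_loss(
    d_pred: DepthImage | np.ndarray,
    d_true: DepthImage | np.ndarray,
    t_pred: np.ndarray | None = None,
    t_true: np.ndarray | None = None,
    lam: float = 1e-3,
    normalize_pixels: bool = False,
) -> float:
    """The view-synthesis cost (module docstring); zero iff both match.

    The pixel term is a plain sum of squared differences over all h x w
    pixels (``normalize_pixels=True`` divides by h*w for cross-resolution
    comparability); the translation term is ``lam * ||t_pred - t_true||^2``
    and is omitted when either translation is None (depth-only models).
    """
    a = d_pred.values if isinstance(d_pred, DepthImage) else np.asarray(d_pred)
    b = d_true.values if isinstance(d_true, DepthImage) else np.asarray(d_true)
    if a.shape != b.shape:
        raise ValueError(f"depth shapes differ: {a.shape} vs {b.shape}")
    pixel = float(((a - b) ** 2).sum())
    if normalize_pixels:
        pixel /= a.size
    if t_pred is None or t_true is None:
        return pixel
    dt = np.asarray(t_pred, dtype=np.float64) - np.asarray(t_true, dtype=np.float64)
    return pixel + lam * float(dt @ dt)


def mirror_pose(initial_pose: RigidPose) -> RigidPose:
    """The exactly-mirrored opposite camera: same distance on the antipodal
    side of the object, orientation ``Ry(180) @ R_initial``."""
    ry = rotation_about_y(180.0)
    return RigidPose(ry @ initial_pose.R, -(ry @ initial_pose.T))


def oracle_synthesize(
    mesh,
    initial_pose: RigidPose,
    k: Intrinsics,
    depth_noise_sd: float = 0.0,
    translation_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    opposite_pose: RigidPose | None = None,
) -> Prediction:
    """Ground-truth opposite view plus controlled Gaussian noise.

    The opposite view is rendered at ``opposite_pose`` (default: the exact
    mirror of ``initial_pose``); i.i.d. depth noise is added to valid pixels
    only (clipped at 0, invalid pixels stay 0) and per-axis translation noise
    to the true inter-camera translation.  With both SDs zero this returns
    the exact ground truth.
    """
    if depth_noise_sd < 0 or translation_noise_sd < 0:
        raise ValueError("noise SDs must be non-negative")
    rng = rng or np.random.default_rng()
    opp = opposite_pose or mirror_pose(initial_pose)
    t_gt = opp.T - rotation_about_y(180.0) @ initial_pose.T
    depth = render_depth(mesh, opp, k)
    values = depth.values
    if depth_noise_sd > 0:
        valid = values > 0
        noisy = values + rng.normal(0.0, depth_noise_sd, size=values.shape)
        values = np.where(valid, np.clip(noisy, 0.0, None), 0.0)
    t = t_gt + (rng.normal(0.0, translation_noise_sd, size=3)
                if translation_noise_sd > 0 else 0.0)
    return Prediction(DepthImage(values), t)


# ---------------------------------------------------------------------------
# models and training


class _EncoderDecoder:
    """Shared machinery of the two view-synthesis variants.

    Encoder: four stride-2 convolutions to 1/16 resolution, flattened into a
    latent vector.  Decoder: a linear expansion followed by four nearest-
    neighbour-upsample + convolution stages back to full resolution, with a
    softplus output so predicted depths are non-negative.  The inception
    variant prepends two inception blocks (parallel 3/5/7 kernels
    concatenated) and adds a translation head on the latent vector.
    """

    def __init__(self, config: SynthConfig, inception: bool, extrinsic: bool):
        from . import nn

        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        h16, w16 = config.height // 16, config.width // 16
        self.inception = inception
        self.extrinsic = extrinsic
        self.config = config

        stem_out = 1
        self.stem = None
        if inception:
            # the first inception block is strided so the expensive large
            # kernels run once over the input instead of at full resolution
            # throughout; the encoder then needs one fewer stage
            b1 = nn.InceptionBlock(1, max(c // 2, 2), config.inception_kernels,
                                   stride=2, rng=rng)
            b2 = nn.InceptionBlock(b1.c_out, max(c // 2, 2),
                                   config.inception_kernels, rng=rng)
            self.stem = nn.Sequential(b1, b2)
            stem_out = b2.c_out
        stages = [
            nn.Conv2d(stem_out, c, stride=2, rng=rng), nn.ReLU(),
            nn.Conv2d(c, 2 * c, stride=2, rng=rng), nn.ReLU(),
            nn.Conv2d(2 * c, 4 * c, stride=2, rng=rng), nn.ReLU(),
            nn.Conv2d(4 * c, 8 * c, stride=2, rng=rng), nn.ReLU(),
        ]
        if inception:  # the strided stem already halved the resolution
            stages = [
                nn.Conv2d(stem_out, 2 * c, stride=2, rng=rng), nn.ReLU(),
                nn.Conv2d(2 * c, 4 * c, stride=2, rng=rng), nn.ReLU(),
                nn.Conv2d(4 * c, 8 * c, stride=2, rng=rng), nn.ReLU(),
            ]
        self.encoder = nn.Sequential(
            *stages,
            nn.Flatten(),
            nn.Linear(8 * c * h16 * w16, config.latent, rng=rng), nn.ReLU(),
        )
        self.expand = nn.Sequential(
            nn.Linear(config.latent, 8 * c * h16 * w16, rng=rng), nn.ReLU())
        self.decoder = nn.Sequential(
            nn.Upsample2x(), nn.Conv2d(8 * c, 4 * c, rng=rng), nn.ReLU(),
            nn.Upsample2x(), nn.Conv2d(4 * c, 2 * c, rng=rng), nn.ReLU(),
            nn.Upsample2x(), nn.Conv2d(2 * c, c, rng=rng), nn.ReLU(),
            nn.Upsample2x(), nn.Conv2d(c, 1, rng=rng), nn.Softplus(),
        )  # softplus keeps predicted depths non-negative
        self.t_head = None
        if extrinsic:
            self.t_head = nn.Sequential(
                nn.Linear(config.latent, 64, rng=rng), nn.ReLU(),
                nn.Linear(64, 3, rng=rng))
        pieces = [self.encoder, self.expand, self.decoder]
        if self.stem is not None:
            pieces.append(self.stem)
        if self.t_head is not None:
            pieces.append(self.t_head)
        self.params = sum((p.params for p in pieces), [])
        self.grads = sum((p.grads for p in pieces), [])

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray):
        """x: (N, 1, H, W) -> (depth (N, 1, H, W), translation (N, 3) | None)."""
        if self.stem is not None:
            x = self.stem.forward(x)
        z = self.encoder.forward(x)
        h16, w16 = self.config.height // 16, self.config.width // 16
        c8 = 8 * self.config.base_channels
        d = self.expand.forward(z).reshape(len(z), c8, h16, w16)
        depth = self.decoder.forward(d)
        t = self.t_head.forward(z) if self.t_head is not None else None
        return depth, t

    def backward(self, d_depth: np.ndarray, d_t: np.ndarray | None):
        dz = self.expand.backward(
            self.decoder.backward(d_depth).reshape(len(d_depth), -1))
        if self.t_head is not None and d_t is not None:
            dz = dz + self.t_head.backward(d_t)
        dx = self.encoder.backward(dz)
        if self.stem is not None:
            dx = self.stem.backward(dx)
        return dx

    def predict(self, depth: "DepthImage") -> Prediction:
        x = depth.values[None, None, :, :].astype(np.float32)
        d, t = self.forward(x)
        return Prediction(
            DepthImage(np.maximum(d[0, 0], 0.0)),
            np.zeros(3) if t is None else t[0],
        )


def build_model(config: SynthConfig, variant: str = "inception_extrinsic") -> _EncoderDecoder:
    """Construct a view-synthesis model.

    ``"naive"``: plain convolutional encoder-decoder, depth output only.
    ``"inception_extrinsic"``: two inception blocks before the encoder and a
    second head emitting the inter-camera translation.
    """
    if variant == "naive":
        return _EncoderDecoder(config, inception=False, extrinsic=False)
    if variant == "inception_extrinsic":
        return _EncoderDecoder(config, inception=True, extrinsic=True)
    raise ValueError(f"unknown variant {variant!r}")


def evaluate_loss(model: _EncoderDecoder, x, y, t, lam: float = 1e-3,
                  batch: int = 64) -> float:
    """Mean per-sample synthesis loss of ``model`` on a dataset."""
    total = 0.0
    for i in range(0, len(x), batch):
        d_pred, t_pred = model.forward(x[i:i + batch])
        total += ((d_pred - y[i:i + batch]) ** 2).sum()
        if t_pred is not None:
            total += lam * ((t_pred - t[i:i + batch]) ** 2).sum()
    return float(total / len(x))


def train(model: _EncoderDecoder, data: dict, config: SynthConfig,
          eval_every: int = 25) -> dict:
    """Minibatch Adam training on rendered pairs.

    ``data`` holds ``x`` (initial views, (N,1,H,W)), ``y`` (opposite views),
    ``t`` (translations, (N,3)) for the ``train`` and ``val`` splits.
    The parameters with the best validation loss seen are restored at the
    end (early stopping — at this data scale long training overfits).
    Returns per-evaluation train/validation loss curves; raises on
    divergence (non-finite loss).
    """
    from . import nn

    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.params, model.grads, lr=config.learning_rate)
    xt, yt, tt = data["train"]["x"], data["train"]["y"], data["train"]["t"]
    curves = {"iteration": [], "train": [], "val": []}
    best_val, best_params = np.inf, None
    for it in range(config.iterations):
        idx = rng.choice(len(xt), size=min(config.batch_size, len(xt)), replace=False)
        xb = xt[idx].astype(np.float32)
        yb, tb = yt[idx], tt[idx]
        d_pred, t_pred = model.forward(xb)
        resid = d_pred - yb
        loss = float((resid**2).sum() / len(xb))
        d_depth = 2.0 * resid / len(xb)
        d_t = None
        if t_pred is not None:
            t_resid = t_pred - tb
            loss += config.lam * float((t_resid**2).sum() / len(xb))
            d_t = 2.0 * config.lam * t_resid / len(xb)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it}: loss={loss}")
        model.backward(d_depth, d_t)
        opt.step()
        if it % eval_every == 0 or it == config.iterations - 1:
            val = evaluate_loss(model, data["val"]["x"], data["val"]["y"],
                                data["val"]["t"], config.lam)
            curves["iteration"].append(it)
            curves["train"].append(loss)
            curves["val"].append(val)
            if val < best_val:
                best_val = val
                best_params = [p.copy() for p in model.params]
    if best_params is not None:
        for p, bp in zip(model.params, best_params):
            p[...] = bp
    return curves


def render_training_pairs(meshes: dict, n_per_object: int, seed: int,
                          k: Intrinsics, config=None) -> dict:
    """Render pose-pair arrays for training (in memory, no files)."""
    from .render import render_sample

    xs, ys, ts = [], [], []
    for obj_i, (name, mesh) in enumerate(sorted(meshes.items())):
        for i in range(n_per_object):
            s_seed = int(np.random.SeedSequence(
                [seed, obj_i, i]).generate_state(1)[0] % (2**31))
            s = render_sample(mesh, s_seed, config, k, object_id=name)
            xs.append(s.initial.values)
            ys.append(s.opposite.values)
            ts.append(s.t_gt)
    x = np.asarray(xs)[:, None, :, :]
    y = np.asarray(ys)[:, None, :, :]
    t = np.asarray(ts)
    return {"x": x, "y": y, "t": t}


def save_model(model: _EncoderDecoder, path) -> None:
    """Checkpoint: parameters plus the embedded configuration."""
    import json

    meta = {
        "config": dataclasses.asdict(model.config),
        "variant": ("inception_extrinsic" if model.inception else "naive"),
    }
    arrays = {f"p{i}": p for i, p in enumerate(model.params)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> _EncoderDecoder:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import json

    blob = np.load(path, allow_pickle=False)
    meta = json.loads(str(blob["meta"]))
    cfg = meta["config"]
    cfg["inception_kernels"] = tuple(cfg["inception_kernels"])
    model = build_model(SynthConfig(**cfg), meta["variant"])
    for i, p in enumerate(model.params):
        p[...] = blob[f"p{i}"]
    return model
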