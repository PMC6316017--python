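# depthvol

Estimating the volume of a food portion from a **single depth image** is a
core step in objective dietary assessment: portion size drives nutrient
intake, and self-reported estimates are notoriously biased.  A single
depth map, however, only sees the near surface of an object — the far side
is self-occluded, and volumes computed from one view alone are unreliable.

`depthvol` implements the opposite-view completion approach to this
problem.  The observed depth map d(u, v) is paired with the depth map an
exactly opposite-facing camera would see (rendered from a mesh,
synthesized by an oracle with controlled noise, or predicted by a small
encoder–decoder network that also emits the inter-camera translation).
Both maps are back-projected through the pinhole model,

    [X, Y, Z]ᵀ = Z · K⁻¹ · [u, v, 1]ᵀ,

and the opposite view is registered into the initial camera's frame
through a fixed 180° rotation about the vertical axis plus a translation
T, p_w = Ry(180°)⁻¹ (p − T), with Ry(180°) = diag(−1, 1, −1).  T is
refined by a **translation-only ICP** on the silhouette contours (the
rotation is never updated), the fused cloud is cleaned by statistical
outlier removal, and the volume is measured by an **alpha-shape** surface
reconstruction with a stability-selected alpha.  A synthetic-data module
generates the whole study: analytic primitives (cube, sphere, cylinder,
capsule, ellipsoid, bent "banana" capsule) with closed-form volumes,
pose-pair sampling over azimuth/elevation/distance/centre-shift ranges,
and a deterministic depth rasterizer.

See `docs/methods.md` for the model, the registration corrections
(rim-retreat and perspective tangency gap, free-space clamp) and the
alpha-ladder volumetry.

## Worked example

```python
import numpy as np
from depthvol import (DEFAULT_INTRINSICS, complete_cloud, default_catalogue,
                      estimate_volume, make_primitive, oracle_synthesize,
                      render_sample)

mesh, analytic_cm3 = make_primitive(default_catalogue()["sphere"])
sample = render_sample(mesh, seed=42, k=DEFAULT_INTRINSICS)  # one pose pair

# opposite view from the oracle: noisy depth + noisy translation
pred = oracle_synthesize(mesh, sample.initial_pose, DEFAULT_INTRINSICS,
                         depth_noise_sd=0.003, translation_noise_sd=0.02,
                         rng=np.random.default_rng(1),
                         opposite_pose=sample.opposite_pose)
print("translation error before ICP: %.1f mm"
      % (1000 * np.linalg.norm(pred.translation - sample.t_gt)))

cloud = complete_cloud(sample.initial, pred.depth, DEFAULT_INTRINSICS,
                       pred.translation, refine=True)
result = estimate_volume(cloud)
print("estimated %.1f cm^3 vs analytic %.1f cm^3 (error %.1f%%)"
      % (result.volume_cm3, analytic_cm3,
         100 * abs(result.volume_cm3 - analytic_cm3) / analytic_cm3))
```

prints

```
translation error before ICP: 26.5 mm
estimated 210.3 cm^3 vs analytic 203.7 cm^3 (error 3.3%)
```

— the ICP stage and the tangency-gap corrections recover the registration
from an initial translation error of several centimetres, and the fused
two-view cloud reproduces the sphere's volume to a few percent.

A command-line interface covers the same pipeline
(`depthvol render-dataset`, `depthvol complete`, `depthvol volume`,
`depthvol evaluate`).

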