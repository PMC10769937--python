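# earreg

Complete-to-partial non-rigid point-cloud registration for middle-ear
anatomy, together with the synthetic shape-variant generator and the
evaluation metrics needed to exercise the whole method on self-generated
data.

## Who this is for

Depth-resolved imaging of the middle ear in vivo (e.g., endoscopic optical
coherence tomography) yields point clouds that are noisy and only partially
visible: the ear-canal wall and tympanic membrane shadow the ossicles
behind them. Fitting a complete segmented template — canal wall, tympanic
membrane, malleus, incus, stapes — onto such a partial scan transfers
structure labels, landmarks and hidden geometry onto the patient data.
`earreg` implements that fitting problem for researchers working on
anatomical registration who need a reproducible, CPU-scale pipeline with
full ground truth.

## The method

Given a complete template `P_exv = {x_i}` and a partial target
`P_inv = {y_j}` (coordinates in mm), registration runs in two stages:

1. **Rigid initialization.** A pluggable backend estimates
   `tau in SE(3)` and a sparse correspondence set `sigma = {(u, v)}`
   linking template and target indices. Backends: `oracle` (exact pairs
   from simulator provenance) and `descriptor` (voxel downsampling, FPFH
   descriptors, mutual matching, seeded RANSAC with symmetry-aware model
   selection, trimmed-ICP polish).
2. **Deformation pyramid.** With the template pre-aligned by `tau`, the
   residual motion is decomposed over pyramid levels. At level `k`, points
   are encoded as `Gamma(p) = (sin(2^(k+k0) p), cos(2^(k+k0) p))` and a
   small per-level MLP maps encodings to per-point displacement
   increments, optimized per instance against a masked Chamfer distance
   plus a point-to-point term over `sigma` and an increment-norm
   regularizer. The final field `phi_est` is expressed in the original
   template frame.

Accuracy is reported as mean displacement error
`MDE = mean_i ||phi_est,i - phi_gt,i||`, Chamfer distance between the
deformed template and the target, and a per-structure landmark error.
Details, defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

```python
import earreg

cfg = earreg.SimulationConfig()                  # default study conditions
sample = earreg.generate_sample(cfg, seed=7)     # simulate one "patient"
print(f"template: {len(sample.template)} points, target: {len(sample.target)} points")
print(f"visible ratio: {sample.visible_ratio:.3f}")
print(f"mean target displacement: {sample.gt_displacement.mean_norm():.3f} mm")

result = earreg.register_c2p(
    sample.template, sample.target,
    stage1_backend="oracle", cfg=earreg.PyramidConfig(seed=0),
)
report = earreg.evaluate_sample(result, sample, sample_id="demo")
print(f"MDE: {report.mde:.3f} mm")
print(f"Chamfer distance: {report.chamfer:.3f} mm")
print(f"landmark error: {report.landmark_error:.3f} mm")
```

Output:

```
template: 1600 points, target: 864 points
visible ratio: 0.540
mean target displacement: 1.675 mm
MDE: 0.243 mm
Chamfer distance: 0.303 mm
landmark error: 0.428 mm
```

The simulated patient differs from the template by ~1.7 mm of articulated
and soft-tissue motion, and only 54 % of its surface is visible; the
pipeline recovers the per-point motion to 0.24 mm, i.e., registration
reduces the anatomical mismatch by roughly a factor of seven.

## Command line

```sh
earreg simulate --n 10 --seed 0 --out-dir data/           # dataset + manifest
earreg register --source data/sample_0000/template.ply \
                --target data/sample_0000/target.ply \
                --backend oracle --out-dir results/sample_0000
earreg evaluate --results-dir results --samples-dir data --out-csv report.csv
```

Clouds are PLY (ascii or binary little-endian; optional `label` and
`source_index` vertex properties) or whitespace XYZ; displacement fields
are 3-column CSV; landmarks, transforms, correspondences and manifests are
JSON. All runs are deterministic in their seeds.

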