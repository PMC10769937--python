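# Methods

`earreg` registers a complete ("ex vivo") middle-ear point-cloud template
onto a partial, noisy ("in vivo") target cloud, and ships the synthetic
generator used to exercise and validate the method end-to-end. This note
records the models, the defaults and why they were chosen, and what the
synthetic experiments do and do not demonstrate.

## Problem setting

The middle ear comprises the tympanic membrane and the ossicular chain
(malleus, incus, stapes) behind the ear-canal wall. Depth-resolved optical
imaging of the ear in vivo sees only part of this anatomy: posterior
structures are shadowed by anterior ones, surfaces are sampled unevenly,
and coordinates are noisy. Registration of a complete segmented template
onto such a partial view transfers anatomical knowledge (structure labels,
landmarks, hidden geometry) onto the patient scan.

Formally: given a template cloud `P_exv = {x_i}` (N points, mm) and a
partial target `P_inv = {y_j}` (M points), estimate a displacement field
`phi` such that `x_i + phi_i` lies on the patient's anatomy. The pipeline
is two-staged:

1. **Rigid initialization + correspondences.** A stage-1 backend returns a
   rigid transform `tau in SE(3)` aligning the template toward the target
   and a sparse correspondence set `sigma = {(u, v)}` of index pairs.
2. **Deformation pyramid.** With the template pre-aligned by `tau`, the
   non-rigid residual is decomposed into per-level sub-motions. At level
   `k` the current points `p` are encoded as
   `Gamma(p) = (sin(2^(k+k0) p), cos(2^(k+k0) p))` (componentwise, a
   6-vector per point) and a small randomly initialized MLP maps encodings
   to per-point 3-D increments, optimized per instance. Low levels see
   near-constant encodings and can only express near-global motion; deeper
   levels refine local detail.

### Stage-2 loss

Each level minimizes

```
L = CD(deformed_masked, P_inv) + w_sigma * mean_{(u,v)} ||x_u - y_v||^2
    + gamma_k * mean_i ||incr_i||^2
```

where `CD` is the (non-squared) Chamfer distance restricted on the source
side to the points indexed by `sigma`, the second term anchors matched
pairs point-to-point, and the third penalizes unnecessary motion with
`gamma_k = gamma * 0.5^(k-1)` so high-frequency levels may express finer
corrections. The pairwise anchor exists because Chamfer alone is blind to
motion tangential to the target surface: in calibration runs the deformed
template landed on the target surface (mean nearest-neighbour distance
~0.18 mm) while the displacement error remained ~40-55 % of the true
motion. Anchoring the `sigma` pairs removes precisely that null space; it
is the same device as the landmark/correspondence energies of classical
non-rigid ICP.

Gradients of the Chamfer term are computed with nearest-neighbour
assignments frozen at the current iterate (exact at that point, the
standard treatment); optimization is Adam. The output layer of every level
regressor is zero-initialized so each level starts from the identity and
the first loss value is the level's incoming loss.

### Numerical choices

- Coordinates are normalized to the joint unit bounding box of source and
  target before encoding, and fields are rescaled to mm afterwards; this
  makes the frequency ladder transferable across specimen sizes.
- Defaults: `n_levels = 11`, `k0 = -8` (top frequency `2^3` per unit box),
  `m = 100` iterations/level, width 64, depth 3, step size `1e-3`,
  `gamma = 0.5`, `w_sigma = 10`. An earlier 7-level ladder topping out at
  frequency `2^-1` left every encoding nearly constant and could not
  express spatially varying motion; eleven levels resolve the articulated
  per-structure motions the simulator produces.
- Early stop per level: when the best total loss improves by less than
  `1e-4` (relative) over the last 10 iterations. The best-so-far parameters
  are restored at level end, so the accepted-loss trajectory is
  non-increasing by construction.
- Chamfer nearest neighbours use a KD-tree rebuilt every iteration; no
  subsampling at the <10k-point scale this package targets.
- Degenerate inputs: empty `sigma` and non-finite losses raise immediately
  with level/iteration context.

### Stage-1 backends

- `oracle`: uses the simulator's per-point provenance (`source_index`) to
  return exact pairs and the least-squares (Kabsch) rigid fit over them.
  It isolates stage-2 behaviour from stage-1 quality in experiments.
- `descriptor`: classical global registration — 0.3 mm voxel downsampling,
  local-PCA normals oriented away from the centroid, FPFH descriptors
  (11 bins x 3 angular features, distance-weighted neighbour pooling),
  mutual nearest-neighbour matching, and seeded RANSAC (50k iterations,
  0.5 mm inlier threshold). The ear is nearly rotationally symmetric about
  the canal axis (tube + disc), so RANSAC hypotheses are re-scored by
  target-node coverage after a short trimmed-ICP polish, with a residual
  tightness tiebreak; only the asymmetric ossicles separate the aliases.
  `sigma` is reported in original index space (each node mapped to its
  nearest original point) restricted to inliers under the refined `tau`.

A learned correspondence network could implement the same contract; the
backend interface exists so any such model can be plugged in without
touching stage 2.

## Synthetic generator

The generator stands in for real acquisitions, which are not available. A
procedural segmented template (curved open tube for the canal wall, conical
disc for the membrane, three articulated prolate bodies for the ossicles;
1600 vertices at default counts, mm units, +z posterior) is deformed in two
stages and then partially observed:

- **Non-rigid stage.** Per structure, a trilinear free-form-deformation
  lattice (3x3x3) is fitted to the structure's principal-axes bounding box.
  Control points are grouped into slabs along length/thickness/width; each
  slab receives a random bounded rigid motion and vertices move by
  trilinear interpolation (convex weights, so no vertex moves farther than
  the most-displaced control point). Landmarks, support and articulation
  points ride the same field.
- **Rigid stage.** A forward-kinematic chain over the articulation points:
  joint 0 (canal rim) is the root and re-poses the whole assembly; each
  deeper joint rotates/translates its downstream structures about the
  already-transformed pivot. Within-structure distances are preserved to
  1e-9.
- **Partial view.** Per structure, vertex keep-scores
  `exp(-d_i / lambda) + eps_i` (distance to the structure's support point,
  default the centroid; Gaussian score noise sd 0.15) are thresholded so
  that exactly `round(sum_i exp(-d_i/lambda) * u^t)` vertices survive,
  where `u ~ U(0.5, 1)` and `t` is the structure's normalized depth from
  the external-ear reference point — posterior structures are thinned
  more, and the full cloud is retained exactly when `lambda = inf` and the
  occlusion range collapses to 1. Survivors get per-axis uniform jitter
  (+-0.05 mm).

Deformation bounds (lattice-slab translations up to 0.35-0.55 mm and
rotations up to 9 degrees; joint rotations 10-14 degrees, joint
translations 0.15-1.5 mm) were fixed once so that the mean target
displacement over seeds is ~1.5 mm, a clinically plausible inter-subject
scale for this anatomy; they are package choices, not measured values.
Every stage is a pure function of (inputs, seed); datasets derive
per-sample seeds as `seed + index`.

**What the generator does not emulate:** speckle and detector noise
statistics of real depth-resolved imaging, segmentation errors, surface
reconstruction artifacts, pathology (effusion, retraction, discontinuity),
and inter-subject topology changes. Passing the synthetic experiments
therefore demonstrates the pipeline's mechanics — rigid recovery,
non-rigid recovery under partial visibility, metric correctness — not
clinical-grade accuracy on patient data.

## Evaluation metrics

- **Chamfer distance** `CD(A,B) = mean_x min_y |x-y| + mean_y min_x |x-y|`
  (non-squared norms, mm). Reported between the *full* deformed template
  and the target, so squeezing unseen geometry onto the visible patch is
  penalized.
- **Mean displacement error (MDE)**: mean Euclidean norm of
  `phi_est - phi_gt` over template points; across a dataset, the mean of
  per-sample values. (The per-sample per-point reduction is made explicit
  here; a dataset-level mean without it would be dimensionally identical
  but ill-defined for unequal cloud sizes.)
- **Landmark error**: mean over template landmarks of the distance to the
  nearest target landmark *of the same structure*; structures missing on
  either side are skipped with a warning. Template landmarks are extremal
  /centroid vertices of each structure, and the estimated field is sampled
  at a landmark by nearest-vertex lookup (exact for vertex landmarks).
- **Visible-points ratio**: `|P_inv| / |T~|`, the fraction of the shape
  variant present in the target.

## Known limitations

- Per-level motion is a free 3-D displacement per point; rigid character at
  shallow levels is emergent (near-constant encodings), not enforced as an
  explicit per-point SE(3) action.
- `sigma` is estimated once and held fixed; no re-matching between levels.
- The descriptor backend assumes the target is a rigid+small-deformation
  view of the template; it is not a partial-to-partial matcher.
- Runtime scales with N * m * n_levels through the per-iteration KD-tree
  rebuild; the defaults target ~2 s per registration at 1.6k points on one
  CPU core.
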