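"""Procedural middle-ear simulator.

Builds a segmented template (ear-canal wall, tympanic membrane, malleus,
incus, stapes), then produces "patient" shape variants in two stages:

1. non-rigid: per-structure trilinear free-form deformation (FFD) whose
   control points are grouped into slabs along the structure's principal
   axes (length / thickness / width) and moved by random bounded rigid
   motions — a mathematical equivalent of lattice-modifier rigs;
2. rigid: a forward-kinematic chain over the articulation points, each
   joint receiving a random bounded rotation + translation that propagates
   to all downstream structures.

Finally, a partial noisy "in vivo" view is extracted: per-structure
visibility decays exponentially with distance from a support point
(perturbed by Gaussian score noise), posterior structures are thinned by a
random occlusion factor that decays with depth from the external-ear
reference point, and surviving points receive bounded uniform jitter.

Everything is a pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ConfigError, ModelError
from .geometry import (
    CorrespondenceSet,
    DisplacementField,
    PointCloud,
    RigidTransform,
    compose_rigid,
)

STRUCTURE_ORDER = ("canal_wall", "tympanic_membrane", "malleus", "incus", "stapes")

DEFAULT_POINTS_PER_STRUCTURE = {
    "canal_wall": 500,
    "tympanic_membrane": 400,
    "malleus": 300,
    "incus": 250,
    "stapes": 150,
}


@dataclass
class LandmarkSet:
    """Per-structure anatomical landmark coordinates (mm)."""

    landmarks: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for k, v in self.landmarks.items():
            v = np.asarray(v, dtype=np.float64).reshape(-1, 3)
            if len(v) < 1:
                raise ValueError(f"structure {k!r} has no landmarks")
            clean[k] = v
        if not clean:
            raise ValueError("landmark set is empty")
        self.landmarks = clean

    def structures(self) -> List[str]:
        return list(self.landmarks)

    def total(self) -> int:
        return sum(len(v) for v in self.landmarks.values())


@dataclass
class EarModel:
    """Segmented middle-ear model: ordered structures (anterior→posterior),
    articulation chain, per-structure support anchors and landmarks."""

    structures: Dict[str, PointCloud]
    articulation_points: np.ndarray  # (S-1, 3), joint j between structures j, j+1
    support_points: Dict[str, np.ndarray]
    landmarks: LandmarkSet
    external_point: np.ndarray  # external-ear reference (canal entry)

    def __post_init__(self) -> None:
        if len(self.structures) < 2:
            raise ModelError("ear model needs at least 2 structures")
        for name, cloud in self.structures.items():
            if len(cloud) < 1:
                raise ModelError(f"structure {name!r} is empty")
        self.articulation_points = np.asarray(
            self.articulation_points, dtype=np.float64
        ).reshape(-1, 3)
        if len(self.articulation_points) != len(self.structures) - 1:
            raise ModelError(
                "articulation point count must equal structure count - 1"
            )
        self.support_points = {
            k: np.asarray(v, dtype=np.float64).reshape(3)
            for k, v in self.support_points.items()
        }
        self.external_point = np.asarray(self.external_point, dtype=np.float64).reshape(3)

    @property
    def structure_names(self) -> List[str]:
        return list(self.structures)

    def structure_slices(self) -> Dict[str, slice]:
        out, start = {}, 0
        for name, cloud in self.structures.items():
            out[name] = slice(start, start + len(cloud))
            start += len(cloud)
        return out

    def all_points(self) -> PointCloud:
        """All vertices stacked in structure order, labelled by structure index."""
        pts = np.vstack([c.points for c in self.structures.values()])
        labels = np.concatenate(
            [np.full(len(c), i) for i, c in enumerate(self.structures.values())]
        )
        return PointCloud(pts, labels=labels)

    def n_vertices(self) -> int:
        return sum(len(c) for c in self.structures.values())


@dataclass
class GroupBounds:
    """Bounds for one structure's FFD control-point groups."""

    max_translation_mm: float = 0.0
    max_rotation_deg: float = 0.0

    def validate(self) -> None:
        if self.max_translation_mm < 0 or self.max_rotation_deg < 0:
            raise ConfigError("non-rigid bounds must be >= 0")


@dataclass
class JointBounds:
    """Bounds for one kinematic-chain joint."""

    max_rotation_deg: float = 0.0
    max_translation_mm: float = 0.0

    def validate(self) -> None:
        if self.max_rotation_deg < 0 or self.max_translation_mm < 0:
            raise ConfigError("rigid bounds must be >= 0")


def _default_nonrigid_bounds() -> Dict[str, GroupBounds]:
    # calibrated once to give a mean target displacement of ~1.5 mm together
    # with the joint bounds below
    return {
        "canal_wall": GroupBounds(0.45, 7.0),
        "tympanic_membrane": GroupBounds(0.55, 9.0),
        "malleus": GroupBounds(0.45, 9.0),
        "incus": GroupBounds(0.45, 9.0),
        "stapes": GroupBounds(0.35, 9.0),
    }


def _default_rigid_bounds() -> List[JointBounds]:
    # joint 0 = chain root (whole-assembly pose), then malleus/incus/stapes
    return [
        JointBounds(14.0, 1.5),
        JointBounds(10.0, 0.45),
        JointBounds(10.0, 0.35),
        JointBounds(10.0, 0.25),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults define the study conditions."""

    nonrigid_bounds: Dict[str, GroupBounds] = field(default_factory=_default_nonrigid_bounds)
    rigid_bounds: List[JointBounds] = field(default_factory=_default_rigid_bounds)
    lattice_resolution: Tuple[int, int, int] = (3, 3, 3)
    visibility_lambda: float = 3.0  # mm; distance-decay scale of visibility
    visibility_noise_sd: float = 0.15  # sd of the Gaussian keep-score noise
    occlusion_range: Tuple[float, float] = (0.5, 1.0)  # U(a,b) retention factor
    jitter_delta: float = 0.05  # mm, per-axis uniform jitter bound
    n_points_per_structure: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POINTS_PER_STRUCTURE)
    )
    template_seed: int = 0
    seed: int = 0

    def validate(self) -> None:
        for b in self.nonrigid_bounds.values():
            b.validate()
        for b in self.rigid_bounds:
            b.validate()
        a, b = self.occlusion_range
        if not (0.0 <= a <= b <= 1.0):
            raise ConfigError("occlusion_range must satisfy 0 <= a <= b <= 1")
        if any(r < 2 for r in self.lattice_resolution):
            raise ConfigError("lattice_resolution must be >= 2 per axis")
        if self.jitter_delta < 0:
            raise ConfigError("jitter_delta must be >= 0")
        if self.visibility_lambda <= 0:
            raise ConfigError("visibility_lambda must be > 0")
        if self.visibility_noise_sd < 0:
            raise ConfigError("visibility_noise_sd must be >= 0")

    @staticmethod
    def keep_all(**overrides) -> "SimulationConfig":
        """Deformations at defaults but full visibility and no jitter."""
        cfg = SimulationConfig(
            visibility_lambda=np.inf,
            visibility_noise_sd=0.0,
            occlusion_range=(1.0, 1.0),
            jitter_delta=0.0,
        )
        return replace(cfg, **overrides)

    @staticmethod
    def neutral(**overrides) -> "SimulationConfig":
        """Zero bounds everywhere: every stage is the identity."""
        cfg = SimulationConfig.keep_all()
        cfg.nonrigid_bounds = {k: GroupBounds(0.0, 0.0) for k in STRUCTURE_ORDER}
        cfg.rigid_bounds = [JointBounds(0.0, 0.0) for _ in range(4)]
        return replace(cfg, **overrides)


@dataclass
class Sample:
    """One simulated registration problem with full ground truth."""

    template: PointCloud  # P_exv: complete template vertices
    target: PointCloud  # P_inv: partial noisy view, source_index into variant
    gt_displacement: DisplacementField  # template -> variant, per vertex
    variant: PointCloud  # complete shape-variant vertices
    landmarks_template: LandmarkSet
    landmarks_target: LandmarkSet
    visible_ratio: float
    template_model: Optional[EarModel] = None
    variant_model: Optional[EarModel] = None

    def __post_init__(self) -> None:
        if len(self.gt_displacement) != len(self.template):
            raise ModelError("ground-truth field length must equal template size")
        expected = len(self.target) / len(self.variant)
        if abs(self.visible_ratio - expected) > 1e-12:
            raise ModelError("visible_ratio must equal |target| / |variant|")


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


def _sample_tube(rng, n, radius, length, curvature, z0):
    """Open curved tube along +z (ear-canal wall)."""
    z = rng.uniform(0.0, length, n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    x = radius * np.cos(theta) + curvature * np.sin(np.pi * z / length)
    y = radius * np.sin(theta)
    return np.column_stack([x, y, z + z0])


def _sample_cone_disc(rng, n, radius, apex_depth, z0):
    """Shallow cone (tympanic membrane); apex (umbo) points posteriorly."""
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    theta = rng.uniform(0.0, 2 * np.pi, n)
    z = z0 + apex_depth * (1.0 - r / radius)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _sample_ellipsoid(rng, n, semi_axes, center, tilt_deg):
    """Prolate ellipsoid surface, long axis tilted from +z in the x-z plane."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = v * np.asarray(semi_axes)
    a = np.radians(tilt_deg)
    R = np.array(
        [[np.cos(a), 0.0, np.sin(a)], [0.0, 1.0, 0.0], [-np.sin(a), 0.0, np.cos(a)]]
    )
    return pts @ R.T + np.asarray(center)


def build_template(
    n_points_per_structure: Optional[Dict[str, int]] = None, seed: int = 0
) -> EarModel:
    """Construct the procedural segmented template.

    The depth axis is +z (anterior → posterior): a curved open tube (canal
    wall), a conical disc (tympanic membrane) and three articulated prolate
    ossicle bodies chained end-to-end. Landmarks per structure are the two
    extremal vertices along the structure's principal axis plus the vertex
    nearest the centroid; all are actual cloud vertices.
    """
    counts = dict(DEFAULT_POINTS_PER_STRUCTURE)
    if n_points_per_structure:
        counts.update(n_points_per_structure)
    for name in STRUCTURE_ORDER:
        if counts.get(name, 0) < 50:
            raise ConfigError(f"need >= 50 points for structure {name!r}")
    rng = np.random.default_rng(seed)

    geom = {
        "canal_wall": _sample_tube(rng, counts["canal_wall"], 2.2, 6.5, 0.4, -7.0),
        "tympanic_membrane": _sample_cone_disc(
            rng, counts["tympanic_membrane"], 2.0, 0.6, -0.2
        ),
        "malleus": _sample_ellipsoid(
            rng, counts["malleus"], (0.30, 0.30, 1.10), (0.35, 0.35, 1.30), 20.0
        ),
        "incus": _sample_ellipsoid(
            rng, counts["incus"], (0.35, 0.30, 0.85), (0.55, 0.10, 2.90), -15.0
        ),
        "stapes": _sample_ellipsoid(
            rng, counts["stapes"], (0.25, 0.20, 0.50), (0.30, -0.10, 4.10), 10.0
        ),
    }
    structures = {
        name: PointCloud(geom[name], labels=np.full(counts[name], i))
        for i, name in enumerate(STRUCTURE_ORDER)
    }
    articulations = np.array(
        [
            [0.0, 2.1, -0.4],  # canal rim / membrane annulus (chain root)
            [0.35, 0.35, 0.40],  # umbo: membrane -> malleus manubrium
            [0.45, 0.20, 2.15],  # incudomalleolar joint
            [0.40, -0.05, 3.65],  # incudostapedial joint
        ]
    )
    support = {name: geom[name].mean(axis=0) for name in STRUCTURE_ORDER}
    landmarks = {}
    for name in STRUCTURE_ORDER:
        pts = geom[name]
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        centroid_idx = int(np.argmin(np.linalg.norm(centered, axis=1)))
        landmarks[name] = pts[[int(np.argmin(proj)), int(np.argmax(proj)), centroid_idx]]
    canal = geom["canal_wall"]
    external = canal[int(np.argmin(canal[:, 2]))]
    return EarModel(
        structures=structures,
        articulation_points=articulations,
        support_points=support,
        landmarks=LandmarkSet(landmarks),
        external_point=external,
    )


# ---------------------------------------------------------------------------
# non-rigid stage: per-structure free-form deformation
# ---------------------------------------------------------------------------


def _principal_frame(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed principal-axes frame (rows = axes)."""
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center, full_matrices=False)
    axes = vt.copy()
    for i in range(3):  # fix signs deterministically
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return center, axes


class _FFDLattice:
    """Trilinear free-form deformation grid over a structure's local
    bounding box (principal-axes frame)."""

    def __init__(self, points: np.ndarray, resolution: Tuple[int, int, int]):
        self.center, self.axes = _principal_frame(points)
        local = (points - self.center) @ self.axes.T
        lo = local.min(axis=0)
        hi = local.max(axis=0)
        pad = 1e-6 + 0.01 * np.maximum(hi - lo, 1e-9)
        self.lo = lo - pad
        self.hi = hi + pad
        self.res = tuple(int(r) for r in resolution)
        grids = [np.linspace(self.lo[a], self.hi[a], self.res[a]) for a in range(3)]
        gx, gy, gz = np.meshgrid(*grids, indexing="ij")
        self.control = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        self.control_disp = np.zeros_like(self.control)
        self._index = np.stack(
            np.meshgrid(*[np.arange(r) for r in self.res], indexing="ij"), axis=-1
        ).reshape(-1, 3)

    def randomize_groups(self, bounds: GroupBounds, rng: np.random.Generator) -> None:
        """Slab groups along each principal axis (length/thickness/width);
        each group receives a bounded random rigid motion of its control
        points; contributions accumulate."""
        t_max = bounds.max_translation_mm
        r_max = np.radians(bounds.max_rotation_deg)
        for axis in range(3):
            for slab in range(self.res[axis]):
                mask = self._index[:, axis] == slab
                # draws happen regardless of bounds so that the RNG stream —
                # and hence the variant for a given seed — does not depend on
                # whether a bound is zero
                trans = rng.uniform(-1.0, 1.0, 3) * t_max
                rot_axis = rng.normal(size=3)
                angle = rng.uniform(-1.0, 1.0) * r_max
                if not mask.any():
                    continue
                group = self.control[mask]
                g = group.mean(axis=0)
                if np.linalg.norm(rot_axis) < 1e-12:
                    rot_axis = np.array([1.0, 0.0, 0.0])
                R = RigidTransform.from_axis_angle(rot_axis, angle).rotation
                moved = (group - g) @ R.T + g + trans
                self.control_disp[mask] += moved - group

    def max_control_displacement(self) -> float:
        return float(np.linalg.norm(self.control_disp, axis=1).max())

    def deform(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of control displacements; points are
        clamped into the lattice so every weight set is convex."""
        local = (points - self.center) @ self.axes.T
        u = (local - self.lo) / (self.hi - self.lo)  # in [0,1] for cloud pts
        u = np.clip(u, 0.0, 1.0)
        disp = np.zeros_like(points)
        cell = [u[:, a] * (self.res[a] - 1) for a in range(3)]
        i0 = [np.clip(np.floor(c).astype(int), 0, self.res[a] - 2) for a, c in enumerate(cell)]
        frac = [c - i for c, i in zip(cell, i0)]
        strides = (self.res[1] * self.res[2], self.res[2], 1)
        for dx in (0, 1):
            wx = frac[0] if dx else 1.0 - frac[0]
            for dy in (0, 1):
                wy = frac[1] if dy else 1.0 - frac[1]
                for dz in (0, 1):
                    wz = frac[2] if dz else 1.0 - frac[2]
                    idx = (
                        (i0[0] + dx) * strides[0]
                        + (i0[1] + dy) * strides[1]
                        + (i0[2] + dz)
                    )
                    w = (wx * wy * wz)[:, None]
                    disp += w * self.control_disp[idx]
        return points + disp @ self.axes


def simulate_nonrigid(
    t: EarModel, cfg: SimulationConfig, seed: int = 0
) -> EarModel:
    """Random per-structure shape variation via grouped FFD lattices.

    Topology (structure ids, vertex order, landmark count) is preserved;
    landmarks, support points and articulation points are deformed by the
    same field as their structure (articulation point j follows the
    downstream structure j+1).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    names = t.structure_names
    new_structures: Dict[str, PointCloud] = {}
    new_landmarks: Dict[str, np.ndarray] = {}
    new_support: Dict[str, np.ndarray] = {}
    new_artic = t.articulation_points.copy()
    for si, name in enumerate(names):
        cloud = t.structures[name]
        lattice = _FFDLattice(cloud.points, cfg.lattice_resolution)
        bounds = cfg.nonrigid_bounds.get(name, GroupBounds())
        lattice.randomize_groups(bounds, rng)
        new_pts = lattice.deform(cloud.points)
        new_structures[name] = PointCloud(
            new_pts,
            None if cloud.labels is None else cloud.labels.copy(),
            None if cloud.source_index is None else cloud.source_index.copy(),
        )
        if name in t.landmarks.landmarks:
            new_landmarks[name] = lattice.deform(t.landmarks.landmarks[name])
        new_support[name] = lattice.deform(t.support_points[name][None])[0]
        if si >= 1:
            new_artic[si - 1] = lattice.deform(t.articulation_points[si - 1][None])[0]
    return EarModel(
        structures=new_structures,
        articulation_points=new_artic,
        support_points=new_support,
        landmarks=LandmarkSet(new_landmarks),
        external_point=t.external_point.copy(),
    )


# ---------------------------------------------------------------------------
# rigid stage: forward-kinematic articulation chain
# ---------------------------------------------------------------------------


def simulate_rigid(t_nr: EarModel, cfg: SimulationConfig, seed: int = 0) -> EarModel:
    """Random articulated pose via a kinematic chain.

    Joint j sits at articulation point j (between structures j and j+1) and
    receives a random rotation about that point plus a random translation.
    Joint 0 is the chain root and moves the entire assembly (canal wall and
    membrane receive only this root motion); each deeper joint moves its
    downstream structures only, with pivots propagated through upstream
    motion (forward kinematics).
    """
    cfg.validate()
    names = t_nr.structure_names
    n_joints = len(names) - 1
    if len(t_nr.articulation_points) != n_joints:
        raise ModelError("articulation points missing for the kinematic chain")
    if len(cfg.rigid_bounds) < n_joints:
        raise ConfigError(f"need rigid bounds for {n_joints} joints")
    rng = np.random.default_rng(seed)

    cumulative = RigidTransform.identity()
    structure_tf: List[RigidTransform] = []
    for j in range(n_joints):
        b = cfg.rigid_bounds[j]
        axis = rng.normal(size=3)
        if np.linalg.norm(axis) < 1e-12:
            axis = np.array([0.0, 0.0, 1.0])
        angle = rng.uniform(-1.0, 1.0) * np.radians(b.max_rotation_deg)
        trans = rng.uniform(-1.0, 1.0, 3) * b.max_translation_mm
        pivot = cumulative.apply_to_points(t_nr.articulation_points[j][None])[0]
        motion = RigidTransform.rotation_about_point(axis, angle, pivot)
        motion = RigidTransform(motion.rotation, motion.translation + trans)
        cumulative = compose_rigid(motion, cumulative)
        if j == 0:
            structure_tf.append(cumulative)  # canal wall: root motion only
        structure_tf.append(cumulative)
    # structure_tf[k] now holds the transform for structure k
    artic_out = np.array(
        [structure_tf[j + 1].apply_to_points(t_nr.articulation_points[j][None])[0]
         for j in range(n_joints)]
    )

    new_structures: Dict[str, PointCloud] = {}
    new_landmarks: Dict[str, np.ndarray] = {}
    new_support: Dict[str, np.ndarray] = {}
    for k, name in enumerate(names):
        tf = structure_tf[k]
        cloud = t_nr.structures[name]
        new_structures[name] = PointCloud(
            tf.apply_to_points(cloud.points),
            None if cloud.labels is None else cloud.labels.copy(),
            None if cloud.source_index is None else cloud.source_index.copy(),
        )
        if name in t_nr.landmarks.landmarks:
            new_landmarks[name] = tf.apply_to_points(t_nr.landmarks.landmarks[name])
        new_support[name] = tf.apply_to_points(t_nr.support_points[name][None])[0]
    return EarModel(
        structures=new_structures,
        articulation_points=artic_out,
        support_points=new_support,
        landmarks=LandmarkSet(new_landmarks),
        external_point=structure_tf[0].apply_to_points(t_nr.external_point[None])[0],
    )


# ---------------------------------------------------------------------------
# ground truth and partial sampling
# ---------------------------------------------------------------------------


def ground_truth_field(template: EarModel, variant: EarModel) -> DisplacementField:
    """Per-vertex displacement template → variant (identical topology)."""
    a = template.all_points().points
    b = variant.all_points().points
    if a.shape != b.shape or template.structure_names != variant.structure_names:
        raise ModelError("template and variant vertex sets do not align")
    return DisplacementField(b - a)


def sample_partial(
    variant: EarModel, cfg: SimulationConfig, seed: int = 0
) -> PointCloud:
    """Extract the noisy partial "in vivo" view of a shape variant.

    Per structure, vertex i gets keep-score ``exp(-d_i/lambda) + eps_i``
    (d_i = distance to the structure's support point, eps Gaussian); the
    top-scoring vertices are kept up to a budget. The base budget is the
    model's own expected keep-count ``sum_i exp(-d_i/lambda)``, multiplied
    by an occlusion factor ``u^t`` with ``u ~ U(a, b)`` and ``t`` the
    structure's normalized depth from the external-ear reference point, so
    posterior structures are thinned more. Survivors get per-axis uniform
    jitter in [-delta, +delta]. Output carries source_index into the stacked
    variant vertex order.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    a, b = cfg.occlusion_range
    names = variant.structure_names
    centroids = {n: variant.structures[n].points.mean(axis=0) for n in names}
    depths = np.array(
        [np.linalg.norm(centroids[n] - variant.external_point) for n in names]
    )
    depth_max = max(depths.max(), 1e-12)

    slices = variant.structure_slices()
    keep_points: List[np.ndarray] = []
    keep_index: List[np.ndarray] = []
    keep_labels: List[np.ndarray] = []
    for k, name in enumerate(names):
        pts = variant.structures[name].points
        n = len(pts)
        d = np.linalg.norm(pts - variant.support_points[name], axis=1)
        decay = np.exp(-d / cfg.visibility_lambda) if np.isfinite(cfg.visibility_lambda) else np.ones(n)
        base_budget = decay.sum()
        u = rng.uniform(a, b)
        t_norm = depths[k] / depth_max
        occlusion = u ** t_norm if u > 0 else (1.0 if t_norm == 0 else 0.0)
        budget = int(round(base_budget * occlusion))
        budget = min(budget, n)
        noise = rng.normal(0.0, cfg.visibility_noise_sd, n) if cfg.visibility_noise_sd > 0 else np.zeros(n)
        score = decay + noise
        if budget <= 0:
            continue
        # threshold chosen so exactly `budget` vertices survive
        order = np.argsort(-score, kind="stable")
        sel = np.sort(order[:budget])
        keep_points.append(pts[sel])
        keep_index.append(sel + slices[name].start)
        keep_labels.append(np.full(len(sel), k))
    if not keep_points:
        raise ModelError("partial sampling retained no points (all budgets zero)")
    pts = np.vstack(keep_points)
    if cfg.jitter_delta > 0:
        pts = pts + rng.uniform(-cfg.jitter_delta, cfg.jitter_delta, pts.shape)
    return PointCloud(
        pts,
        labels=np.concatenate(keep_labels),
        source_index=np.concatenate(keep_index),
    )


# ---------------------------------------------------------------------------
# sample / dataset assembly
# ---------------------------------------------------------------------------


def generate_sample(
    cfg: SimulationConfig, seed: int = 0, template: Optional[EarModel] = None
) -> Sample:
    """Full simulation chain: template → non-rigid → rigid → partial view.

    The template is shared across samples (one ex vivo model fitted to all
    patients); the variant and its partial view depend on `seed`.
    """
    cfg.validate()
    if template is None:
        template = build_template(cfg.n_points_per_structure, cfg.template_seed)
    ss = np.random.SeedSequence(seed)
    s_nr, s_r, s_p = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    variant_nr = simulate_nonrigid(template, cfg, s_nr)
    variant = simulate_rigid(variant_nr, cfg, s_r)
    gt = ground_truth_field(template, variant)
    target = sample_partial(variant, cfg, s_p)
    variant_pts = variant.all_points()
    return Sample(
        template=template.all_points(),
        target=target,
        gt_displacement=gt,
        variant=variant_pts,
        landmarks_template=template.landmarks,
        landmarks_target=variant.landmarks,
        visible_ratio=len(target) / len(variant_pts),
        template_model=template,
        variant_model=variant,
    )


def oracle_correspondences(sample: Sample) -> CorrespondenceSet:
    """Exact (template vertex, target row) pairs from simulator bookkeeping."""
    if sample.target.source_index is None:
        raise ValueError("target cloud carries no source_index provenance")
    pairs = np.column_stack(
        [sample.target.source_index, np.arange(len(sample.target))]
    )
    return CorrespondenceSet(pairs)


def generate_dataset(
    n: int, cfg: SimulationConfig, seed: int, out_dir: Path
) -> dict:
    """Write `n` samples (per-sample seed = seed + i) plus a manifest."""
    from . import io as _io  # local import to avoid a cycle

    if n < 1:
        raise ConfigError("dataset size must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = build_template(cfg.n_points_per_structure, cfg.template_seed)
    rows = []
    for i in range(n):
        sample_seed = seed + i
        sample = generate_sample(cfg, sample_seed, template=template)
        sdir = out_dir / f"sample_{i:04d}"
        _io.write_sample(sample, sdir)
        rows.append(
            {
                "sample": sdir.name,
                "seed": sample_seed,
                "visible_ratio": sample.visible_ratio,
                "mean_gt_displacement_mm": sample.gt_displacement.mean_norm(),
            }
        )
    manifest = {"n": n, "seed": seed, "samples": rows}
    _io.write_json(manifest, out_dir / "manifest.json")
    return manifest
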