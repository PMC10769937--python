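"""Evaluation metrics: Chamfer distance, mean displacement error (MDE),
per-structure landmark error, and the visible-points ratio.

Chamfer distance uses non-squared Euclidean norms: symmetric mean
nearest-neighbour distance between two sets. MDE is the mean norm of the
difference between estimated and ground-truth displacement fields; at
dataset level, per-sample MDEs are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DisplacementField, PointCloud
from .synthetic import LandmarkSet, Sample

if TYPE_CHECKING:  # pragma: no cover
    from .pyramid import RegistrationResult


@dataclass
class MetricReport:
    """All per-sample evaluation numbers (mm except the ratio)."""

    mde: float
    chamfer: float
    landmark_error: float
    visible_ratio: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name in ("mde", "chamfer", "landmark_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.visible_ratio <= 1.0):
            raise ValueError("visible_ratio must lie in [0, 1]")


def chamfer_distance(a: PointCloud, b: PointCloud) -> float:
    """CD(A,B) = mean_x min_y |x-y| + mean_y min_x |x-y|  (mm)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Chamfer distance needs two non-empty clouds")
    d_ab, _ = cKDTree(b.points).query(a.points, k=1)
    d_ba, _ = cKDTree(a.points).query(b.points, k=1)
    return float(d_ab.mean() + d_ba.mean())


def mde(est: DisplacementField, gt: DisplacementField) -> float:
    """Mean Euclidean norm of (est - gt) over points (mm)."""
    if len(est) != len(gt):
        raise ValueError("displacement fields differ in length")
    return float(np.linalg.norm(est.vectors - gt.vectors, axis=1).mean())


def landmark_error(l_exv: LandmarkSet, l_inv: LandmarkSet) -> float:
    """Mean over ex vivo landmarks of the distance to the nearest in vivo
    landmark of the same structure; structures absent from either side are
    skipped (with a warning)."""
    shared = [k for k in l_exv.landmarks if k in l_inv.landmarks]
    if not shared:
        raise ValueError("landmark sets share no structures")
    skipped = (set(l_exv.landmarks) | set(l_inv.landmarks)) - set(shared)
    if skipped:
        warnings.warn(f"landmark structures skipped: {sorted(skipped)}", stacklevel=2)
    dists = []
    for k in shared:
        src = l_exv.landmarks[k]
        dst = l_inv.landmarks[k]
        d = np.linalg.norm(src[:, None, :] - dst[None, :, :], axis=2).min(axis=1)
        dists.append(d)
    return float(np.concatenate(dists).mean())


def visible_ratio(target: PointCloud, variant: PointCloud) -> float:
    """|target| / |variant| — fraction of the shape variant that is seen."""
    if len(variant) < 1:
        raise ValueError("variant cloud is empty")
    return len(target) / len(variant)


def displace_landmarks(
    landmarks: LandmarkSet, cloud: PointCloud, phi: DisplacementField
) -> LandmarkSet:
    """Move landmarks with a displacement field defined on `cloud` by
    nearest-vertex lookup (exact when landmarks are cloud vertices)."""
    tree = cKDTree(cloud.points)
    moved = {}
    for k, pts in landmarks.landmarks.items():
        _, idx = tree.query(pts, k=1)
        moved[k] = pts + phi.vectors[idx]
    return LandmarkSet(moved)


def evaluate_sample(
    result: "RegistrationResult", sample: Sample, sample_id: str = ""
) -> MetricReport:
    """Score one registration against its simulated ground truth.

    Chamfer is measured between the full deformed template and the target
    (unmasked), so over-compression of unseen geometry is penalized.
    """
    phi = result.displacement
    if len(phi) != len(sample.template):
        raise ValueError("result field is not aligned with the sample template")
    deformed = PointCloud(sample.template.points + phi.vectors)
    moved_lm = displace_landmarks(sample.landmarks_template, sample.template, phi)
    return MetricReport(
        mde=mde(phi, sample.gt_displacement),
        chamfer=chamfer_distance(deformed, sample.target),
        landmark_error=landmark_error(moved_lm, sample.landmarks_target),
        visible_ratio=sample.visible_ratio,
        sample_id=sample_id,
    )
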