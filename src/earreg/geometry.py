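"""Fundamental point-cloud types and rigid-body (SE(3)) algebra.

All coordinates are millimetres, dimension-ordered (x, y, z), right-handed.
Rotations are stored as proper orthonormal 3x3 matrices so group invariants
(orthonormality, det = +1) are directly checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateFitError, InvalidTransformError

_ORTHO_TOL = 1e-9


@dataclass
class PointCloud:
    """N x 3 coordinates (mm) with optional per-point metadata.

    Parameters
    ----------
    points
        Array of shape (N, 3); all coordinates finite, N >= 1.
    labels
        Optional integer structure identifier per point.
    source_index
        Optional per-point index into an originating cloud (provenance for
        partial samples extracted from a complete shape variant).
    """

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    source_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if len(self.points) < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.points),):
                raise ValueError("labels length must equal point count")
        if self.source_index is not None:
            self.source_index = np.asarray(self.source_index, dtype=np.int64)
            if self.source_index.shape != (len(self.points),):
                raise ValueError("source_index length must equal point count")
            if np.any(self.source_index < 0):
                raise ValueError("source_index values must be non-negative")

    def __len__(self) -> int:
        return len(self.points)

    def bounding_box_diagonal(self) -> float:
        extent = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(extent))

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.points.copy(),
            None if self.labels is None else self.labels.copy(),
            None if self.source_index is None else self.source_index.copy(),
        )


@dataclass
class RigidTransform:
    """Element of SE(3): proper rotation plus translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        _check_rotation(self.rotation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_axis_angle(
        axis: Sequence[float], angle_rad: float, translation: Sequence[float] = (0, 0, 0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=np.float64)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("rotation axis must be non-zero")
        axis = axis / n
        K = np.array(
            [
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ]
        )
        R = np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)
        return RigidTransform(R, np.asarray(translation, dtype=np.float64))

    @staticmethod
    def rotation_about_point(
        axis: Sequence[float], angle_rad: float, center: Sequence[float]
    ) -> "RigidTransform":
        """Rotation about an arbitrary pivot point."""
        c = np.asarray(center, dtype=np.float64)
        t = RigidTransform.from_axis_angle(axis, angle_rad)
        return RigidTransform(t.rotation, c - t.rotation @ c)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return RigidTransform(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class CorrespondenceSet:
    """Sparse (source index u, target index v) pairs linking two clouds."""

    pairs: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError(f"pairs must be (K, 2), got {self.pairs.shape}")
        if len(self.pairs) != len(np.unique(self.pairs, axis=0)):
            raise ValueError("duplicate (u, v) correspondence pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def source_indices(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def target_indices(self) -> np.ndarray:
        return self.pairs[:, 1]

    def validate_against(self, n_source: int, n_target: int) -> None:
        if len(self.pairs) and (
            self.pairs[:, 0].max() >= n_source or self.pairs[:, 1].max() >= n_target
        ):
            raise ValueError("correspondence index out of range")
        if len(self.pairs) and self.pairs.min() < 0:
            raise ValueError("negative correspondence index")


@dataclass
class DisplacementField:
    """Per-source-point 3-D motion vectors (mm), index-aligned with a cloud."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError(f"vectors must be (N, 3), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite components")

    def __len__(self) -> int:
        return len(self.vectors)

    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def mean_norm(self) -> float:
        return float(self.norms().mean())


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    if R.shape != (3, 3):
        raise InvalidTransformError(f"rotation must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise InvalidTransformError("rotation contains non-finite entries")
    if np.max(np.abs(R.T @ R - np.eye(3))) > max(tol, 1e-9):
        raise InvalidTransformError("rotation is not orthonormal within 1e-9")
    if abs(np.linalg.det(R) - 1.0) > max(tol, 1e-9):
        raise InvalidTransformError("rotation determinant differs from +1")


def apply_rigid(t: RigidTransform, p: PointCloud) -> PointCloud:
    """Apply ``x -> R x + t`` to every point; metadata carried through."""
    _check_rotation(t.rotation)
    return PointCloud(
        t.apply_to_points(p.points),
        None if p.labels is None else p.labels.copy(),
        None if p.source_index is None else p.source_index.copy(),
    )


def compose_rigid(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition a∘b: applying the result equals applying b, then a."""
    _check_rotation(a.rotation)
    _check_rotation(b.rotation)
    R = a.rotation @ b.rotation
    # re-orthonormalize to keep long chains within the 1e-9 invariant
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:
        R = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return RigidTransform(R, a.rotation @ b.translation + a.translation)


def fit_rigid(
    src: PointCloud, dst: PointCloud, pairs: CorrespondenceSet
) -> RigidTransform:
    """Least-squares rigid alignment of matched points (Kabsch / orthogonal
    Procrustes).

    Minimizes ``sum_k || R src[u_k] + t - dst[v_k] ||^2`` in closed form via
    SVD of the cross-covariance; the returned transform is the global optimum
    of that objective.

    Raises
    ------
    DegenerateFitError
        Fewer than 3 pairs, or the matched source points are (near-)collinear
        so the rotation is not uniquely determined.
    """
    pairs.validate_against(len(src), len(dst))
    if len(pairs) < 3:
        raise DegenerateFitError("need at least 3 correspondence pairs")
    a = src.points[pairs.source_indices]
    b = dst.points[pairs.target_indices]
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    # collinearity check: a well-posed rotation needs >= 2 significant axes
    s_src = np.linalg.svd(a0, compute_uv=False)
    if s_src[1] <= 1e-9 * max(s_src[0], 1.0):
        raise DegenerateFitError("matched source points are collinear/degenerate")
    H = a0.T @ b0
    u, _, vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    R = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # polish orthonormality to the 1e-9 invariant
    uu, _, vvt = np.linalg.svd(R)
    R = uu @ vvt
    if np.linalg.det(R) < 0:
        R = uu @ np.diag([1.0, 1.0, -1.0]) @ vvt
    return RigidTransform(R, cb - R @ ca)
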