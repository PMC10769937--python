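"""Stage 1: initial rigid alignment and sparse correspondences.

The learned correspondence network of the original pipeline is replaced by
pluggable backends that honour the same contract — return a rigid transform
tau aligning the complete source toward the partial target, plus a sparse
correspondence set sigma of (source index, target index) pairs consistent
with tau:

- ``oracle``: exact pairs from simulator provenance (source_index), used to
  isolate stage-2 behaviour from stage-1 quality;
- ``descriptor``: a classical feature pipeline — voxel downsampling, local
  PCA normals, fast-point-feature-histogram (FPFH) descriptors, mutual
  nearest-neighbour matching and seeded RANSAC rigid estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, DegenerateFitError, RegistrationFailureError
from .geometry import (
    CorrespondenceSet,
    PointCloud,
    RigidTransform,
    fit_rigid,
)


@dataclass
class StageOneResult:
    transform: RigidTransform
    correspondences: CorrespondenceSet
    inlier_rmse: float
    backend_name: str

    def __post_init__(self) -> None:
        if len(self.correspondences) == 0:
            raise RegistrationFailureError("stage-1 produced no correspondences")
        if self.inlier_rmse < 0:
            raise ValueError("inlier_rmse must be >= 0")


@dataclass
class DescriptorParams:
    """Tunables of the classical descriptor backend."""

    voxel_size: float = 0.3  # mm
    normal_k: int = 20
    feature_radius: float = 1.2  # mm, SPFH neighbourhood
    ransac_iterations: int = 50_000
    inlier_threshold: float = 0.5  # mm
    min_nodes: int = 10
    seed: int = 0


def estimate(
    source: PointCloud,
    target: PointCloud,
    backend: str = "descriptor",
    params: Optional[DescriptorParams] = None,
) -> StageOneResult:
    """Dispatch to the named stage-1 backend."""
    if len(source) < 3 or len(target) < 3:
        raise ValueError("stage 1 needs >= 3 points in each cloud")
    if backend == "oracle":
        return backend_oracle(source, target)
    if backend == "descriptor":
        return backend_descriptor(source, target, params)
    raise ConfigError(f"unknown stage-1 backend {backend!r}")


def backend_oracle(source: PointCloud, target: PointCloud) -> StageOneResult:
    """Exact correspondences from simulator bookkeeping.

    Requires the target to carry ``source_index`` provenance into a variant
    whose vertex order matches the source template. sigma contains every
    target point; tau is the least-squares rigid fit over sigma.
    """
    if target.source_index is None:
        raise ValueError("oracle backend needs target.source_index provenance")
    pairs = CorrespondenceSet(
        np.column_stack([target.source_index, np.arange(len(target))])
    )
    tau = fit_rigid(source, target, pairs)
    res = tau.apply_to_points(source.points[pairs.source_indices]) - target.points[
        pairs.target_indices
    ]
    rmse = float(np.sqrt((res**2).sum(axis=1).mean()))
    return StageOneResult(tau, pairs, rmse, "oracle")


# ---------------------------------------------------------------------------
# descriptor backend
# ---------------------------------------------------------------------------


def _voxel_downsample(points: np.ndarray, voxel: float):
    """Voxel-grid downsampling; returns (node coords, index of the original
    point nearest each node)."""
    keys = np.floor(points / voxel).astype(np.int64)
    _, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    n_vox = len(counts)
    centroids = np.zeros((n_vox, 3))
    np.add.at(centroids, inverse, points)
    centroids /= counts[:, None]
    _, nearest = cKDTree(points).query(centroids, k=1)
    order = np.argsort(nearest, kind="stable")  # deterministic node order
    return centroids[order], nearest[order]


def _estimate_normals(points: np.ndarray, k: int) -> np.ndarray:
    """Local-PCA normals, oriented away from the cloud centroid."""
    k = min(k, len(points))
    _, idx = cKDTree(points).query(points, k=k)
    neigh = points[idx]  # (n, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest-eigenvalue direction
    outward = points - points.mean(axis=0)
    flip = np.einsum("ni,ni->n", normals, outward) < 0
    normals[flip] = -normals[flip]
    return normals


def _spfh(points: np.ndarray, normals: np.ndarray, radius: float, bins: int = 11):
    """Simplified point feature histograms (alpha, phi, theta), plus the
    neighbour lists used for the FPFH weighting step."""
    tree = cKDTree(points)
    neighbor_lists = tree.query_ball_point(points, r=radius)
    n = len(points)
    hist = np.zeros((n, 3 * bins))
    for i in range(n):
        nb = [j for j in neighbor_lists[i] if j != i]
        if not nb:
            continue
        p, np_i = points[i], normals[i]
        q = points[nb]
        d = q - p
        dist = np.linalg.norm(d, axis=1)
        ok = dist > 1e-12
        if not ok.any():
            continue
        d, dist, nq = d[ok], dist[ok], normals[np.asarray(nb)[ok]]
        dn = d / dist[:, None]
        u = np_i
        v = np.cross(dn, np.broadcast_to(u, dn.shape))
        vnorm = np.linalg.norm(v, axis=1, keepdims=True)
        vnorm[vnorm < 1e-12] = 1.0
        v /= vnorm
        w = np.cross(np.broadcast_to(u, v.shape), v)
        alpha = np.einsum("ki,ki->k", v, nq)  # [-1, 1]
        phi = dn @ u  # [-1, 1]
        theta = np.arctan2(np.einsum("ki,ki->k", w, nq), nq @ u)  # [-pi, pi]
        for f, lo, hi, off in (
            (alpha, -1.0, 1.0, 0),
            (phi, -1.0, 1.0, bins),
            (theta, -np.pi, np.pi, 2 * bins),
        ):
            b = np.clip(((f - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
            np.add.at(hist[i], b + off, 1.0)
        s = hist[i].sum()
        if s > 0:
            hist[i] /= s
    return hist, neighbor_lists


def _fpfh(points: np.ndarray, normals: np.ndarray, radius: float) -> np.ndarray:
    spfh, neighbor_lists = _spfh(points, normals, radius)
    n = len(points)
    fpfh = spfh.copy()
    for i in range(n):
        nb = [j for j in neighbor_lists[i] if j != i]
        if not nb:
            continue
        d = np.linalg.norm(points[nb] - points[i], axis=1)
        w = 1.0 / np.maximum(d, 1e-6)
        fpfh[i] = spfh[i] + (w[:, None] * spfh[nb]).sum(axis=0) / len(nb)
        s = fpfh[i].sum()
        if s > 0:
            fpfh[i] /= s
    return fpfh


def _kabsch(a: np.ndarray, b: np.ndarray):
    """Batched closed-form rigid fit of 3-point sets a->b: (B,3,3),(B,3,3)."""
    ca = a.mean(axis=1, keepdims=True)
    cb = b.mean(axis=1, keepdims=True)
    H = np.einsum("bki,bkj->bij", a - ca, b - cb)
    u, _, vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("bij,bjk->bik", np.swapaxes(vt, 1, 2), np.swapaxes(u, 1, 2))))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("bij,bjk,bkl->bil", np.swapaxes(vt, 1, 2), D, np.swapaxes(u, 1, 2))
    t = cb[:, 0, :] - np.einsum("bij,bj->bi", R, ca[:, 0, :])
    return R, t


def backend_descriptor(
    source: PointCloud,
    target: PointCloud,
    params: Optional[DescriptorParams] = None,
) -> StageOneResult:
    """Classical global registration: FPFH + mutual matching + RANSAC.

    Deterministic for a fixed ``params.seed``. sigma is returned in the
    original index space (each downsampled node mapped to its nearest
    original point), restricted to RANSAC inliers under the refined tau.
    """
    p = params or DescriptorParams()
    src_nodes, src_map = _voxel_downsample(source.points, p.voxel_size)
    dst_nodes, dst_map = _voxel_downsample(target.points, p.voxel_size)
    if len(src_nodes) < p.min_nodes or len(dst_nodes) < p.min_nodes:
        raise DegenerateFitError("too few downsampled nodes for descriptors")

    f_src = _fpfh(src_nodes, _estimate_normals(src_nodes, p.normal_k), p.feature_radius)
    f_dst = _fpfh(dst_nodes, _estimate_normals(dst_nodes, p.normal_k), p.feature_radius)

    # mutual nearest neighbours in descriptor space
    _, fwd = cKDTree(f_dst).query(f_src, k=1)
    _, bwd = cKDTree(f_src).query(f_dst, k=1)
    mutual = bwd[fwd] == np.arange(len(f_src))
    cand_src = np.nonzero(mutual)[0]
    cand_dst = fwd[mutual]
    if len(cand_src) < 3:
        raise RegistrationFailureError("too few mutual descriptor matches")

    a_all = src_nodes[cand_src]
    b_all = dst_nodes[cand_dst]
    rng = np.random.default_rng(p.seed)
    n_cand = len(cand_src)
    # RANSAC: keep the best few hypotheses per chunk by match-inlier count,
    # then re-score them by target-node coverage. Near-symmetric anatomy
    # (tube + disc) yields wrong-rotation consensus sets with many match
    # inliers; coverage of the asymmetric ossicles disambiguates.
    candidates: list = []
    chunk = 2048
    remaining = p.ransac_iterations
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        sel = rng.integers(0, n_cand, size=(m, 3))
        ok = (sel[:, 0] != sel[:, 1]) & (sel[:, 0] != sel[:, 2]) & (sel[:, 1] != sel[:, 2])
        sel = sel[ok]
        if not len(sel):
            continue
        R, t = _kabsch(a_all[sel], b_all[sel])
        moved = np.einsum("bij,kj->bki", R, a_all) + t[:, None, :]
        res2 = ((moved - b_all[None]) ** 2).sum(axis=2)
        counts = (res2 <= p.inlier_threshold**2).sum(axis=1)
        top = np.argsort(counts)[-3:]
        for bi in top:
            if counts[bi] >= 3:
                candidates.append((int(counts[bi]), R[bi], t[bi]))
    if not candidates:
        raise RegistrationFailureError("RANSAC found no usable inlier set")
    candidates.sort(key=lambda c: -c[0])
    src_tree = cKDTree(src_nodes)

    def _icp_polish(R, t, iters):
        for _ in range(iters):
            moved_dst_frame = (dst_nodes - t) @ R  # inverse-transform targets
            d, j = src_tree.query(moved_dst_frame, k=1)
            keep = d <= p.inlier_threshold
            if keep.sum() < 3:
                break
            Rb, tb = _kabsch(src_nodes[j[keep]][None], dst_nodes[keep][None])
            R, t = Rb[0], tb[0]
        return R, t

    # polish each leading hypothesis into its local basin, then pick the one
    # explaining the most target nodes
    best_cov = -np.inf
    best_R, best_t = np.eye(3), np.zeros(3)
    for _, R, t in candidates[:100]:
        R, t = _icp_polish(R, t, 5)
        d, _ = src_tree.query((dst_nodes - t) @ R, k=1)
        # coverage with a residual-tightness tiebreak: near-symmetric aliases
        # reach similar coverage but larger residuals
        cov = float((d <= p.inlier_threshold).mean()) - 0.2 * float(
            np.minimum(d, p.inlier_threshold).mean()
        ) / p.inlier_threshold
        if cov > best_cov:
            best_cov = cov
            best_R, best_t = R, t

    # iterative refinement on the inlier set
    R, t = best_R, best_t
    for _ in range(3):
        res = a_all @ R.T + t - b_all
        inl = (res**2).sum(axis=1) <= p.inlier_threshold**2
        if inl.sum() < 3:
            break
        Rb, tb = _kabsch(a_all[inl][None], b_all[inl][None])
        R, t = Rb[0], tb[0]
    # final trimmed-ICP polish on the downsampled nodes
    R, t = _icp_polish(R, t, 10)
    # orthonormality polish
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:
        R = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    tau = RigidTransform(R, t)

    res = a_all @ R.T + t - b_all
    res_norm2 = (res**2).sum(axis=1)
    inl = res_norm2 <= p.inlier_threshold**2
    if inl.sum() < 1:
        raise RegistrationFailureError("no inliers after refinement")
    pairs = np.column_stack([src_map[cand_src[inl]], dst_map[cand_dst[inl]]])
    pairs = np.unique(pairs, axis=0)
    sigma = CorrespondenceSet(pairs)
    rmse = float(np.sqrt(res_norm2[inl].mean()))
    return StageOneResult(tau, sigma, rmse, "descriptor")
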