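"""Stage 2: hierarchical non-rigid registration (neural deformation pyramid).

The total motion is decomposed into per-level sub-motions. At level k the
current point set is mapped to sinusoidal encodings
``Gamma(p) = (sin(2^(k+k0) p), cos(2^(k+k0) p))`` and a small multilayer
regressor maps encodings to per-point 3-D increments, optimized per instance
by Adam against the sigma-masked Chamfer loss plus an increment-norm
regularizer. Low frequencies at shallow levels yield near-rigid sub-motions;
deeper levels refine non-rigid detail.

All optimization runs on coordinates normalized to a unit bounding box so
the frequency ladder transfers across specimen sizes; displacement fields
are returned in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import NumericalFailureError
from .geometry import (
    CorrespondenceSet,
    DisplacementField,
    PointCloud,
    RigidTransform,
    apply_rigid,
)
from .metrics import chamfer_distance
from . import correspondence as stage1


@dataclass
class PyramidConfig:
    n_levels: int = 11
    max_iters_per_level: int = 100
    k0: int = -8
    regressor_width: int = 64
    regressor_depth: int = 3
    step_size: float = 1e-3
    stop_tol: float = 1e-5
    patience: int = 10
    reg_weight: float = 0.5
    sigma_weight: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_levels < 1 or self.max_iters_per_level < 1:
            raise ValueError("n_levels and max_iters_per_level must be >= 1")
        if self.regressor_depth < 1 or self.regressor_width < 1:
            raise ValueError("regressor size must be >= 1")
        if self.stop_tol <= 0 or self.step_size <= 0:
            raise ValueError("stop_tol and step_size must be > 0")
        if self.reg_weight < 0 or self.sigma_weight < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class LevelDiagnostics:
    iterations: int
    loss_correspondence: List[float]
    loss_regularization: List[float]
    loss_total: List[float]  # running best (accepted) total loss
    increment_mean_norm_mm: float


@dataclass
class PyramidDiagnostics:
    levels: List[LevelDiagnostics] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "levels": [
                {
                    "iterations": lv.iterations,
                    "loss_correspondence": lv.loss_correspondence,
                    "loss_regularization": lv.loss_regularization,
                    "loss_total": lv.loss_total,
                    "increment_mean_norm_mm": lv.increment_mean_norm_mm,
                }
                for lv in self.levels
            ]
        }


@dataclass
class RegistrationResult:
    """End-to-end output: rigid init, sparse correspondences, displacement
    field in the original source frame, and per-level diagnostics."""

    transform: RigidTransform
    correspondences: CorrespondenceSet
    displacement: DisplacementField
    diagnostics: PyramidDiagnostics
    stage1: Optional[stage1.StageOneResult] = None


def sinusoidal_encode(points: PointCloud, k: int, k0: int) -> np.ndarray:
    """Per-point 6-vector: component-wise sin then cos of 2^(k+k0) * xyz."""
    if k < 0:
        raise ValueError("level index k must be >= 0")
    f = 2.0 ** (k + k0)
    scaled = f * points.points
    return np.concatenate([np.sin(scaled), np.cos(scaled)], axis=1)


def correspondence_loss(
    deformed_source: PointCloud, target: PointCloud, sigma: CorrespondenceSet
) -> float:
    """Chamfer distance between the sigma-masked deformed source and the
    full target (mm)."""
    if len(sigma) == 0:
        raise ValueError("correspondence set is empty")
    sigma.validate_against(len(deformed_source), len(target))
    mask = np.unique(sigma.source_indices)
    masked = PointCloud(deformed_source.points[mask])
    return chamfer_distance(masked, target)


# ---------------------------------------------------------------------------
# tiny numpy MLP + Adam
# ---------------------------------------------------------------------------


class _MLP:
    """Fully connected ReLU network, zero-initialized output layer so the
    initial increment field is exactly zero."""

    def __init__(self, in_dim: int, width: int, depth: int, rng: np.random.Generator):
        dims = [in_dim] + [width] * depth + [3]
        self.W = []
        self.b = []
        for i in range(len(dims) - 1):
            if i == len(dims) - 2:
                w = np.zeros((dims[i], dims[i + 1]))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
            self.W.append(w)
            self.b.append(np.zeros(dims[i + 1]))

    def forward(self, x: np.ndarray):
        acts = [x]
        h = x
        for i in range(len(self.W) - 1):
            h = np.maximum(h @ self.W[i] + self.b[i], 0.0)
            acts.append(h)
        out = h @ self.W[-1] + self.b[-1]
        return out, acts

    def backward(self, acts, dout):
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = dout
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            if i > 0:
                g = (g @ self.W[i].T) * (acts[i] > 0)
        return gW, gb

    def params(self):
        return self.W + self.b

    def set_params(self, flat):
        n = len(self.W)
        self.W = [p.copy() for p in flat[:n]]
        self.b = [p.copy() for p in flat[n:]]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _chamfer_loss_and_grad(x_masked: np.ndarray, target: np.ndarray):
    """Masked-Chamfer value and gradient w.r.t. the masked points, with
    nearest-neighbour assignments held fixed (exact at the current iterate)."""
    P, M = len(x_masked), len(target)
    tree_t = cKDTree(target)
    d_ab, j_ab = tree_t.query(x_masked, k=1)
    tree_s = cKDTree(x_masked)
    d_ba, i_ba = tree_s.query(target, k=1)
    loss = d_ab.mean() + d_ba.mean()
    grad = np.zeros_like(x_masked)
    nz = d_ab > 1e-12
    grad[nz] += (x_masked[nz] - target[j_ab[nz]]) / (d_ab[nz, None] * P)
    nz2 = d_ba > 1e-12
    diff = x_masked[i_ba[nz2]] - target[nz2]
    contrib = diff / (d_ba[nz2, None] * M)
    np.add.at(grad, i_ba[nz2], contrib)
    return loss, grad


def ndp_register(
    source: PointCloud,
    target: PointCloud,
    sigma: CorrespondenceSet,
    cfg: Optional[PyramidConfig] = None,
):
    """Per-instance pyramid optimization.

    The source must already be rigidly pre-aligned to the target (the
    caller applies tau first). Returns the displacement field (mm, aligned
    with `source` rows) and per-level diagnostics. Deterministic for a
    fixed ``cfg.seed``.
    """
    cfg = cfg or PyramidConfig()
    cfg.validate()
    if len(sigma) == 0:
        raise ValueError("sigma must be non-empty")
    sigma.validate_against(len(source), len(target))

    # normalize both clouds to the joint unit bounding box
    both = np.vstack([source.points, target.points])
    lo, hi = both.min(axis=0), both.max(axis=0)
    center = (lo + hi) / 2.0
    scale = max(float((hi - lo).max()), 1e-9)
    src_n = (source.points - center) / scale
    dst_n = (target.points - center) / scale
    mask = np.unique(sigma.source_indices)
    u_idx = sigma.source_indices
    v_idx = sigma.target_indices
    n_pairs = len(sigma)
    w_sig = cfg.sigma_weight

    master = np.random.default_rng(cfg.seed)
    level_seeds = master.integers(0, 2**31, size=cfg.n_levels)

    p_cur = src_n.copy()
    diagnostics = PyramidDiagnostics()
    n_all = len(p_cur)
    for level in range(1, cfg.n_levels + 1):
        gamma = cfg.reg_weight * 0.5 ** (level - 1)
        enc = np.concatenate(
            [
                np.sin(2.0 ** (level + cfg.k0) * p_cur),
                np.cos(2.0 ** (level + cfg.k0) * p_cur),
            ],
            axis=1,
        )
        rng = np.random.default_rng(int(level_seeds[level - 1]))
        mlp = _MLP(6, cfg.regressor_width, cfg.regressor_depth, rng)
        opt = _Adam(mlp.params(), cfg.step_size)

        best_loss = np.inf
        best_params = [p.copy() for p in mlp.params()]
        traj_corr: List[float] = []
        traj_reg: List[float] = []
        traj_total: List[float] = []
        best_history: List[float] = []
        iters = 0
        for it in range(cfg.max_iters_per_level):
            iters += 1
            incr, acts = mlp.forward(enc)
            x = p_cur + incr
            l_cd, g_x = _chamfer_loss_and_grad(x[mask], dst_n)
            # point-to-point anchor over the sigma pairs: constrains the
            # tangential motion that Chamfer alone cannot see
            pair_diff = x[u_idx] - dst_n[v_idx]
            l_sig = w_sig * float((pair_diff**2).sum()) / n_pairs
            l_corr = l_cd + l_sig
            l_reg = gamma * float((incr**2).sum()) / n_all
            total = l_corr + l_reg
            if not np.isfinite(total):
                raise NumericalFailureError(
                    f"non-finite loss at level {level}, iteration {it}"
                )
            if total < best_loss:
                best_loss = total
                best_params = [p.copy() for p in mlp.params()]
            traj_corr.append(l_corr)
            traj_reg.append(l_reg)
            traj_total.append(best_loss)
            best_history.append(best_loss)
            # windowed early stop: relative improvement of the best loss over
            # the last `patience` iterations fell below stop_tol
            if it >= cfg.patience:
                ref = best_history[-cfg.patience - 1]
                if (ref - best_loss) / max(ref, 1e-30) < cfg.stop_tol:
                    break
            # gradient of total loss w.r.t. increments
            d_incr = np.zeros_like(incr)
            d_incr[mask] = g_x
            np.add.at(d_incr, u_idx, 2.0 * w_sig * pair_diff / n_pairs)
            d_incr += 2.0 * gamma * incr / n_all
            gW, gb = mlp.backward(acts, d_incr)
            opt.step(mlp.params(), gW + gb)
        mlp.set_params(best_params)
        incr, _ = mlp.forward(enc)
        p_cur = p_cur + incr
        diagnostics.levels.append(
            LevelDiagnostics(
                iterations=iters,
                loss_correspondence=traj_corr,
                loss_regularization=traj_reg,
                loss_total=traj_total,
                increment_mean_norm_mm=float(
                    np.linalg.norm(incr, axis=1).mean() * scale
                ),
            )
        )
    phi = DisplacementField((p_cur - src_n) * scale)
    return phi, diagnostics


def register_c2p(
    source: PointCloud,
    target: PointCloud,
    stage1_backend: str = "descriptor",
    cfg: Optional[PyramidConfig] = None,
    stage1_params: Optional[stage1.DescriptorParams] = None,
) -> RegistrationResult:
    """Full two-stage pipeline: rigid init + correspondences, then pyramid
    refinement. The returned displacement field is expressed in the
    ORIGINAL source frame: ``phi(x) = tau(x) + phi_ndp(tau(x)) - x``."""
    s1 = stage1.estimate(source, target, stage1_backend, stage1_params)
    aligned = apply_rigid(s1.transform, source)
    phi_ndp, diag = ndp_register(aligned, target, s1.correspondences, cfg)
    total = aligned.points + phi_ndp.vectors - source.points
    return RegistrationResult(
        transform=s1.transform,
        correspondences=s1.correspondences,
        displacement=DisplacementField(total),
        diagnostics=diag,
        stage1=s1,
    )
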