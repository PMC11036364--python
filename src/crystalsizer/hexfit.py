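"""Gradient-descent fitting of the hexagon template to binary masks.

The fit minimises a composite loss over a candidate template's free
parameters (centre, first normal angle, six distances; the relative angles
stay frozen at their crystallographic values):

* mean squared pixel difference between the soft-rendered candidate mask
  and the binary target,
* the sum of the six distances (minimal-bounding pressure),
* the sum of squared within-pair distance differences (symmetry pressure),
* a temporal anchor to the previous frame's distances (smoothness along a
  sequence).

Gradients of the soft rendering are analytic (the render is a product of
logistic half-plane factors, so the chain rule is short) and parameters are
updated with Adam under a decay-on-plateau learning-rate schedule.  A batch
of initial candidates with different orientations is optimised jointly for a
prescreen stage; the best few are then refined to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import CrystalAngles, HexTemplate, half_turn, recenter
from .segmentation import SegmentationError, mask_centroid, segment

__all__ = [
    "FitConfig",
    "FrameFit",
    "SequenceResult",
    "DivergenceError",
    "init_candidates",
    "loss",
    "loss_grad",
    "fit_frame",
    "fit_sequence",
    "template_errors",
]


def template_errors(
    fitted: HexTemplate, truth: HexTemplate
) -> tuple[np.ndarray, float]:
    """Gauge-fixed parameter errors of a fit against a ground truth.

    The template parametrisation has two exact symmetries that must be
    quotiented out before parameters are comparable: a half-turn of theta1
    (which swaps the +/- distances) and the free choice of centre (the six
    face lines are unchanged when the centre moves and the distances
    re-shift accordingly).  Returns ``(|dists_err| (3, 2) in px,
    |theta1_err| in degrees)`` with the fit expressed in the truth's gauge.
    """
    f = fitted
    dth = (f.theta1 - truth.theta1) % 360.0
    if 90.0 < dth < 270.0:
        f = half_turn(f)
    f = recenter(f, truth.center)
    theta_err = abs((f.theta1 - truth.theta1 + 180.0) % 360.0 - 180.0)
    return np.abs(f.dists - truth.dists), float(theta_err)


class DivergenceError(RuntimeError):
    """Raised when a candidate's loss becomes non-finite."""


@dataclass
class FitConfig:
    """Optimisation knobs; defaults recover noiseless targets to sub-pixel.

    ``weights`` is (w_mse, w_sumdist, w_sym, w_temporal); the regularizer
    weights are small so they perturb noiseless recovery well below a pixel
    while still breaking ties.  ``sharpness`` (1/px) sets the softness of
    the differentiable rendering used during optimisation.
    """

    n_candidates: int = 12
    sharpness: float = 1.5
    weights: tuple[float, float, float, float] = (1.0, 1e-6, 1e-6, 1e-5)
    lr0: float = 0.5
    lr_decay: float = 0.5
    plateau_patience: int = 20
    tol: float = 1e-4
    max_iters: int = 600
    seed: int = 0
    # prescreen: iterations all candidates run before only the best
    # refine_top continue to convergence
    prescreen_iters: int = 80
    refine_top: int = 2
    plateaus_to_converge: int = 4
    crop_margin: int = 24
    # pixel stride used during the prescreen stage only (ranking is robust
    # to coarse sampling; the refine stage always runs at full resolution)
    prescreen_stride: int = 3

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("loss weights must be >= 0")
        if not 0.0 < self.lr_decay < 1.0:
            raise ValueError("lr_decay must lie in (0, 1)")
        if self.n_candidates < 1:
            raise ValueError("need at least one candidate")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be positive")


@dataclass
class FrameFit:
    """Result of fitting one frame."""

    template: HexTemplate
    loss_terms: dict
    converged: bool
    iterations: int
    candidate_index: int = 0
    #: best total loss at each plateau checkpoint (non-increasing)
    loss_history: list = field(default_factory=list)


@dataclass
class SequenceResult:
    """Per-frame fits in input order; ``failed_at`` is the index of the
    first frame whose processing raised, or None."""

    fits: list
    times: np.ndarray
    failed_at: int | None = None
    error: str | None = None


# ---------------------------------------------------------------------------
# parameter packing: p = [cx, cy, theta1_deg, d1+, d1-, d2+, d2-, d3+, d3-]

_N_PARAMS = 9


def _pack(t: HexTemplate) -> np.ndarray:
    return np.concatenate([t.center, [t.theta1], t.dists.reshape(6)])


def _unpack(p: np.ndarray, rel_angles: tuple[float, float]) -> HexTemplate:
    return HexTemplate(
        center=p[:2].copy(),
        theta1=float(p[2]),
        dists=np.clip(p[3:9], 0.0, None).reshape(3, 2),
        rel_angles=rel_angles,
    )


def _batched_loss_grad(
    P: np.ndarray,
    rel_angles: tuple[float, float],
    xs: np.ndarray,
    ys: np.ndarray,
    tvals: np.ndarray,
    n_total: int,
    cfg: FitConfig,
    prev_dists: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total loss, gradient and mse term for a (B, 9) parameter batch.

    ``xs, ys, tvals`` are flattened pixel coordinates and target values of
    the evaluation region; the mse is normalised by ``n_total`` (the full
    frame pixel count) so cropping the region only drops negligible
    far-field contributions.
    """
    w_mse, w_sum, w_sym, w_temp = cfg.weights
    s = cfg.sharpness
    B = P.shape[0]
    cx = P[:, 0:1, None]
    cy = P[:, 1:2, None]
    theta = np.deg2rad(P[:, 2])
    d = P[:, 3:9].reshape(B, 3, 2)
    rel = np.deg2rad(np.array([0.0, *rel_angles]))
    phi = theta[:, None] + rel[None, :]  # (B, 3)
    nx = np.cos(phi)[:, :, None]  # (B, 3, 1)
    ny = -np.sin(phi)[:, :, None]
    dx = xs[None, None, :] - cx
    dy = ys[None, None, :] - cy
    proj = nx * dx + ny * dy  # (B, 3, Np)
    z_p = s * (d[:, :, 0, None] - proj)
    z_m = s * (d[:, :, 1, None] + proj)
    log_f_p = -np.logaddexp(0.0, -z_p)
    log_f_m = -np.logaddexp(0.0, -z_m)
    m = np.exp(log_f_p.sum(axis=1) + log_f_m.sum(axis=1))  # (B, Np)
    r = m - tvals[None, :]
    mse = (r * r).sum(axis=1) / n_total

    # chain: dL/dz_k = (2/N) * r * m * (1 - f_k)
    common = (2.0 * w_mse / n_total) * (r * m)  # (B, Np)
    one_mf_p = -np.expm1(log_f_p)  # 1 - f, stably
    one_mf_m = -np.expm1(log_f_m)
    g_p = common[:, None, :] * one_mf_p  # (B, 3, Np)
    g_m = common[:, None, :] * one_mf_m

    grad = np.zeros((B, _N_PARAMS))
    grad[:, 3:9:2] = s * g_p.sum(axis=2)
    grad[:, 4:9:2] = s * g_m.sum(axis=2)
    diff = g_p - g_m  # (B, 3, Np)
    grad[:, 0] = s * (nx * diff).sum(axis=(1, 2))
    grad[:, 1] = s * (ny * diff).sum(axis=(1, 2))
    dproj_dth = -np.sin(phi)[:, :, None] * dx - np.cos(phi)[:, :, None] * dy
    grad[:, 2] = np.deg2rad(1.0) * s * (-(diff) * dproj_dth).sum(axis=(1, 2))

    dflat = P[:, 3:9]
    sumdist = dflat.sum(axis=1)
    grad[:, 3:9] += w_sum
    gap = d[:, :, 0] - d[:, :, 1]
    sym = (gap * gap).sum(axis=1)
    grad[:, 3:9:2] += 2.0 * w_sym * gap
    grad[:, 4:9:2] += -2.0 * w_sym * gap
    if prev_dists is not None and w_temp > 0:
        dd = dflat - prev_dists.reshape(6)[None, :]
        temporal = (dd * dd).sum(axis=1)
        grad[:, 3:9] += 2.0 * w_temp * dd
    else:
        temporal = np.zeros(B)

    total = w_mse * mse + w_sum * sumdist + w_sym * sym + w_temp * temporal
    terms = np.stack([mse, sumdist, sym, temporal], axis=1)
    return total, grad, terms


def _full_frame_args(target: np.ndarray):
    target = np.asarray(target, dtype=float)
    h, w = target.shape
    ys, xs = np.mgrid[0:h, 0:w]
    return xs.ravel().astype(float), ys.ravel().astype(float), target.ravel(), h * w


def loss(
    t: HexTemplate,
    target: np.ndarray,
    prev: HexTemplate | None,
    cfg: FitConfig,
) -> tuple[float, dict]:
    """Composite loss of one candidate against a binary target mask.

    Returns ``(total, terms)`` where terms holds the unweighted components
    ``mse``, ``sumdist``, ``sym`` and ``temporal``.
    """
    target = np.asarray(target, dtype=float)
    if target.ndim != 2:
        raise ValueError("target must be a 2D mask")
    xs, ys, tv, n = _full_frame_args(target)
    prev_d = None if prev is None else prev.dists
    total, _, terms = _batched_loss_grad(
        _pack(t)[None, :], t.rel_angles, xs, ys, tv, n, cfg, prev_d
    )
    keys = ("mse", "sumdist", "sym", "temporal")
    return float(total[0]), dict(zip(keys, terms[0].tolist()))


def loss_grad(
    t: HexTemplate,
    target: np.ndarray,
    prev: HexTemplate | None,
    cfg: FitConfig,
) -> np.ndarray:
    """Analytic gradient of the total loss in the packed parameter order
    ``[cx, cy, theta1, d1+, d1-, d2+, d2-, d3+, d3-]``."""
    xs, ys, tv, n = _full_frame_args(np.asarray(target, dtype=float))
    prev_d = None if prev is None else prev.dists
    _, grad, _ = _batched_loss_grad(
        _pack(t)[None, :], t.rel_angles, xs, ys, tv, n, cfg, prev_d
    )
    return grad[0]


# ---------------------------------------------------------------------------


def init_candidates(
    mask: np.ndarray,
    angles: CrystalAngles,
    n: int,
    seed: int = 0,
) -> list[HexTemplate]:
    """Initial candidates: centroid centre, theta1 on a uniform grid.

    theta1 takes n values evenly spaced on [0, 180) (the template is
    invariant under a 180-degree rotation with the distance pairs swapped,
    so half a turn covers all orientations); each candidate's distances are
    the maximal signed projections of the foreground pixels along its
    normals.  Deterministic for a fixed seed.
    """
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("cannot initialise candidates from an empty mask")
    c = np.array([xs.mean(), ys.mean()])
    rel = angles.rel_angles()
    out = []
    for j in range(n):
        theta = 180.0 * j / n
        phis = np.deg2rad(theta + np.array([0.0, *rel]))
        nxy = np.stack([np.cos(phis), -np.sin(phis)], axis=1)  # (3, 2)
        proj = (np.stack([xs, ys], axis=1) - c) @ nxy.T  # (Npx, 3)
        dists = np.stack(
            [proj.max(axis=0), -proj.min(axis=0)], axis=1
        ).clip(1.0, None)
        out.append(
            HexTemplate(center=c.copy(), theta1=theta, dists=dists,
                        rel_angles=rel)
        )
    return out


def _crop_args(mask: np.ndarray, cfg: FitConfig, stride: int = 1):
    mask = np.asarray(mask, dtype=float)
    h, w = mask.shape
    ys0, xs0 = np.nonzero(mask)
    if xs0.size == 0:
        raise ValueError("empty mask")
    mgn = cfg.crop_margin
    x0, x1 = max(0, xs0.min() - mgn), min(w, xs0.max() + mgn + 1)
    y0, y1 = max(0, ys0.min() - mgn), min(h, ys0.max() + mgn + 1)
    sub = mask[y0:y1:stride, x0:x1:stride]
    yy, xx = np.mgrid[y0:y1:stride, x0:x1:stride]
    return (
        xx.ravel().astype(float),
        yy.ravel().astype(float),
        sub.ravel(),
        max(1, h * w // stride**2),
    )


def _adam_run(
    P: np.ndarray,
    rel_angles,
    args,
    cfg: FitConfig,
    prev_dists,
    n_iters: int,
    schedule: bool,
):
    """Run Adam on a parameter batch; returns (P, loss, iterations, converged).

    With ``schedule=True`` the learning rate decays by ``lr_decay`` whenever
    the relative loss improvement over ``plateau_patience`` iterations falls
    below ``tol``; convergence is declared after ``plateaus_to_converge``
    decays.
    """
    xs, ys, tv, n_total = args
    B = P.shape[0]
    m = np.zeros_like(P)
    v = np.zeros_like(P)
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = np.full(B, cfg.lr0)
    plateaus = np.zeros(B, dtype=int)
    active = np.ones(B, dtype=bool)
    last_check = np.full(B, np.inf)
    total = np.full(B, np.inf)
    best_total = np.full(B, np.inf)
    best_P = P.copy()
    history: list[np.ndarray] = []
    it = 0
    for it in range(1, n_iters + 1):
        total, grad, _ = _batched_loss_grad(
            P, rel_angles, xs, ys, tv, n_total, cfg, prev_dists
        )
        if not np.all(np.isfinite(total)):
            bad = int(np.argmax(~np.isfinite(total)))
            raise DivergenceError(f"candidate {bad} diverged (non-finite loss)")
        improved = total < best_total
        best_total = np.where(improved, total, best_total)
        best_P[improved] = P[improved]
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad * grad
        mhat = m / (1 - b1**it)
        vhat = v / (1 - b2**it)
        step = lr[:, None] * mhat / (np.sqrt(vhat) + eps)
        P = P - np.where(active[:, None], step, 0.0)
        P[:, 3:9] = np.clip(P[:, 3:9], 0.0, None)
        if schedule and it % cfg.plateau_patience == 0:
            history.append(best_total.copy())
            rel = (last_check - total) / np.maximum(np.abs(total), 1e-30)
            plateau = active & (rel < cfg.tol)
            lr[plateau] *= cfg.lr_decay
            plateaus[plateau] += 1
            active &= plateaus < cfg.plateaus_to_converge
            last_check = total.copy()
            if not active.any():
                break
    if schedule:
        return best_P, best_total, it, ~active, history
    return P, total, it, np.zeros(B, dtype=bool), history


def fit_frame(
    mask: np.ndarray,
    inits: Sequence[HexTemplate],
    cfg: FitConfig,
    prev: HexTemplate | None = None,
) -> FrameFit:
    """Fit the template to one binary mask.

    All candidates are optimised for a prescreen stage; the ``refine_top``
    best by loss are then refined under the decay-on-plateau schedule and
    the candidate with the lowest final total loss is returned (ties break
    to the lowest candidate index).
    """
    if len(inits) == 0:
        raise ValueError("need at least one initial candidate")
    rel_angles = inits[0].rel_angles
    args = _crop_args(mask, cfg)
    prev_d = None if prev is None else prev.dists
    P = np.stack([_pack(t) for t in inits])
    order = np.arange(len(inits))
    if len(inits) > 1 and cfg.prescreen_iters > 0:
        coarse = _crop_args(mask, cfg, stride=max(1, cfg.prescreen_stride))
        P, total, _, _, _ = _adam_run(
            P, rel_angles, coarse, cfg, prev_d, cfg.prescreen_iters, False
        )
        order = np.argsort(total, kind="stable")[: max(1, cfg.refine_top)]
        P = P[order]
    P, total, iters, converged, history = _adam_run(
        P, rel_angles, args, cfg, prev_d, cfg.max_iters, True
    )
    best = int(np.argmin(total))
    tmpl = _unpack(P[best], rel_angles)
    tot, terms = loss(tmpl, mask, prev, cfg)
    terms["total"] = tot
    return FrameFit(
        template=tmpl,
        loss_terms=terms,
        converged=bool(converged[best]),
        iterations=iters,
        candidate_index=int(order[best]),
        loss_history=[float(h[best]) for h in history],
    )


def _reinit_at_theta(mask: np.ndarray, ref: HexTemplate) -> HexTemplate:
    """Fresh candidate at the reference orientation: centroid centre and
    maximal-projection distances along the reference normals."""
    ys, xs = np.nonzero(np.asarray(mask))
    c = np.array([xs.mean(), ys.mean()])
    phis = np.deg2rad(ref.theta1 + np.array([0.0, *ref.rel_angles]))
    nxy = np.stack([np.cos(phis), -np.sin(phis)], axis=1)
    proj = (np.stack([xs, ys], axis=1) - c) @ nxy.T
    dists = np.stack([proj.max(axis=0), -proj.min(axis=0)], axis=1).clip(1.0, None)
    return HexTemplate(center=c, theta1=ref.theta1, dists=dists,
                       rel_angles=ref.rel_angles)


def _is_binary(frame: np.ndarray) -> bool:
    u = np.unique(np.asarray(frame)[::4, ::4])
    return frame.dtype == bool or (
        u.size <= 2 and np.isin(u, [0, 1]).all()
    )


def fit_sequence(
    frames: Sequence[np.ndarray],
    times: Sequence[float],
    select: tuple[int, tuple[float, float]],
    cfg: FitConfig,
    angles: CrystalAngles | None = None,
    backend: str = "otsu",
) -> SequenceResult:
    """Segment and fit a whole time-lapse, tracking forward and backward.

    The selected frame is processed first with the full candidate batch;
    each neighbouring frame is then segmented at the previously fitted
    centre and optimised from the previous template with the temporal
    anchor active.  Frames may be grayscale images (segmented per
    ``backend``) or ready binary masks.  On a frame-level failure the
    propagation in that direction halts; partial results are returned with
    the failing index recorded.
    """
    if len(frames) == 0:
        raise ValueError("frames must be nonempty")
    sel_idx, sel_point = select
    if not 0 <= sel_idx < len(frames):
        raise ValueError("selected frame index out of range")
    angles = angles or CrystalAngles()
    fits: list = [None] * len(frames)
    failed_at = None
    error = None

    def get_mask(i: int, point) -> np.ndarray:
        f = np.asarray(frames[i])
        if _is_binary(f):
            return f.astype(np.uint8)
        return segment(f, point, backend=backend)

    try:
        mask0 = get_mask(sel_idx, sel_point)
        inits = init_candidates(mask0, angles, cfg.n_candidates, cfg.seed)
        fits[sel_idx] = fit_frame(mask0, inits, cfg)
    except (SegmentationError, DivergenceError, ValueError) as exc:
        return SequenceResult(
            fits=fits, times=np.asarray(times, float),
            failed_at=sel_idx, error=str(exc),
        )

    for direction in (1, -1):
        prev_fit = fits[sel_idx]
        i = sel_idx + direction
        while 0 <= i < len(frames):
            prev_t = prev_fit.template
            try:
                mask = get_mask(i, tuple(prev_t.center))
                cands = [prev_t.copy(), _reinit_at_theta(mask, prev_t)]
                fits[i] = fit_frame(mask, cands, cfg, prev=prev_t)
            except (SegmentationError, DivergenceError, ValueError) as exc:
                failed_at = i
                error = str(exc)
                break
            prev_fit = fits[i]
            i += direction
    return SequenceResult(
        fits=fits, times=np.asarray(times, float),
        failed_at=failed_at, error=error,
    )
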