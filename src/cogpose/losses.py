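"""Physics-constrained training losses and the MPJPE evaluation metric.

Three losses supervise the lifted 3D pose:

* position loss ``L`` — mean Euclidean distance between predicted and
  ground-truth keypoints (the conventional lifting loss, same form as the
  MPJPE metric);
* center-of-gravity loss ``L_gd`` — for each keypoint, the distance to
  the pose's own whole-body CoG (moment synthesis over the mass-bearing
  segments) must match the ground truth: mean squared difference of those
  distances. Being built from within-pose distances it is invariant to a
  rigid motion applied to both poses;
* bone loss ``L_bone`` — per bone, one minus the cosine similarity of the
  predicted and true bone vectors plus ``lambda`` times the norm of their
  difference, enforcing limb-length and orientation consistency.

The weighted total is ``w_pos * L + w_cog * L_gd + w_bone * L_bone``.

Every loss accepts plain arrays / :class:`~cogpose.skeleton.Pose3D`
(returning a float) or an autodiff :class:`~cogpose.autodiff.Tensor`
prediction (returning a Tensor for backprop), with an optional batch
dimension ahead of the keypoint axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import AnthropometricTable, cog_weight_vector
from .autodiff import Tensor
from .skeleton import BoneTree, Pose3D, make_layout

__all__ = [
    "LossWeights",
    "loss_position",
    "loss_cog",
    "cog_distances",
    "loss_bone",
    "loss_total",
    "mpjpe",
    "percent_change",
]


@dataclass
class LossWeights:
    """Weights of the total loss and the bone-length trade-off lambda.

    ``bone_squared`` selects the squared bone-difference penalty
    ``lambda * ||b - b_hat||^2`` whose gradient vanishes at the optimum;
    the default is the plain norm.
    """

    w_pos: float = 1.0
    w_cog: float = 1.0
    w_bone: float = 1.0
    lambda_bone: float = 1.0
    bone_squared: bool = False

    def __post_init__(self):
        if min(self.w_pos, self.w_cog, self.w_bone, self.lambda_bone) < 0:
            raise ValueError("loss weights must be nonnegative")


def _coords(pose):
    if isinstance(pose, Pose3D):
        return pose.coords
    return pose


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(_coords(x), dtype=float))


def _maybe_float(value: Tensor, *inputs):
    if any(isinstance(x, Tensor) and x.requires_grad for x in inputs):
        return value
    return float(value.data)


def _norm(t: Tensor, floor: float = 0.0) -> Tensor:
    sq = (t * t).sum(axis=-1)
    if floor > 0.0:
        sq = sq.maximum(floor)
    return sq.sqrt()


def _masked_mean(values: Tensor, mask) -> Tensor:
    if mask is None:
        return values.mean()
    mask = np.broadcast_to(np.asarray(mask, dtype=float), values.shape)
    count = mask.sum()
    if count == 0:
        raise ValueError("no valid entries to average over")
    return (values * mask).sum() * (1.0 / count)


def _joint_mask(pred, gt, valid):
    if valid is not None:
        return np.asarray(valid, bool)
    masks = [p.valid for p in (pred, gt) if isinstance(p, Pose3D)]
    if masks:
        m = masks[0]
        for other in masks[1:]:
            m = m & other
        return m
    return None


def loss_position(pred, gt, valid=None, squared: bool = False):
    """Mean per-joint Euclidean distance between prediction and truth.

    With ``squared`` the mean squared distance is returned instead.
    Raises if no joint is valid.
    """
    mask = _joint_mask(pred, gt, valid)
    p, g = _as_tensor(pred), _as_tensor(gt)
    d = p - g
    sq = (d * d).sum(axis=-1)
    per_joint = sq if squared else sq.sqrt()
    out = _masked_mean(per_joint, mask)
    return _maybe_float(out, pred)


def _weights(table_or_weights, layout):
    if isinstance(table_or_weights, AnthropometricTable):
        return cog_weight_vector(table_or_weights, layout)
    return np.asarray(table_or_weights, float)


def cog_distances(pose, table_or_weights, layout=None) -> np.ndarray:
    """Distance of every keypoint to the pose's whole-body CoG (mm)."""
    layout = layout or make_layout()
    w = _weights(table_or_weights, layout)
    coords = np.asarray(_coords(pose), float)
    cog = np.tensordot(coords, w, axes=(-2, 0))[..., None, :]
    return np.linalg.norm(coords - cog, axis=-1)


def loss_cog(pred, gt, table_or_weights, valid=None, layout=None,
             absolute: bool = False):
    """Center-of-gravity distance-consistency loss ``L_gd``.

    ``g_i = ||p_i - CoG(pred)||`` and ``g_hat_i`` likewise for the ground
    truth; returns the mean of ``(g_i - g_hat_i)^2`` over valid joints
    (mean absolute difference with ``absolute``). Invariant under a
    common rigid motion of both poses; zero when ``pred == gt``.
    """
    layout = layout or make_layout()
    w = _weights(table_or_weights, layout)
    mask = _joint_mask(pred, gt, valid)
    p = _as_tensor(pred)
    wt = Tensor(w[:, None].astype(p.data.dtype))
    cog = (p * wt).sum(axis=-2, keepdims=True)
    g = _norm(p - cog)
    g_hat = cog_distances(gt, w, layout)
    diff = g - Tensor(g_hat.astype(g.data.dtype))
    if absolute:
        per_joint = (diff * diff).maximum(0.0).sqrt()
    else:
        per_joint = diff * diff
    out = _masked_mean(per_joint, mask)
    return _maybe_float(out, pred)


def _bone_valid(gt_coords, tree, valid):
    p, c = tree.edges[:, 0], tree.edges[:, 1]
    b_gt = gt_coords[..., c, :] - gt_coords[..., p, :]
    ok = np.linalg.norm(b_gt, axis=-1) > 0
    if valid is not None:
        v = np.asarray(valid, bool)
        ok = ok & v[..., c] & v[..., p]
    return b_gt, ok


def loss_bone(pred, gt, tree: BoneTree, lambda_bone: float = 1.0,
              valid=None, squared_length: bool = False):
    """Bone orientation/length consistency loss ``L_bone``.

    Mean over valid bones of ``(1 - cos(b, b_hat)) + lambda * ||b - b_hat||``
    (``||.||^2`` with ``squared_length``). Bones whose ground-truth vector
    is zero, or with an invalid endpoint, are masked; if all bones are
    masked an error is raised.
    """
    gt_coords = np.asarray(_coords(gt), float)
    mask = _joint_mask(pred, gt, valid)
    b_gt, ok = _bone_valid(gt_coords, tree, mask)
    if not np.any(ok):
        raise ValueError("all bones are masked; bone loss undefined")
    p = _as_tensor(pred)
    pi, ci = tree.edges[:, 0], tree.edges[:, 1]
    b = p[..., ci, :] - p[..., pi, :]
    bt_gt = Tensor(b_gt.astype(b.data.dtype))
    nb = _norm(b, floor=1e-24)
    nb_gt = np.linalg.norm(b_gt, axis=-1)
    cos = (b * bt_gt).sum(axis=-1) / (nb * np.where(ok, nb_gt, 1.0))
    diff = b - bt_gt
    if squared_length:
        length_term = (diff * diff).sum(axis=-1)
    else:
        length_term = _norm(diff)
    per_bone = (1.0 - cos) + length_term * lambda_bone
    out = _masked_mean(per_bone, ok)
    return _maybe_float(out, pred)


def loss_total(pred, gt, table_or_weights, tree: BoneTree,
               weights: LossWeights | None = None, valid=None, layout=None):
    """Weighted total loss and its per-term breakdown.

    Returns ``(total, breakdown)`` where breakdown maps
    ``{"position", "cog", "bone"}`` to detached floats. Terms with zero
    weight are skipped, so ``LossWeights(1, 0, 0)`` reduces exactly to
    :func:`loss_position`.
    """
    weights = weights or LossWeights()
    zero = Tensor(np.zeros(())) if isinstance(pred, Tensor) else 0.0
    total = zero
    breakdown = {"position": 0.0, "cog": 0.0, "bone": 0.0}
    if weights.w_pos > 0:
        term = loss_position(pred, gt, valid=valid)
        breakdown["position"] = float(term.data) if isinstance(term, Tensor) \
            else float(term)
        total = total + term * weights.w_pos
    if weights.w_cog > 0:
        term = loss_cog(pred, gt, table_or_weights, valid=valid, layout=layout)
        breakdown["cog"] = float(term.data) if isinstance(term, Tensor) \
            else float(term)
        total = total + term * weights.w_cog
    if weights.w_bone > 0:
        term = loss_bone(pred, gt, tree, lambda_bone=weights.lambda_bone,
                         valid=valid, squared_length=weights.bone_squared)
        breakdown["bone"] = float(term.data) if isinstance(term, Tensor) \
            else float(term)
        total = total + term * weights.w_bone
    return total, breakdown


def mpjpe(pred, gt, group=None, valid=None) -> float:
    """Mean per-joint position error (mm) over a keypoint group.

    Both poses must share a frame (root-relative for the standard
    protocol). ``group`` is an index array (default: all keypoints).
    """
    p = np.asarray(_coords(pred), float)
    g = np.asarray(_coords(gt), float)
    mask = _joint_mask(pred, gt, valid)
    if group is not None:
        group = np.asarray(group, int)
        p, g = p[..., group, :], g[..., group, :]
        mask = None if mask is None else mask[..., group]
    d = np.linalg.norm(p - g, axis=-1)
    if mask is None:
        if d.size == 0:
            raise ValueError("empty keypoint group")
        return float(d.mean())
    mask = np.broadcast_to(mask, d.shape)
    if not mask.any():
        raise ValueError("no valid joints in group")
    return float(d[mask].mean())


def percent_change(reference: float, ours: float,
                   decimals: int | None = None) -> float:
    """Relative improvement of ``ours`` over ``reference`` in percent.

    ``100 * (reference - ours) / reference``; positive when ``ours`` is
    smaller (an error reduction). Optionally rounded to ``decimals``.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    value = 100.0 * (reference - ours) / reference
    return round(value, decimals) if decimals is not None else value
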