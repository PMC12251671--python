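"""Dual-branch cross-attention Transformer for 2D-to-3D pose lifting.

The model ingests two token streams built from the same 2D observation:
coordinate tokens (one per keypoint: root-centered pixel coordinates plus
detection confidence) and bone tokens (one per skeleton edge: unit
direction plus log length). A stack of cross-attention fusion layers lets
joint tokens query bone tokens and vice versa; the fused joint tokens then
pass through a self-attention encoder and a linear head regresses the
root-relative 3D position of every keypoint.

Training minimizes the physics-constrained total loss (position + CoG
consistency + bone consistency) with AdamW under cosine-annealed learning
rate, with rotation/scale/flip augmentation of each batch.

Reference configuration: 6 encoder layers, 8 heads, hidden width 256,
4 cross-attention fusion layers, 210 epochs at batch size 64 and initial
learning rate 1e-3 with drops at epochs 170 and 200. A small CPU-friendly
profile (``desk_model_config`` / ``desk_train_config``) is used by the
test suite and the shipped synthetic benchmark.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import nn
from .anthropometry import AnthropometricTable, cog_weight_vector, load_table
from .autodiff import Tensor
from .camera import CameraIntrinsics, backproject, project
from .encoding import bone_features
from .losses import LossWeights, loss_total, mpjpe
from .skeleton import (BoneTree, KeypointLayout, Pose2D, Pose3D,
                       make_bone_tree, make_layout)

__all__ = [
    "ModelConfig", "TrainConfig", "LiftingModel",
    "desk_model_config", "desk_train_config",
    "fit", "evaluate", "select_hypothesis",
    "save_checkpoint", "load_checkpoint", "layout_hash",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the lifting network."""

    depth: int = 6              # self-attention encoder layers
    heads: int = 8
    hidden: int = 256
    cross_layers: int = 4       # dual-branch fusion layers
    dropout: float = 0.1
    multi_hypothesis: bool = False
    ffn_mult: int = 4
    activation: str = "gelu"
    input_scale: float = 250.0   # px; divisor for root-centered 2D input
    output_scale: float = 1000.0  # mm per network output unit
    bone_log_eps: float = 1e-4

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")
        if self.depth < 1 or self.cross_layers < 1:
            raise ValueError("depth and cross_layers must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule and loss weighting."""

    epochs: int = 210
    batch_size: int = 64
    lr: float = 1e-3
    lr_drop_epochs: tuple = (170, 200)
    lr_drop_factor: float = 0.1
    cosine: bool = True
    weight_decay: float = 0.01
    seed: int = 0
    augment: bool = True
    rotation_deg: float = 15.0
    scale_range: tuple = (0.8, 1.2)
    flip_prob: float = 0.5
    loss_weights: LossWeights = field(default_factory=LossWeights)
    # linear ramp-in of the auxiliary (CoG/bone) weights over the first
    # fraction of epochs; 0 disables it
    aux_ramp_frac: float = 0.1

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.lr_drop_epochs and self.epochs <= max(self.lr_drop_epochs):
            raise ValueError("epochs must exceed every lr drop epoch")


def desk_model_config(**overrides) -> ModelConfig:
    """Small CPU profile used by the shipped synthetic benchmark."""
    base = dict(depth=1, heads=1, hidden=32, cross_layers=1, dropout=0.0,
                ffn_mult=2, activation="relu")
    base.update(overrides)
    return ModelConfig(**base)


def desk_train_config(**overrides) -> TrainConfig:
    base = dict(epochs=8, lr_drop_epochs=(), batch_size=64, lr=1e-3)
    base.update(overrides)
    return TrainConfig(**base)


def layout_hash(layout: KeypointLayout) -> str:
    return hashlib.sha256(",".join(layout.names).encode()).hexdigest()[:16]


def _path_matrix(tree: BoneTree) -> np.ndarray:
    """A (133, 132): coords = A @ bone_vectors for a root-at-origin pose."""
    n = len(tree.parent)
    A = np.zeros((n, tree.n_edges), dtype=np.float32)
    edge_of_child = {int(c): i for i, (_, c) in enumerate(tree.edges)}
    for node in tree.preorder():
        if node == tree.root:
            continue
        A[node] = A[tree.parent[node]]
        A[node, edge_of_child[node]] = 1.0
    return A


class LiftingModel(nn.Module):
    """The dual-branch cross-attention lifting network."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None,
                 layout: KeypointLayout | None = None,
                 tree: BoneTree | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.layout = layout or make_layout()
        self.tree = tree or make_bone_tree()
        nk, ne, d = self.layout.n_keypoints, self.tree.n_edges, cfg.hidden
        f32 = np.float32
        self.embed_joint = nn.Linear(3, d, rng)
        self.embed_bone = nn.Linear(3, d, rng)
        self.pos_joint = Tensor((0.02 * rng.standard_normal((nk, d))).astype(f32),
                                requires_grad=True)
        self.pos_bone = Tensor((0.02 * rng.standard_normal((ne, d))).astype(f32),
                               requires_grad=True)
        blk = lambda: nn.TransformerBlock(d, cfg.heads, rng, cfg.dropout,
                                          cfg.ffn_mult, cfg.activation)
        self.cross_joint = [blk() for _ in range(cfg.cross_layers)]
        self.cross_bone = [blk() for _ in range(cfg.cross_layers)]
        self.encoder = [blk() for _ in range(cfg.depth)]
        self.ln_out = nn.LayerNorm(d)
        self.head = nn.Linear(d, 3, rng)
        if cfg.multi_hypothesis:
            self.ln_pre = nn.LayerNorm(d)
            self.head_pre = nn.Linear(d, 3, rng)
            self.ln_bone = nn.LayerNorm(d)
            self.head_bone = nn.Linear(d, 3, rng)
        self._A = _path_matrix(self.tree)
        hips = self.layout.root_definition
        self._hips = hips

    # -- forward ----------------------------------------------------------
    def _center(self, out: Tensor) -> Tensor:
        lh, rh = self._hips
        root = (out[:, lh:lh + 1, :] + out[:, rh:rh + 1, :]) * 0.5
        return out - root

    def _streams(self, feats_joint, feats_bone, train, rng,
                 need_bone_stream: bool = False):
        x = self.embed_joint(Tensor(feats_joint)) + self.pos_joint
        y = self.embed_bone(Tensor(feats_bone)) + self.pos_bone
        last = len(self.cross_joint) - 1
        for i, (bj, bb) in enumerate(zip(self.cross_joint, self.cross_bone)):
            x_new = bj(x, kv=y, train=train, rng=rng)
            # the bone stream's last update only feeds the bone-branch
            # hypothesis head; skip it when nothing consumes it
            if i < last or need_bone_stream:
                y = bb(y, kv=x, train=train, rng=rng)
            x = x_new
        return x, y

    def forward(self, feats_joint: np.ndarray, feats_bone: np.ndarray,
                train: bool = False, rng=None) -> Tensor:
        """Lift a batch: (B,133,3) joint feats + (B,132,3) bone feats ->
        (B,133,3) root-relative coordinates in network units."""
        x, _ = self._streams(feats_joint, feats_bone, train, rng)
        for blk in self.encoder:
            x = blk(x, train=train, rng=rng)
        out = self.head(self.ln_out(x))
        return self._center(out)

    def forward_hypotheses(self, feats_joint, feats_bone, train=False,
                           rng=None) -> list:
        """All regression readouts (fused, pre-encoder, bone-branch)."""
        if not self.cfg.multi_hypothesis:
            raise ValueError("multi_hypothesis is disabled in ModelConfig")
        x, y = self._streams(feats_joint, feats_bone, train, rng,
                             need_bone_stream=True)
        pre = self._center(self.head_pre(self.ln_pre(x)))
        for blk in self.encoder:
            x = blk(x, train=train, rng=rng)
        fused = self._center(self.head(self.ln_out(x)))
        bones = self.head_bone(self.ln_bone(y))          # (B,132,3)
        coords = Tensor(self._A) @ bones                 # prefix sums
        return [fused, pre, self._center(coords)]

    # -- data preparation -------------------------------------------------
    def prepare_inputs(self, kp2d: np.ndarray, conf: np.ndarray,
                       valid: np.ndarray):
        """Root-center, mask and scale a (B,133,2) pixel batch into the
        joint/bone feature arrays the forward pass consumes."""
        lh, rh = self._hips
        root = 0.5 * (kp2d[:, lh] + kp2d[:, rh])
        x = (kp2d - root[:, None, :]) / self.cfg.input_scale
        v = valid.astype(bool)
        x = np.where(v[..., None], x, 0.0)
        c = np.where(v, conf, 0.0)
        feats_joint = np.concatenate([x, c[..., None]], axis=-1)
        p, ch = self.tree.edges[:, 0], self.tree.edges[:, 1]
        bvec = x[:, ch] - x[:, p]
        bok = v[:, ch] & v[:, p]
        fb = bone_features(bvec, self.cfg.bone_log_eps)
        fb = np.where(bok[..., None], fb, 0.0)
        return feats_joint.astype(np.float32), fb.astype(np.float32)

    def predict_batch(self, kp2d, conf, valid, batch_size: int = 256
                      ) -> np.ndarray:
        """Root-relative 3D predictions in millimetres, (B,133,3)."""
        outs = []
        for i in range(0, len(kp2d), batch_size):
            fj, fb = self.prepare_inputs(kp2d[i:i + batch_size],
                                         conf[i:i + batch_size],
                                         valid[i:i + batch_size])
            out = self.forward(fj, fb, train=False)
            outs.append(out.data * self.cfg.output_scale)
        return np.concatenate(outs, axis=0).astype(float)

    def predict(self, pose2d: Pose2D) -> Pose3D:
        coords = self.predict_batch(pose2d.coords[None],
                                    pose2d.confidence[None],
                                    pose2d.valid[None])[0]
        return Pose3D(coords=coords, frame="root_relative")


# -- training ---------------------------------------------------------------

def _lr_at(epoch: int, tcfg: TrainConfig) -> float:
    lr = tcfg.lr
    if tcfg.cosine and tcfg.epochs > 1:
        lr *= 0.5 * (1.0 + np.cos(np.pi * epoch / tcfg.epochs))
    for drop in tcfg.lr_drop_epochs:
        if epoch >= drop:
            lr *= tcfg.lr_drop_factor
    return float(lr)


def _augment_batch(kp2d, kp3d, conf, valid, layout, tcfg, rng):
    """Rotation (both), scaling (2D only) and flipping (both), per batch."""
    theta = np.deg2rad(rng.uniform(-tcfg.rotation_deg, tcfg.rotation_deg))
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    kp2d = kp2d @ R.T
    kp3d = kp3d.copy()
    kp3d[..., :2] = kp3d[..., :2] @ R.T
    kp2d = kp2d * rng.uniform(*tcfg.scale_range)
    if rng.random() < tcfg.flip_prob:
        perm = layout.left_right_swap
        kp2d = kp2d[:, perm]
        kp2d[..., 0] = -kp2d[..., 0]
        kp3d = kp3d[:, perm]
        kp3d[..., 0] = -kp3d[..., 0]
        conf, valid = conf[:, perm], valid[:, perm]
    return kp2d, kp3d, conf, valid


def fit(train_data, val_data, mcfg: ModelConfig, tcfg: TrainConfig,
        table: AnthropometricTable | None = None,
        layout: KeypointLayout | None = None,
        tree: BoneTree | None = None,
        progress: bool = False,
        model: "LiftingModel | None" = None,
        start_epoch: int = 0):
    """Train a lifting model; returns ``(model, history)``.

    ``train_data``/``val_data`` are mappings with arrays ``kp2d`` (N,133,2
    px), ``kp3d`` (N,133,3 mm, root-relative), ``conf`` and ``valid``.
    History records per-epoch learning rate, training loss (with per-term
    breakdown) and validation loss / MPJPE. Aborts with a RuntimeError
    naming the offending batch and seed if the loss goes non-finite.
    """
    layout = layout or make_layout()
    tree = tree or make_bone_tree()
    table = table or load_table("M")
    rng = np.random.default_rng(tcfg.seed + start_epoch)
    if model is None:
        model = LiftingModel(mcfg,
                             rng=np.random.default_rng(rng.integers(2**31)),
                             layout=layout, tree=tree)
    w_cog = cog_weight_vector(table, layout)
    opt = nn.AdamW(model.parameters(), lr=tcfg.lr,
                   weight_decay=tcfg.weight_decay)

    kp2d = np.asarray(train_data["kp2d"], float)
    kp3d = np.asarray(train_data["kp3d"], float) / mcfg.output_scale
    conf = np.asarray(train_data["conf"], float)
    valid = np.asarray(train_data["valid"], bool)
    n = len(kp2d)
    history = []
    for epoch in range(start_epoch, tcfg.epochs):
        opt.lr = _lr_at(epoch, tcfg)
        lw = tcfg.loss_weights
        if tcfg.aux_ramp_frac > 0:
            ramp_epochs = max(tcfg.aux_ramp_frac * tcfg.epochs, 1e-9)
            ramp = min(1.0, (epoch + 1) / ramp_epochs)
            lw = LossWeights(lw.w_pos, lw.w_cog * ramp, lw.w_bone * ramp,
                             lw.lambda_bone)
        order = rng.permutation(n)
        tot, terms = 0.0, np.zeros(3)
        nb = 0
        for bi, start in enumerate(range(0, n, tcfg.batch_size)):
            idx = order[start:start + tcfg.batch_size]
            b2d, b3d = kp2d[idx], kp3d[idx]
            bc, bv = conf[idx], valid[idx]
            if tcfg.augment:
                b2d, b3d, bc, bv = _augment_batch(b2d, b3d, bc, bv, layout,
                                                  tcfg, rng)
            fj, fb = model.prepare_inputs(b2d, bc, bv)
            pred = model.forward(fj, fb, train=True, rng=rng)
            loss, breakdown = loss_total(pred, b3d.astype(np.float32),
                                         w_cog, tree, weights=lw,
                                         layout=layout)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi}, "
                    f"seed {tcfg.seed}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += float(loss.data)
            terms += [breakdown["position"], breakdown["cog"],
                      breakdown["bone"]]
            nb += 1
        val_loss, val_mpjpe = _validate(model, val_data, w_cog, tree,
                                        tcfg.loss_weights, layout)
        history.append({
            "epoch": epoch, "lr": opt.lr, "train_loss": tot / nb,
            "train_position": terms[0] / nb, "train_cog": terms[1] / nb,
            "train_bone": terms[2] / nb,
            "val_loss": val_loss, "val_mpjpe_mm": val_mpjpe,
        })
        if progress:
            print(f"epoch {epoch:3d} lr {opt.lr:.2e} "
                  f"train {tot / nb:.4f} val {val_loss:.4f} "
                  f"val MPJPE {val_mpjpe:.1f} mm")
    return model, history


def _validate(model, data, w_cog, tree, weights, layout):
    kp2d = np.asarray(data["kp2d"], float)
    gt_mm = np.asarray(data["kp3d"], float)
    conf = np.asarray(data["conf"], float)
    valid = np.asarray(data["valid"], bool)
    pred_mm = model.predict_batch(kp2d, conf, valid)
    scale = model.cfg.output_scale
    loss, _ = loss_total(pred_mm / scale, gt_mm / scale, w_cog, tree,
                         weights=weights, layout=layout)
    return float(loss), mpjpe(pred_mm, gt_mm)


def evaluate(model: LiftingModel, data, layout: KeypointLayout | None = None
             ) -> dict:
    """Part-grouped MPJPE report (mm): whole_body, body, face, hands."""
    layout = layout or make_layout()
    pred = model.predict_batch(np.asarray(data["kp2d"], float),
                               np.asarray(data["conf"], float),
                               np.asarray(data["valid"], bool))
    gt = np.asarray(data["kp3d"], float)
    return {name: mpjpe(pred, gt, group=idx)
            for name, idx in layout.part_groups.items()}


# -- hypothesis selection ----------------------------------------------------

def _reprojection_error(coords_rel, root, pose2d: Pose2D,
                        cam: CameraIntrinsics) -> float:
    pts = coords_rel + root
    if np.any(pts[:, 2] <= 0):
        return np.inf
    uv = project(pts, cam)
    err = np.linalg.norm(uv - pose2d.coords, axis=-1)
    if pose2d.valid.any():
        return float(err[pose2d.valid].mean())
    return float(err.mean())


def select_hypothesis(candidates: list, pose2d: Pose2D,
                      cam: CameraIntrinsics,
                      root_position=None,
                      layout: KeypointLayout | None = None):
    """Pick the candidate 3D pose with the lowest 2D reprojection error.

    Candidates are root-relative poses. If the absolute root position is
    unknown, each candidate's root is placed on the back-projection ray of
    the observed 2D mid-hip point at the depth minimizing its reprojection
    error. Ties break toward the lowest candidate index.
    """
    if not candidates:
        raise ValueError("no candidate poses to select from")
    layout = layout or make_layout()
    lh, rh = layout.root_definition
    best_i, best_err = 0, np.inf
    for i, cand in enumerate(candidates):
        coords = np.asarray(cand.coords if isinstance(cand, Pose3D) else cand,
                            float)
        if root_position is not None:
            err = _reprojection_error(coords, np.asarray(root_position, float),
                                      pose2d, cam)
        else:
            uv_root = 0.5 * (pose2d.coords[lh] + pose2d.coords[rh])
            def err_at(z):
                return _reprojection_error(coords, backproject(uv_root, z, cam),
                                           pose2d, cam)
            res = minimize_scalar(err_at, bounds=(200.0, 30000.0),
                                  method="bounded")
            err = float(res.fun)
        if err < best_err:
            best_i, best_err = i, err
    return candidates[best_i]


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(path, model: LiftingModel,
                    tcfg: TrainConfig | None = None,
                    extra: dict | None = None) -> None:
    """Serialize parameters plus model/train config and layout hash."""
    meta = {
        "model_config": asdict(model.cfg),
        "train_config": asdict(tcfg) if tcfg else None,
        "layout_hash": layout_hash(model.layout),
        "extra": extra or {},
    }
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple:
    """Rebuild a model from a checkpoint; returns (model, metadata)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        cfg = ModelConfig(**meta["model_config"])
        model = LiftingModel(cfg)
        if layout_hash(model.layout) != meta["layout_hash"]:
            raise ValueError("checkpoint layout hash does not match the "
                             "installed keypoint layout")
        params = model.parameters()
        for i, p in enumerate(params):
            p.data = z[f"p{i}"]
    if meta.get("train_config"):
        meta["train_config"]["loss_weights"] = LossWeights(
            **meta["train_config"]["loss_weights"])
        meta["train_config"]["lr_drop_epochs"] = tuple(
            meta["train_config"]["lr_drop_epochs"])
        meta["train_config"]["scale_range"] = tuple(
            meta["train_config"]["scale_range"])
        meta["train_config"] = TrainConfig(**meta["train_config"])
    return model, meta
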