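"""Bone-vector pose encoding and token features for the lifting network.

A pose can be represented either by its keypoint coordinates or by the
132 bone vectors of the skeleton tree (child minus parent). The bone
representation carries limb length and orientation explicitly, which is
what the physics constraints act on; summing bone vectors from the tree
root reconstructs the coordinates exactly.

For the network, each representation becomes a token sequence:
coordinate tokens are a linear embedding of each keypoint plus a
learnable positional encoding, and bone tokens embed the decomposed
feature ``b/||b||  (+)  log(||b|| + eps)`` — unit direction concatenated
with log length — the same construction in 2D (3 features) and 3D
(4 features).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import BoneTree, Pose2D, Pose3D

__all__ = [
    "BoneVectors",
    "EmbeddingConfig",
    "TokenEmbedder",
    "bone_vectors",
    "reconstruct_from_bones",
    "joint_angle",
    "bone_feature",
    "bone_features",
    "make_tokens",
]


@dataclass
class BoneVectors:
    """Per-edge bone vectors (child minus parent) and their lengths."""

    vectors: np.ndarray   # (132, D)
    lengths: np.ndarray   # (132,)
    valid: np.ndarray     # (132,) bool — both endpoints valid


@dataclass(frozen=True)
class EmbeddingConfig:
    """Token embedding width and numerical constants."""

    dim: int = 256
    epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.dim <= 0 or self.epsilon <= 0:
            raise ValueError("dim and epsilon must be positive")


def bone_vectors(pose, tree: BoneTree) -> BoneVectors:
    """Compute bone vectors for a 2D or 3D pose over the tree's edges.

    Edges with an invalid endpoint are masked (zero vector, valid=False).
    """
    coords = pose.coords
    p, c = tree.edges[:, 0], tree.edges[:, 1]
    vec = coords[c] - coords[p]
    ok = pose.valid[c] & pose.valid[p]
    vec = np.where(ok[:, None], vec, 0.0)
    return BoneVectors(vectors=vec, lengths=np.linalg.norm(vec, axis=1),
                       valid=ok)


def reconstruct_from_bones(bv: BoneVectors, tree: BoneTree,
                           root_coord=None) -> np.ndarray:
    """Rebuild keypoint coordinates by summing bones from the tree root.

    Exact inverse of :func:`bone_vectors` when all edges are valid and the
    root coordinate is supplied (default: origin).
    """
    dim = bv.vectors.shape[1]
    coords = np.zeros((len(tree.parent), dim))
    coords[tree.root] = 0.0 if root_coord is None else np.asarray(root_coord)
    vec_of_child = {int(c): i for i, (_, c) in enumerate(tree.edges)}
    for node in tree.preorder():
        if node == tree.root:
            continue
        coords[node] = coords[tree.parent[node]] + bv.vectors[vec_of_child[node]]
    return coords


def joint_angle(prox_vec, dist_vec) -> float:
    """Angle (radians, in [0, pi]) between two bone vectors at a joint.

    The cosine is clamped to [-1, 1] before arccos so nearly collinear
    bones never raise a domain error. Zero-length input is an error: the
    angle is undefined.
    """
    a = np.asarray(prox_vec, float)
    b = np.asarray(dist_vec, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("joint angle undefined for a zero-length bone")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def bone_feature(b, epsilon: float = 1e-8):
    """Direction-plus-log-length feature of one bone vector.

    Returns ``(b/||b||, log(||b|| + epsilon))`` as a flat vector (D+1
    components) and a validity flag that is False for a zero bone, whose
    direction part is all zeros.
    """
    b = np.asarray(b, float)
    n = np.linalg.norm(b)
    direction = b / n if n > 0 else np.zeros_like(b)
    return np.concatenate([direction, [np.log(n + epsilon)]]), n > 0


def bone_features(vectors: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Vectorized :func:`bone_feature` over an ``(E, D)`` array."""
    v = np.asarray(vectors, float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    direction = np.where(n > 0, v / np.where(n > 0, n, 1.0), 0.0)
    return np.concatenate([direction, np.log(n + epsilon)], axis=-1)


class TokenEmbedder:
    """Linear token embeddings with learnable positional encodings.

    Holds the coordinate-token projection (keypoint pixel coordinates and
    confidence -> dim), the bone-token projection (2D bone feature ->
    dim), and one positional-encoding row per token. Used stand-alone for
    feature inspection; the lifting network keeps its own trainable copy.
    """

    def __init__(self, cfg: EmbeddingConfig, n_keypoints: int = 133,
                 n_bones: int = 132, coord_features: int = 3,
                 bone_feat_dim: int = 3, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(cfg.seed)
        d = cfg.dim
        s = 1.0 / np.sqrt(coord_features)
        self.cfg = cfg
        self.W_p = rng.uniform(-s, s, (coord_features, d))
        self.b_p = np.zeros(d)
        s = 1.0 / np.sqrt(bone_feat_dim)
        self.W_b = rng.uniform(-s, s, (bone_feat_dim, d))
        self.b_b = np.zeros(d)
        self.pos_p = 0.02 * rng.standard_normal((n_keypoints, d))
        self.pos_b = 0.02 * rng.standard_normal((n_bones, d))


def make_tokens(pose2d: Pose2D, tree: BoneTree, cfg: EmbeddingConfig,
                embedder: TokenEmbedder | None = None):
    """Build coordinate tokens (133 x dim) and bone tokens (132 x dim).

    Coordinate token i = W_p @ (u_i, v_i, conf_i) + b_p + pos_p[i];
    bone token j embeds the direction/log-length feature of bone j.
    """
    emb = embedder or TokenEmbedder(cfg)
    conf = np.where(pose2d.valid, pose2d.confidence, 0.0)
    coords = np.where(pose2d.valid[:, None], pose2d.coords, 0.0)
    feats_p = np.concatenate([coords, conf[:, None]], axis=1)
    bv = bone_vectors(pose2d, tree)
    feats_b = bone_features(bv.vectors, cfg.epsilon)
    tok_p = feats_p @ emb.W_p + emb.b_p + emb.pos_p
    tok_b = feats_b @ emb.W_b + emb.b_b + emb.pos_b
    return tok_p, tok_b
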