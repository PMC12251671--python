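"""Whole-body keypoint layout, bone tree, and pose containers.

The 133-keypoint COCO-WholeBody layout is the lingua franca of whole-body
pose estimation: 17 main-body keypoints, 6 foot keypoints, 68 face
landmarks (iBUG-68 order) and 21 keypoints per hand. The layout carries no
pelvis keypoint, so the pelvis "root" used for normalization is the virtual
midpoint of the two hips — the standard Human3.6M-protocol convention.

The skeleton is organized as a single rooted tree over the 133 keypoints
(132 bones), with the face fanned out from the nose and each hand rooted at
its wrist. The tree is shipped as packaged data (``data/layout.csv``)
together with the left/right swap permutation used for flip augmentation.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

N_KEYPOINTS = 133

__all__ = [
    "N_KEYPOINTS",
    "KeypointLayout",
    "BoneTree",
    "Pose2D",
    "Pose3D",
    "make_layout",
    "make_bone_tree",
    "root_center",
    "flip_pose",
    "read_coco_keypoints",
    "write_coco_keypoints",
]


class MissingKeypointError(ValueError):
    """A keypoint required by an operation is flagged invalid."""


@dataclass(frozen=True)
class KeypointLayout:
    """Names, groupings and symmetry of the 133-keypoint whole-body layout.

    Attributes
    ----------
    names : tuple of str
        Keypoint names in layout order.
    part_groups : mapping
        ``{"whole_body", "body", "face", "hands"}`` to index arrays. The
        ``body`` group (23 keypoints) includes the 6 foot keypoints.
    left_right_swap : ndarray
        Permutation pairing each left keypoint with its right counterpart;
        an involution.
    root_definition : (int, int)
        The two hip indices whose midpoint is the virtual pelvis root.
    """

    names: tuple
    part_groups: Mapping[str, np.ndarray]
    left_right_swap: np.ndarray
    root_definition: tuple
    sides: tuple = field(default=(), repr=False)

    @property
    def n_keypoints(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class BoneTree:
    """Rooted spanning tree over the keypoints.

    ``parent[i]`` is the parent keypoint of ``i`` (``-1`` for the root);
    ``edges`` lists the 132 ``(parent, child)`` bone pairs in a fixed
    order (ascending child index).
    """

    parent: np.ndarray
    edges: np.ndarray

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def preorder(self) -> np.ndarray:
        """Preorder traversal of keypoint indices starting at the root."""
        children: list[list[int]] = [[] for _ in self.parent]
        for p, c in self.edges:
            children[p].append(c)
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(children[node]))
        return np.asarray(order)


@dataclass
class Pose2D:
    """Per-frame 2D keypoints in pixels, relative to the principal point."""

    coords: np.ndarray          # (133, 2)
    confidence: np.ndarray      # (133,), in [0, 1]
    valid: np.ndarray           # (133,), bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.coords.shape != (len(self.valid), 2):
            raise ValueError(f"bad 2D coords shape {self.coords.shape}")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ValueError("confidence outside [0, 1]")
        if not np.all(np.isfinite(self.coords[self.valid])):
            raise ValueError("non-finite coordinates at valid keypoints")


@dataclass
class Pose3D:
    """Per-frame 3D keypoints in millimetres.

    ``frame`` records whether coordinates are camera-frame or relative to
    the virtual pelvis root.
    """

    coords: np.ndarray          # (133, 3)
    frame: str = "camera"       # {"camera", "root_relative"}
    valid: np.ndarray = None    # (133,), bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.coords), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"bad 3D coords shape {self.coords.shape}")
        if self.frame not in ("camera", "root_relative"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if not np.all(np.isfinite(self.coords[self.valid])):
            raise ValueError("non-finite coordinates at valid keypoints")


def _load_layout_rows() -> list[dict]:
    with resources.files("cogpose.data").joinpath("layout.csv").open() as fh:
        return list(csv.DictReader(fh))


_LAYOUT_CACHE: dict = {}


def make_layout() -> KeypointLayout:
    """Return the fixed 133-keypoint whole-body layout.

    Idempotent; the table is read once from packaged data and cached.
    """
    if "layout" not in _LAYOUT_CACHE:
        rows = _load_layout_rows()
        names = tuple(r["name"] for r in rows)
        groups = [r["group"] for r in rows]
        idx = np.arange(len(rows))
        body = idx[np.isin(groups, ["body", "foot"])]
        face = idx[np.asarray(groups) == "face"]
        hands = idx[np.isin(groups, ["left_hand", "right_hand"])]
        part_groups = {
            "whole_body": idx,
            "body": body,
            "face": face,
            "hands": hands,
        }
        swap = np.asarray([int(r["swap"]) for r in rows])
        _LAYOUT_CACHE["layout"] = KeypointLayout(
            names=names,
            part_groups=part_groups,
            left_right_swap=swap,
            root_definition=(names.index("left_hip"), names.index("right_hip")),
            sides=tuple(r["side"] for r in rows),
        )
    return _LAYOUT_CACHE["layout"]


def make_bone_tree() -> BoneTree:
    """Return the packaged rooted bone tree (132 edges)."""
    if "tree" not in _LAYOUT_CACHE:
        rows = _load_layout_rows()
        parent = np.asarray([int(r["parent"]) for r in rows])
        children = np.flatnonzero(parent >= 0)
        edges = np.stack([parent[children], children], axis=1)
        _LAYOUT_CACHE["tree"] = BoneTree(parent=parent, edges=edges)
    return _LAYOUT_CACHE["tree"]


def root_center(pose, layout: KeypointLayout | None = None):
    """Express a pose relative to the virtual pelvis (mid-hip) root.

    Works on :class:`Pose2D` and :class:`Pose3D`; for 3D poses the frame
    tag becomes ``root_relative``. Raises :class:`MissingKeypointError`
    if either hip keypoint is invalid.
    """
    layout = layout or make_layout()
    lh, rh = layout.root_definition
    if not (pose.valid[lh] and pose.valid[rh]):
        raise MissingKeypointError(
            "cannot root-center: hip keypoint(s) invalid "
            f"(left_hip valid={bool(pose.valid[lh])}, "
            f"right_hip valid={bool(pose.valid[rh])})"
        )
    root = 0.5 * (pose.coords[lh] + pose.coords[rh])
    if isinstance(pose, Pose3D):
        return replace(pose, coords=pose.coords - root, frame="root_relative")
    return replace(pose, coords=pose.coords - root)


def flip_pose(pose, layout: KeypointLayout | None = None):
    """Mirror a pose laterally and swap left/right keypoint identities.

    Negates the first (lateral) coordinate and permutes keypoints by the
    layout's swap table; an involution.
    """
    layout = layout or make_layout()
    perm = layout.left_right_swap
    coords = pose.coords[perm].copy()
    coords[:, 0] = -coords[:, 0]
    if isinstance(pose, Pose3D):
        return replace(pose, coords=coords, valid=pose.valid[perm])
    return replace(
        pose, coords=coords, confidence=pose.confidence[perm],
        valid=pose.valid[perm],
    )


# --- COCO-style keypoint JSON -------------------------------------------

def write_coco_keypoints(path, poses: Sequence[Pose2D]) -> None:
    """Write 2D poses as COCO-style keypoint annotations (x, y, score)."""
    anns = []
    for i, p in enumerate(poses):
        trip = np.concatenate(
            [p.coords, np.where(p.valid, p.confidence, 0.0)[:, None]], axis=1
        )
        trip = np.where(np.isfinite(trip), trip, 0.0)
        anns.append({
            "id": i,
            "category": "wholebody",
            "num_keypoints": int(p.valid.sum()),
            "keypoints": [round(float(v), 6) for v in trip.ravel()],
        })
    with open(path, "w") as fh:
        json.dump({"annotations": anns}, fh)


def read_coco_keypoints(path) -> list[Pose2D]:
    """Read 2D poses from COCO-style keypoint JSON (inverse of the writer).

    A keypoint with score 0 is treated as missing.
    """
    with open(path) as fh:
        doc = json.load(fh)
    poses = []
    for ann in doc["annotations"]:
        trip = np.asarray(ann["keypoints"], dtype=float).reshape(-1, 3)
        poses.append(Pose2D(
            coords=trip[:, :2],
            confidence=trip[:, 2],
            valid=trip[:, 2] > 0,
        ))
    return poses
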