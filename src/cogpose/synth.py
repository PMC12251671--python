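"""Synthetic paired 2D/3D whole-body pose data.

The generator supplies the structural assumptions the lifting method
relies on, without imitating any motion-capture corpus: a kinematic tree
with constant limb lengths (fixed proportions of a sampled stature),
anatomically bounded joint articulation, rigid face and hand templates,
exact pinhole projection to 2D, Gaussian pixel noise, and occlusion
modeled as missingness (invalid mask + zero confidence).

Each skeleton (one sampled stature) yields several poses; benchmark
splits are disjoint by skeleton identity so that test subjects are never
seen in training. All randomness flows from one seeded generator; the
same seed reproduces coordinates bit for bit.
"""
from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .camera import CameraIntrinsics, project
from .skeleton import (BoneTree, Pose2D, Pose3D, make_bone_tree, make_layout)

__all__ = [
    "SynthConfig", "Sample", "sample_skeleton", "sample_pose3d",
    "render_sample", "make_dataset", "make_benchmark", "load_benchmark",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generation conditions for the synthetic benchmark."""

    n_train: int = 2000
    n_val: int = 400
    n_test: int = 400
    poses_per_skeleton: int = 10
    seed: int = 0
    stature_range_mm: tuple = (1500.0, 1900.0)
    fx_range: tuple = (1000.0, 1500.0)
    fy_range: tuple = (1000.0, 1500.0)
    depth_range_mm: tuple = (3000.0, 6000.0)
    lateral_range_mm: tuple = (-500.0, 500.0)
    noise_sigma_px: float = 1.0
    occlusion_prob: float = 0.05
    # single-camera capture: the subject roughly faces the camera, so the
    # learned pose prior can resolve the monocular depth-sign ambiguity
    yaw_range_deg: tuple = (-45.0, 45.0)
    # articulation bounds (degrees) — moderate daily-activity ranges
    elbow_flexion_deg: tuple = (0.0, 110.0)
    knee_flexion_deg: tuple = (0.0, 80.0)
    shoulder_max_deg: float = 60.0
    hip_max_deg: float = 40.0
    wrist_max_deg: float = 15.0
    neck_max_deg: float = 15.0
    torso_max_deg: float = 15.0
    # augmentation defaults consumed by the training pipeline
    rotation_deg: float = 15.0
    scale_range: tuple = (0.8, 1.2)
    flip_prob: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.occlusion_prob <= 1.0):
            raise ValueError("occlusion_prob must be in [0, 1]")
        for lo, hi in (self.stature_range_mm, self.depth_range_mm,
                       self.fx_range, self.fy_range):
            if hi < lo:
                raise ValueError("empty range in SynthConfig")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Sample:
    """One rendered observation: 2D input, 3D truth, camera, placement."""

    pose2d: Pose2D
    pose3d: Pose3D                # root-relative, mm
    camera: CameraIntrinsics
    root_position: np.ndarray     # camera-frame mid-hip position, mm
    skeleton_id: int = -1


def _proportions() -> dict:
    with resources.files("cogpose.data").joinpath(
            "body_proportions.csv").open() as fh:
        return {r["quantity"]: float(r["fraction_of_stature"])
                for r in csv.DictReader(fh)}


_PROP = None


def _prop() -> dict:
    global _PROP
    if _PROP is None:
        _PROP = _proportions()
    return _PROP


def _face_template(fw: float, fh: float) -> np.ndarray:
    """68 face landmarks (iBUG order) in a face-local frame, x lateral,
    y up, z forward; mirror-symmetric about x = 0."""
    pts = np.zeros((68, 3))
    for i in range(17):                                  # jaw
        pts[i] = [fw * np.cos(np.pi * (1 - i / 16.0)),
                  -fh * np.sin(np.pi * i / 16.0), 0.0]
    for k in range(5):                                   # brows
        arc = 0.05 * np.sin(np.pi * k / 4.0)
        pts[17 + k] = [-fw * (0.80 - 0.15 * k), fh * (0.45 + arc), 0.02 * fw]
        pts[26 - k] = [fw * (0.80 - 0.15 * k), fh * (0.45 + arc), 0.02 * fw]
    for k in range(4):                                   # nose bridge
        pts[27 + k] = [0.0, fh * (0.35 - 0.117 * k), 0.05 * fw * (1 + k / 3)]
    for k in range(5):                                   # nostrils
        pts[31 + k] = [(k - 2) * 0.08 * fw, -0.08 * fh, 0.05 * fw]
    eye = np.array([[-0.15, 0.0], [-0.07, 0.05], [0.05, 0.05],
                    [0.12, 0.0], [0.05, -0.05], [-0.07, -0.05]])
    mirror_of = [3, 2, 1, 0, 5, 4]        # iBUG left-eye point order
    for k, (ex, ey) in enumerate(eye):    # right eye 36-41
        pts[36 + k] = [(-0.45 + ex) * fw, (0.30 + ey) * fh, 0.01 * fw]
    for k in range(6):                    # left eye 42-47, mirrored
        src = pts[36 + mirror_of[k]]
        pts[42 + k] = [-src[0], src[1], src[2]]
    for j, (rx, ry) in enumerate([(0.35, 0.12), (0.20, 0.05)]):  # mouth rings
        base = 48 if j == 0 else 60
        n_top = 7 if j == 0 else 5
        n_bot = 5 if j == 0 else 3
        top = np.linspace(180, 0, n_top)
        bot = np.linspace(-(180 - 180 / (n_bot + 1)), -180 / (n_bot + 1),
                          n_bot)
        for k, ang in enumerate(np.concatenate([top, bot])):
            a = np.deg2rad(ang)
            pts[base + k] = [rx * fw * np.cos(a),
                             -0.35 * fh + ry * fh * np.sin(a), 0.03 * fw]
    return pts


def _hand_template(hl: float, direction: float) -> np.ndarray:
    """21 hand keypoints in a wrist-local frame; fingers along x."""
    pts = np.zeros((21, 3))
    spreads = [0.25, 0.12, 0.0, -0.12, -0.22]
    scales = [0.55, 0.95, 1.0, 0.95, 0.85]
    fracs = [0.4, 0.6, 0.8, 1.0]
    for f in range(5):
        for k, frac in enumerate(fracs):
            pts[1 + 4 * f + k] = [direction * hl * frac * scales[f],
                                  0.0, spreads[f] * hl]
    return pts


def _template(stature: float) -> np.ndarray:
    """Canonical T-pose (y up, facing +z), mm; mirror-symmetric."""
    p = _prop()
    s = stature
    hw, sw = p["hip_halfwidth"] * s, p["shoulder_halfwidth"] * s
    hip_h, knee_h = p["hip_height"] * s, p["knee_height"] * s
    ank_h, sho_h = p["ankle_height"] * s, p["shoulder_height"] * s
    ua, fa, hl = (p["upper_arm_length"] * s, p["forearm_length"] * s,
                  p["hand_length"] * s)
    t = np.zeros((133, 3))
    t[11], t[12] = [hw, hip_h, 0], [-hw, hip_h, 0]
    t[13], t[14] = [hw, knee_h, 0], [-hw, knee_h, 0]
    t[15], t[16] = [hw, ank_h, 0], [-hw, ank_h, 0]
    toe_f = (p["foot_length"] - p["heel_offset"]) * s
    for sgn, (bt, st, he) in (((1), (17, 18, 19)), ((-1), (20, 21, 22))):
        t[bt] = [sgn * hw, 0, toe_f]
        t[st] = [sgn * (hw + 0.025 * s), 0, 0.8 * toe_f]
        t[he] = [sgn * hw, 0, -p["heel_offset"] * s]
    t[5], t[6] = [sw, sho_h, 0], [-sw, sho_h, 0]
    t[7], t[8] = [sw + ua, sho_h, 0], [-(sw + ua), sho_h, 0]
    t[9], t[10] = [sw + ua + fa, sho_h, 0], [-(sw + ua + fa), sho_h, 0]
    t[0] = [0, p["nose_height"] * s, 0.05 * s]
    t[1], t[2] = ([p["eye_halfspacing"] * s, p["eye_height"] * s, 0.045 * s],
                  [-p["eye_halfspacing"] * s, p["eye_height"] * s, 0.045 * s])
    t[3], t[4] = ([p["face_halfwidth"] * s, p["ear_height"] * s, 0],
                  [-p["face_halfwidth"] * s, p["ear_height"] * s, 0])
    face = _face_template(p["face_halfwidth"] * s, p["face_height"] * s)
    t[23:91] = face + t[0]
    t[91:112] = _hand_template(hl, +1.0) + t[9]
    t[112:133] = _hand_template(hl, -1.0) + t[10]
    return t


def sample_skeleton(cfg: SynthConfig, rng: np.random.Generator) -> dict:
    """Draw one skeleton: a stature and its limb-length table (mm).

    Lengths are fixed proportions of the stature, identical left and
    right, so every pose generated from this skeleton has constant limb
    lengths.
    """
    p = _prop()
    s = float(rng.uniform(*cfg.stature_range_mm))
    lengths = {
        "thigh": (p["hip_height"] - p["knee_height"]) * s,
        "calf": (p["knee_height"] - p["ankle_height"]) * s,
        "torso": (p["shoulder_height"] - p["hip_height"]) * s,
        "head": (1.0 - p["shoulder_height"]) * s,
        "ankle_height": p["ankle_height"] * s,
        "upper_arm": p["upper_arm_length"] * s,
        "forearm": p["forearm_length"] * s,
        "hand": p["hand_length"] * s,
        "foot": p["foot_length"] * s,
    }
    for side in ("left", "right"):
        for seg in ("thigh", "calf", "upper_arm", "forearm", "hand", "foot"):
            lengths[f"{side}_{seg}"] = lengths[seg]
    return {"stature": s, "lengths": lengths, "template": _template(s)}


def _rot_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rotate_group(coords, idx, pivot_idx, R):
    pivot = coords[pivot_idx]
    coords[idx] = (coords[idx] - pivot) @ R.T + pivot


# articulation groups: (moved keypoints, pivot keypoint); chosen so that
# every skeleton bone keeps its length under any group rotation
_L_HAND = list(range(91, 112))
_R_HAND = list(range(112, 133))
_ARTICULATION = {
    "left_arm": ([7, 9] + _L_HAND, 5),
    "left_forearm": ([9] + _L_HAND, 7),
    "left_hand": (_L_HAND, 9),
    "right_arm": ([8, 10] + _R_HAND, 6),
    "right_forearm": ([10] + _R_HAND, 8),
    "right_hand": (_R_HAND, 10),
    "left_leg": ([13, 15, 17, 18, 19], 11),
    "left_lower_leg": ([15, 17, 18, 19], 13),
    "right_leg": ([14, 16, 20, 21, 22], 12),
    "right_lower_leg": ([16, 20, 21, 22], 14),
    "head": ([1, 2, 3, 4] + list(range(23, 91)), 0),
}


def _random_axis(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _perp_axis(direction, rng) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    v = rng.standard_normal(3)
    v -= d * (v @ d)
    n = np.linalg.norm(v)
    if n < 1e-9:
        v = np.cross(d, [1.0, 0.0, 0.0])
        n = np.linalg.norm(v)
    return v / n


def sample_pose3d(skeleton: dict, cfg: SynthConfig,
                  rng: np.random.Generator, articulate: bool = True,
                  tree: BoneTree | None = None) -> Pose3D:
    """Articulate the skeleton's template into a random plausible pose.

    Joint rotations are rigid on tree subtrees, so bone lengths match the
    skeleton table exactly; elbow/knee flexion stays within the configured
    anatomical ranges. With ``articulate=False`` the canonical template is
    returned. Output is y-up, mm, ``frame='camera'`` (placement relative
    to a camera happens in :func:`render_sample`).
    """
    tree = tree or make_bone_tree()
    coords = skeleton["template"].copy()
    if not articulate:
        return Pose3D(coords=coords, frame="camera")
    d2r = np.deg2rad
    art = _ARTICULATION
    # torso: small rigid rotation about the mid-hip
    mid_hip = 0.5 * (coords[11] + coords[12])
    R = _rot_axis(_random_axis(rng), d2r(rng.uniform(0, cfg.torso_max_deg)))
    coords = (coords - mid_hip) @ R.T + mid_hip
    R = _rot_axis(_random_axis(rng), d2r(rng.uniform(0, cfg.neck_max_deg)))
    _rotate_group(coords, *art["head"], R)
    for side in ("left", "right"):
        sho, elb = (5, 7) if side == "left" else (6, 8)
        hip, kne = (11, 13) if side == "left" else (12, 14)
        R = _rot_axis(_random_axis(rng),
                      d2r(rng.uniform(0, cfg.shoulder_max_deg)))
        _rotate_group(coords, *art[f"{side}_arm"], R)
        axis = _perp_axis(coords[elb] - coords[sho], rng)
        R = _rot_axis(axis, d2r(rng.uniform(*cfg.elbow_flexion_deg)))
        _rotate_group(coords, *art[f"{side}_forearm"], R)
        R = _rot_axis(_random_axis(rng),
                      d2r(rng.uniform(0, cfg.wrist_max_deg)))
        _rotate_group(coords, *art[f"{side}_hand"], R)
        R = _rot_axis(_random_axis(rng), d2r(rng.uniform(0, cfg.hip_max_deg)))
        _rotate_group(coords, *art[f"{side}_leg"], R)
        axis = _perp_axis(coords[kne] - coords[hip], rng)
        R = _rot_axis(axis, d2r(rng.uniform(*cfg.knee_flexion_deg)))
        _rotate_group(coords, *art[f"{side}_lower_leg"], R)
    return Pose3D(coords=coords, frame="camera")


def render_sample(pose3d: Pose3D, cfg: SynthConfig,
                  rng: np.random.Generator, skeleton_id: int = -1,
                  max_retries: int = 20) -> Sample:
    """Place a pose in front of a random pinhole camera and observe it.

    The pose is yawed about the vertical axis, translated to a random
    depth, projected exactly, then corrupted with Gaussian pixel noise.
    Occluded keypoints (never the hips, which anchor root normalization)
    are zeroed with confidence 0 and ``valid=False``. Ground truth is
    stored root-relative in mm.
    """
    layout = make_layout()
    cam = CameraIntrinsics(fx=float(rng.uniform(*cfg.fx_range)),
                           fy=float(rng.uniform(*cfg.fy_range)))
    base = pose3d.coords.copy()
    # template frame is y-up; cameras look along +z with y down
    base = base * np.array([1.0, -1.0, 1.0])
    mid_hip = 0.5 * (base[11] + base[12])
    for attempt in range(max_retries):
        yaw = np.deg2rad(rng.uniform(*cfg.yaw_range_deg))
        R = _rot_axis(np.array([0.0, 1.0, 0.0]), yaw)
        coords = (base - mid_hip) @ R.T
        root = np.array([rng.uniform(*cfg.lateral_range_mm),
                         rng.uniform(*cfg.lateral_range_mm),
                         rng.uniform(*cfg.depth_range_mm)])
        coords_cam = coords + root
        if np.all(coords_cam[:, 2] > 100.0):
            break
    else:
        raise RuntimeError("could not place the subject in front of the "
                           f"camera after {max_retries} attempts")
    uv = project(coords_cam, cam)
    uv = uv + rng.normal(0.0, cfg.noise_sigma_px, uv.shape)
    occluded = rng.random(len(uv)) < cfg.occlusion_prob
    occluded[list(layout.root_definition)] = False
    valid = ~occluded
    conf = np.where(valid, rng.uniform(0.6, 1.0, len(uv)), 0.0)
    uv = np.where(valid[:, None], uv, 0.0)
    pose2d = Pose2D(coords=uv, confidence=conf, valid=valid)
    gt = Pose3D(coords=coords_cam - root, frame="root_relative")
    return Sample(pose2d=pose2d, pose3d=gt, camera=cam,
                  root_position=root, skeleton_id=skeleton_id)


def make_dataset(cfg: SynthConfig, n: int, rng: np.random.Generator,
                 skeleton_id_start: int = 0) -> dict:
    """Generate ``n`` samples as flat arrays (one split)."""
    nk = 133
    out = {
        "kp2d": np.zeros((n, nk, 2)), "kp3d": np.zeros((n, nk, 3)),
        "conf": np.zeros((n, nk)), "valid": np.zeros((n, nk), bool),
        "camera": np.zeros((n, 4)), "root": np.zeros((n, 3)),
        "skeleton_id": np.zeros(n, int),
    }
    sk, sk_id = None, skeleton_id_start - 1
    for i in range(n):
        if i % cfg.poses_per_skeleton == 0:
            sk = sample_skeleton(cfg, rng)
            sk_id += 1
        pose = sample_pose3d(sk, cfg, rng)
        s = render_sample(pose, cfg, rng, skeleton_id=sk_id)
        out["kp2d"][i] = s.pose2d.coords
        out["kp3d"][i] = s.pose3d.coords
        out["conf"][i] = s.pose2d.confidence
        out["valid"][i] = s.pose2d.valid
        out["camera"][i] = [s.camera.fx, s.camera.fy, s.camera.cx, s.camera.cy]
        out["root"][i] = s.root_position
        out["skeleton_id"][i] = sk_id
    return out


def make_benchmark(cfg: SynthConfig, out_dir=None, force: bool = False
                   ) -> dict:
    """Generate the train/val/test benchmark; optionally write to disk.

    Splits are disjoint by skeleton identity. Regeneration with the same
    config is byte-identical. Returns ``{"train": ..., "val": ...,
    "test": ..., "manifest": ...}``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(3)
    sizes = {"train": cfg.n_train, "val": cfg.n_val, "test": cfg.n_test}
    splits, start = {}, 0
    for (name, n), child in zip(sizes.items(), seeds):
        splits[name] = make_dataset(cfg, n, np.random.default_rng(child),
                                    skeleton_id_start=start)
        start += int(np.ceil(n / cfg.poses_per_skeleton))
    manifest = {"counts": sizes, "seed": cfg.seed, "config_hash": cfg.hash(),
                "config": asdict(cfg)}
    splits["manifest"] = manifest
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in sizes:
            path = out / f"{name}.npz"
            if path.exists() and not force:
                raise FileExistsError(f"{path} exists; use force to overwrite")
            np.savez_compressed(path, **splits[name])
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return splits


def load_benchmark(in_dir) -> dict:
    """Read a benchmark written by :func:`make_benchmark`."""
    out = {}
    src = Path(in_dir)
    for name in ("train", "val", "test"):
        with np.load(src / f"{name}.npz") as z:
            out[name] = {k: z[k] for k in z.files}
    out["manifest"] = json.loads((src / "manifest.json").read_text())
    return out
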