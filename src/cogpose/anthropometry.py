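"""Body-segment mass tables and center-of-gravity moment synthesis.

The body is divided into 15 rigid segments (head+neck, upper and lower
torso, and left/right thigh, calf, upper arm, forearm, hand, foot). Each
segment carries a relative mass coefficient ``k`` (fraction of total body
mass) and a centroid position expressed as the proximal/distal split of
its length (``Les``/``Lex``, summing to 100%). These gender-specific
coefficients follow the Chinese national standard "Inertial Parameters of
Adult Human Body" and are shipped as packaged CSV data.

Whole-body center of gravity (CoG) is computed by moment synthesis: each
segment's centroid is the convex combination of its proximal and distal
endpoints, and the body CoG is the mass-weighted sum of segment centroids

    X_CoG = sum_i k_i * x_i   (likewise Y, Z).

Because every step is linear in the keypoint coordinates, the whole
pipeline collapses to a single 133-vector of per-keypoint weights
(:func:`cog_weight_vector`), which is also what the training loss uses.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .skeleton import KeypointLayout, Pose3D, make_layout

__all__ = [
    "SegmentSpec",
    "AnthropometricTable",
    "CoGPoint",
    "SEGMENT_ENDPOINTS",
    "load_table",
    "segment_cog",
    "cog_weight_vector",
    "body_cog",
]

# Segment endpoint definitions in terms of layout keypoint names.
# An endpoint given as several names is the mean of those keypoints;
# "mid_torso" (the midpoint of mean-shoulders and mean-hips) is therefore
# the plain mean of the four shoulder/hip keypoints.
SEGMENT_ENDPOINTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "neck": (("left_shoulder", "right_shoulder"),
             ("nose", "left_ear", "right_ear")),
    "upper_torso": (("left_shoulder", "right_shoulder"),
                    ("left_shoulder", "right_shoulder",
                     "left_hip", "right_hip")),
    "lower_torso": (("left_shoulder", "right_shoulder",
                     "left_hip", "right_hip"),
                    ("left_hip", "right_hip")),
    "left_thigh": (("left_hip",), ("left_knee",)),
    "right_thigh": (("right_hip",), ("right_knee",)),
    "left_calf": (("left_knee",), ("left_ankle",)),
    "right_calf": (("right_knee",), ("right_ankle",)),
    "left_upper_arm": (("left_shoulder",), ("left_elbow",)),
    "right_upper_arm": (("right_shoulder",), ("right_elbow",)),
    "left_forearm": (("left_elbow",), ("left_wrist",)),
    "right_forearm": (("right_elbow",), ("right_wrist",)),
    "left_hand": (("left_wrist",), ("left_hand_12",)),
    "right_hand": (("right_wrist",), ("right_hand_12",)),
    "left_foot": (("left_ankle",), ("left_big_toe", "left_small_toe")),
    "right_foot": (("right_ankle",), ("right_big_toe", "right_small_toe")),
}

_BILATERAL = ("thigh", "calf", "upper_arm", "forearm", "hand", "foot")


class MissingSegmentError(ValueError):
    """Segment endpoints required for CoG synthesis are invalid."""


@dataclass(frozen=True)
class SegmentSpec:
    """One rigid body segment with mass and centroid coefficients.

    ``centroid_les`` is the fraction of segment length from the proximal
    end to the centroid; ``centroid_lex`` the complementary distal
    fraction (les + lex = 1).
    """

    name: str
    proximal_joints: tuple
    distal_joints: tuple
    mass_fraction: float
    centroid_les: float
    centroid_lex: float

    def __post_init__(self):
        if abs(self.centroid_les + self.centroid_lex - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: les + lex must equal 1")
        if self.mass_fraction <= 0:
            raise ValueError(f"{self.name}: mass fraction must be positive")


@dataclass(frozen=True)
class AnthropometricTable:
    """The 15-segment mass/centroid table for one gender."""

    gender: str
    segments: tuple  # of SegmentSpec

    def __post_init__(self):
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 5e-4:
            raise ValueError(
                f"mass fractions sum to {total:.5f}, expected 1 within 5e-4"
            )

    def segment(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class CoGPoint:
    """A center-of-gravity position (mm, same frame as the input pose)."""

    coords: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite CoG")


def _read_packaged(name: str) -> list[dict]:
    with resources.files("cogpose.data").joinpath(name).open() as fh:
        return list(csv.DictReader(fh))


def raw_mass_percentages(gender: str) -> dict[str, float]:
    """Per-segment relative mass in percent, as printed (one side only)."""
    return {r["segment"]: float(r["percent"])
            for r in _read_packaged("mass_fractions.csv")
            if r["gender"] == gender}


def raw_centroid_percentages(gender: str) -> dict[str, tuple[float, float]]:
    """Per-segment (Les, Lex) centroid split in percent, as printed."""
    return {r["segment"]: (float(r["les"]), float(r["lex"]))
            for r in _read_packaged("centroid_positions.csv")
            if r["gender"] == gender}


def load_table(gender: str = "M", renormalize: bool = True,
               lp_is_les: bool = False) -> AnthropometricTable:
    """Build the 15-segment anthropometric table for a gender.

    Parameters
    ----------
    gender : {"M", "F"}
    renormalize : bool
        Rescale mass fractions to sum exactly to 1 (the printed values sum
        to 99.99% / 100.01%). Keeps the CoG an exact convex combination.
    lp_is_les : bool
        Centroid convention switch. By default the centroid lies ``Les``
        of the way from the proximal end, i.e. the coefficient multiplying
        the proximal coordinate is ``Lex`` and the distal coordinate
        ``Les``. Setting this flips the convention.
    """
    if gender not in ("M", "F"):
        raise ValueError(f"unknown gender {gender!r}; expected 'M' or 'F'")
    mass = raw_mass_percentages(gender)
    cent = raw_centroid_percentages(gender)

    entries: dict[str, float] = {}
    for seg, pct in mass.items():
        if seg in _BILATERAL:
            entries[f"left_{seg}"] = pct / 100.0
            entries[f"right_{seg}"] = pct / 100.0
        else:
            entries[seg] = pct / 100.0
    total = sum(entries.values())
    scale = 1.0 / total if renormalize else 1.0

    segments = []
    for name, frac in entries.items():
        base = name.removeprefix("left_").removeprefix("right_")
        les, lex = (v / 100.0 for v in cent[base])
        if lp_is_les:
            les, lex = lex, les
        prox, dist = SEGMENT_ENDPOINTS[name]
        segments.append(SegmentSpec(
            name=name, proximal_joints=prox, distal_joints=dist,
            mass_fraction=frac * scale, centroid_les=les, centroid_lex=lex,
        ))
    return AnthropometricTable(gender=gender, segments=tuple(segments))


def _endpoint(pose: Pose3D, joints: Sequence[str],
              layout: KeypointLayout, segment: str) -> np.ndarray:
    idx = [layout.index(j) for j in joints]
    if not np.all(pose.valid[idx]):
        bad = [j for j in joints if not pose.valid[layout.index(j)]]
        raise MissingSegmentError(
            f"segment {segment!r}: invalid endpoint keypoint(s) {bad}"
        )
    return pose.coords[idx].mean(axis=0)


def segment_cog(pose: Pose3D, spec: SegmentSpec,
                layout: KeypointLayout | None = None) -> CoGPoint:
    """Centroid of one segment: ``prox * lex + dist * les``.

    The centroid lies ``les`` of the segment length from the proximal
    endpoint, hence always on the segment between the two endpoints.
    """
    layout = layout or make_layout()
    p = _endpoint(pose, spec.proximal_joints, layout, spec.name)
    d = _endpoint(pose, spec.distal_joints, layout, spec.name)
    return CoGPoint(p * spec.centroid_lex + d * spec.centroid_les)


def cog_weight_vector(table: AnthropometricTable,
                      layout: KeypointLayout | None = None) -> np.ndarray:
    """Collapse moment synthesis into one per-keypoint weight vector.

    Returns ``w`` (length 133) such that the whole-body CoG of any pose
    ``P`` is ``w @ P``. Weights are nonnegative and sum to 1 (so the CoG
    is a convex combination of segment-endpoint keypoints); keypoints that
    are not segment endpoints get weight 0.
    """
    layout = layout or make_layout()
    w = np.zeros(layout.n_keypoints)
    for spec in table.segments:
        for joints, coeff in ((spec.proximal_joints, spec.centroid_lex),
                              (spec.distal_joints, spec.centroid_les)):
            share = spec.mass_fraction * coeff / len(joints)
            for j in joints:
                w[layout.index(j)] += share
    return w


def body_cog(pose: Pose3D, table: AnthropometricTable,
             layout: KeypointLayout | None = None,
             renormalize_missing: bool = False) -> CoGPoint:
    """Whole-body CoG by mass-weighted synthesis of segment centroids.

    Equals ``cog_weight_vector(table) @ pose.coords`` when all endpoints
    are valid; translation- and rotation-equivariant.

    With ``renormalize_missing`` the synthesis falls back to the segments
    whose endpoints are all valid, renormalizing their mass fractions;
    otherwise a missing endpoint raises :class:`MissingSegmentError`
    naming the affected segments.
    """
    layout = layout or make_layout()
    acc = np.zeros(3)
    used_mass = 0.0
    missing = []
    for spec in table.segments:
        try:
            c = segment_cog(pose, spec, layout)
        except MissingSegmentError:
            missing.append(spec.name)
            continue
        acc += spec.mass_fraction * c.coords
        used_mass += spec.mass_fraction
    if missing and not renormalize_missing:
        raise MissingSegmentError(
            f"cannot synthesize CoG; missing segments: {missing}"
        )
    if used_mass == 0.0:
        raise MissingSegmentError("no segment has valid endpoints")
    return CoGPoint(acc / used_mass)
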