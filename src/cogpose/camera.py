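"""Pinhole camera geometry and the constant-limb-length depth relation.

The pinhole model links a camera-frame 3D point ``(x, y, z)`` (mm) to its
pixel projection ``(u, v)`` through ``u = fx * x / z + cx`` and
``v = fy * y / z + cy``. By default the principal point is the origin, so
2D keypoints are stored relative to it.

Monocular lifting is ambiguous in depth, but a known limb length ``L``
between two keypoints pins the relative depth of one endpoint against the
other: substituting the backprojection of both pixels into
``dx^2 + dy^2 + dz^2 = L^2`` yields a quadratic in the depth offset ``dz``
with zero, one or two real solutions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "project",
    "backproject",
    "depth_offsets_from_limb_length",
]


class BehindCameraError(ValueError):
    """A point with non-positive depth cannot be projected."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point, pixels."""

    fx: float
    fy: float
    cx: float = 0.0
    cy: float = 0.0

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    def to_dict(self) -> dict:
        return {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(**{k: float(d.get(k, 0.0)) for k in ("fx", "fy", "cx", "cy")})


def project(point: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame 3D points (mm) to pixels.

    Accepts a single 3-vector or an ``(..., 3)`` array. Raises
    :class:`BehindCameraError` for any ``z <= 0``.
    """
    p = np.asarray(point, dtype=float)
    z = p[..., 2]
    if np.any(z <= 0):
        raise BehindCameraError("point(s) with z <= 0 cannot be projected")
    u = cam.fx * p[..., 0] / z + cam.cx
    v = cam.fy * p[..., 1] / z + cam.cy
    return np.stack([u, v], axis=-1)


def backproject(uv: np.ndarray, z, cam: CameraIntrinsics) -> np.ndarray:
    """Invert the projection at a known depth ``z`` (mm).

    ``project(backproject(uv, z), cam)`` returns ``uv`` exactly (to
    floating-point precision).
    """
    uv = np.asarray(uv, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise BehindCameraError("depth must be positive")
    x = (uv[..., 0] - cam.cx) * z / cam.fx
    y = (uv[..., 1] - cam.cy) * z / cam.fy
    return np.stack([x, y, np.broadcast_to(z, uv[..., 0].shape)], axis=-1)


def depth_offsets_from_limb_length(uv1, uv2, z1: float, L: float,
                                   cam: CameraIntrinsics,
                                   return_filtered: bool = False):
    """Depth offsets of keypoint 2 consistent with a limb of length ``L``.

    Given pixel observations ``uv1``, ``uv2`` of two skeletally adjacent
    keypoints, the depth ``z1`` of the first, and the limb length ``L``
    (mm), solve for all real offsets ``dz`` such that keypoint 2 at depth
    ``z1 + dz`` lies exactly ``L`` from keypoint 1 in 3D:

        dx = u1*z1/fx - u2*(z1+dz)/fx,  dy likewise,
        dx^2 + dy^2 + dz^2 = L^2.

    Returns the real roots with ``z1 + dz > 0``, sorted by ``|dz|``
    ascending (smallest depth correction first). A negative discriminant
    (no 3D configuration of length ``L`` projects to these pixels) gives
    an empty array. With ``return_filtered`` the roots discarded for
    landing behind the camera are returned as a second array.
    """
    if z1 <= 0:
        raise BehindCameraError("z1 must be positive")
    if L <= 0:
        raise ValueError("limb length must be positive")
    u1, v1 = (np.asarray(uv1, float) - (cam.cx, cam.cy))
    u2, v2 = (np.asarray(uv2, float) - (cam.cx, cam.cy))
    # dx = a1 - b1*dz, dy = a2 - b2*dz
    a1, b1 = (u1 - u2) * z1 / cam.fx, u2 / cam.fx
    a2, b2 = (v1 - v2) * z1 / cam.fy, v2 / cam.fy
    A = b1 * b1 + b2 * b2 + 1.0
    B = -2.0 * (a1 * b1 + a2 * b2)
    C = a1 * a1 + a2 * a2 - L * L
    disc = B * B - 4.0 * A * C
    if disc < 0:
        roots = np.empty(0)
    else:
        s = np.sqrt(disc)
        roots = np.asarray([(-B - s) / (2 * A), (-B + s) / (2 * A)])
    keep = roots[z1 + roots > 0]
    keep = keep[np.argsort(np.abs(keep), kind="stable")]
    if return_filtered:
        return keep, roots[z1 + roots <= 0]
    return keep
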