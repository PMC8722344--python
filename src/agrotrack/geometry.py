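"""Pinhole projection, rigid transforms, and mask reprojection.

Conventions
-----------
* Pixel grid is 0-based; a pixel coordinate is ``(u, v) = (column, row)``
  and continuous coordinates refer to pixel centers.
* Camera frame: +x right, +y down, +z forward (depth).
* Depth value 0 marks missing data and is never back-projected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "RigidPose",
    "FrameTransform",
    "DegeneratePointError",
    "InvalidDepthError",
    "project",
    "backproject",
    "relative_camera_transform",
    "reproject_mask",
]


class DegeneratePointError(ValueError):
    """Raised when a point with non-positive depth is projected."""


class InvalidDepthError(ValueError):
    """Raised when a pixel with non-positive depth is back-projected."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point, in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(
            fx=float(d["fx"]), fy=float(d["fy"]),
            cx=float(d["cx"]), cy=float(d["cy"]),
            width=int(d["width"]), height=int(d["height"]),
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height,
        }


def _check_rotation(R: np.ndarray) -> None:
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation must be orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation must have determinant +1")


@dataclass(frozen=True)
class RigidPose:
    """A rigid transform (rotation + translation), meters.

    Acts on points as ``p' = R @ p + t``.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(3))
        _check_rotation(self.rotation)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls()

    @classmethod
    def from_matrix(cls, T: np.ndarray) -> "RigidPose":
        T = np.asarray(T, dtype=float).reshape(4, 4)
        return cls(rotation=T[:3, :3], translation=T[:3, 3])

    def matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.translation
        return T

    def inverse(self) -> "RigidPose":
        Rt = self.rotation.T
        return RigidPose(rotation=Rt, translation=-Rt @ self.translation)

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return ``self ∘ other`` (apply *other* first, then *self*)."""
        return RigidPose(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of points (or a single 3-vector)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out


@dataclass(frozen=True)
class FrameTransform:
    """Rigid map taking points expressed in camera frame *i* to camera frame *j*."""

    pose: RigidPose

    @classmethod
    def identity(cls) -> "FrameTransform":
        return cls(RigidPose.identity())

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.pose.apply(points)

    def compose(self, other: "FrameTransform") -> "FrameTransform":
        """``self ∘ other``: other maps i→j, self maps j→k; result maps i→k."""
        return FrameTransform(self.pose.compose(other.pose))


def project(point: np.ndarray, K: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame point(s) (meters) to continuous pixel coordinates.

    Returns ``(u, v)`` with ``u = fx*x/z + cx`` and ``v = fy*y/z + cy``.
    Accepts a 3-vector or an (N, 3) array. Rounding to the integer grid is
    the caller's concern.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    z = pts[:, 2]
    if np.any(z <= 0):
        raise DegeneratePointError("cannot project points with non-positive depth")
    u = K.fx * pts[:, 0] / z + K.cx
    v = K.fy * pts[:, 1] / z + K.cy
    uv = np.stack([u, v], axis=1)
    return uv[0] if single else uv


def backproject(pixel: np.ndarray, depth: np.ndarray | float,
                K: CameraIntrinsics) -> np.ndarray:
    """Back-project pixel(s) with metric depth to camera-frame 3D points.

    ``x = (u - cx) * d / fx``, ``y = (v - cy) * d / fy``, ``z = d``.
    """
    px = np.asarray(pixel, dtype=float)
    single = px.ndim == 1
    px = np.atleast_2d(px)
    d = np.broadcast_to(np.asarray(depth, dtype=float), px.shape[:1])
    if np.any(d <= 0):
        raise InvalidDepthError("cannot back-project non-positive depth")
    x = (px[:, 0] - K.cx) * d / K.fx
    y = (px[:, 1] - K.cy) * d / K.fy
    pts = np.stack([x, y, d], axis=1)
    return pts[0] if single else pts


def relative_camera_transform(W_i: RigidPose, W_j: RigidPose,
                              E: RigidPose) -> FrameTransform:
    """Relative camera motion between frames i and j from wheel odometry.

    ``W_i`` and ``W_j`` are world-from-body odometry poses; ``E`` maps the
    camera frame to the odometry body frame.  The returned transform is the
    exact conjugation ``E⁻¹ · (W_j⁻¹ W_i) · E`` and maps points expressed in
    camera frame *i* into camera frame *j*.
    """
    W_ij = W_j.inverse().compose(W_i)
    return FrameTransform(E.inverse().compose(W_ij).compose(E))


def reproject_mask(pixels: np.ndarray, depth_values: np.ndarray,
                   H: FrameTransform, K: CameraIntrinsics) -> np.ndarray:
    """Warp mask pixels from frame i into frame j using per-pixel depth.

    Parameters
    ----------
    pixels : (N, 2) int array of (u, v) coordinates in frame i.
    depth_values : (N,) metric depths aligned with *pixels*; entries <= 0 are
        treated as missing and dropped.
    H : transform taking frame-i points to frame j.
    K : shared intrinsics of both frames.

    Returns
    -------
    (M, 2) int array of unique (u, v) coordinates in frame j.  Pixels that
    land outside the image bounds are dropped; an empty result is a valid
    (empty) mask, not an error.
    """
    pixels = np.asarray(pixels)
    depth_values = np.asarray(depth_values, dtype=float)
    valid = depth_values > 0
    if not np.any(valid):
        return np.empty((0, 2), dtype=np.int64)
    pts = backproject(pixels[valid].astype(float), depth_values[valid], K)
    pts = H.apply(pts)
    in_front = pts[:, 2] > 0
    if not np.any(in_front):
        return np.empty((0, 2), dtype=np.int64)
    uv = project(pts[in_front], K)
    # nearest-integer rounding, ties to even (np.rint)
    ij = np.rint(uv).astype(np.int64)
    inside = (
        (ij[:, 0] >= 0) & (ij[:, 0] < K.width)
        & (ij[:, 1] >= 0) & (ij[:, 1] < K.height)
    )
    ij = ij[inside]
    if ij.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(ij, axis=0)
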