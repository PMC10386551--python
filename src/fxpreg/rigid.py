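"""Rigid 2-D transform algebra in homogeneous coordinates, and image warping.

A rigid motion in the plane has three degrees of freedom: a rotation angle
(degrees, positive = counterclockwise) and two translations (pixels).  All
transforms are represented as 3x3 homogeneous matrices acting on column
vectors ``(x, y, 1)``, with the convention that ``(x, y)`` is
``(column, row)``, indices are 0-based, and pixel centers sit at integer
coordinates.

The parameterization used throughout the package is *rotate about a given
center, then translate*::

    T(p) = translation(dx, dy) @ rotation(rot_deg, center)

Warping is done by inverse mapping with bilinear interpolation and zero fill
outside the source frame, the standard choice for registration resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidParams",
    "NORM_DIVISORS",
    "translation_matrix",
    "rotation_matrix",
    "params_to_matrix",
    "matrix_to_params",
    "compose",
    "invert",
    "is_rigid",
    "warp_image",
]

#: Normalization divisors mapping (rot_deg, dx_px, dy_px) onto [-1, 1]^3.
#: They equal the generation bounds of the pair generator: |rot| <= 11 deg,
#: |dx|, |dy| <= 10 px.
NORM_DIVISORS = np.array([11.0, 10.0, 10.0])


@dataclass(frozen=True)
class RigidParams:
    """The 3-DOF rigid transform: rotation (deg, CCW) and translation (px)."""

    rot_deg: float
    dx_px: float
    dy_px: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("rigid parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.rot_deg, self.dx_px, self.dy_px], dtype=float)

    def normalized(self) -> np.ndarray:
        """Map to network target space: (rot/11, dx/10, dy/10)."""
        return self.as_array() / NORM_DIVISORS

    @staticmethod
    def from_normalized(v) -> "RigidParams":
        """Inverse of :meth:`normalized` (exact)."""
        v = np.asarray(v, dtype=float) * NORM_DIVISORS
        return RigidParams(*v)


def _check_finite(*vals: float) -> None:
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("transform arguments must be finite")


def translation_matrix(dx: float, dy: float) -> np.ndarray:
    """Homogeneous matrix of the translation by (dx, dy) pixels."""
    _check_finite(dx, dy)
    m = np.eye(3)
    m[0, 2] = dx
    m[1, 2] = dy
    return m


def rotation_matrix(theta_deg: float, center=(0.0, 0.0)) -> np.ndarray:
    """Rotation by ``theta_deg`` (CCW) about ``center`` = (cx, cy).

    Conjugation of the origin rotation by translations to and from the
    center: ``Tr(c) @ R(theta) @ Tr(-c)``.
    """
    cx, cy = float(center[0]), float(center[1])
    _check_finite(theta_deg, cx, cy)
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    r = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return translation_matrix(cx, cy) @ r @ translation_matrix(-cx, -cy)


def compose(*mats: np.ndarray) -> np.ndarray:
    """Matrix product, applied right-to-left like function composition."""
    out = np.eye(3)
    for m in mats:
        out = out @ m
    return out


def params_to_matrix(p: RigidParams, center=(0.0, 0.0)) -> np.ndarray:
    """Rotate about ``center`` then translate: ``Tr(dx,dy) @ R(rot, center)``."""
    return translation_matrix(p.dx_px, p.dy_px) @ rotation_matrix(
        p.rot_deg, center
    )


def is_rigid(T: np.ndarray, tol: float = 1e-6) -> bool:
    """True if T is homogeneous with an orthonormal, det=+1 upper block."""
    T = np.asarray(T, dtype=float)
    if T.shape != (3, 3) or not np.all(np.isfinite(T)):
        return False
    if not np.allclose(T[2], [0.0, 0.0, 1.0], atol=tol):
        return False
    R = T[:2, :2]
    return bool(
        np.allclose(R @ R.T, np.eye(2), atol=tol)
        and np.isclose(np.linalg.det(R), 1.0, atol=tol)
    )


def matrix_to_params(T: np.ndarray, center=(0.0, 0.0)) -> RigidParams:
    """Recover (rot_deg, dx, dy) such that ``params_to_matrix`` rebuilds T.

    The angle is reported in (-180, 180].
    """
    T = np.asarray(T, dtype=float)
    if not is_rigid(T):
        raise ValueError("matrix is not a rigid homogeneous transform")
    theta = np.arctan2(T[1, 0], T[0, 0])
    rot_deg = float(np.rad2deg(theta))
    if rot_deg <= -180.0:
        rot_deg += 360.0
    # T = Tr(d) @ R_c(rot)  =>  Tr(d) = T @ R_c(rot)^-1
    residual = T @ np.linalg.inv(rotation_matrix(rot_deg, center))
    return RigidParams(rot_deg, float(residual[0, 2]), float(residual[1, 2]))


def invert(T: np.ndarray) -> np.ndarray:
    """Inverse of a rigid homogeneous matrix (R^T block form, exact)."""
    T = np.asarray(T, dtype=float)
    if not is_rigid(T):
        raise ValueError("matrix is not a rigid homogeneous transform")
    R = T[:2, :2]
    d = T[:2, 2]
    out = np.eye(3)
    out[:2, :2] = R.T
    out[:2, 2] = -R.T @ d
    return out


def image_center(img: np.ndarray) -> tuple[float, float]:
    """Geometric center of an image in (x, y) = (col, row) coordinates."""
    h, w = img.shape[0], img.shape[1]
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def warp_image(img: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Apply a homogeneous transform to an image by inverse mapping.

    Each output pixel ``(x, y)`` samples the input at ``T^-1 @ (x, y, 1)``
    with bilinear interpolation; samples outside the frame contribute 0.
    Works for H x W and H x W x C arrays; output has the input's shape.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return warp_image(img[:, :, None], T)[:, :, 0]
    h, w, c = img.shape
    Tinv = np.linalg.inv(np.asarray(T, dtype=float))
    ys, xs = np.mgrid[0:h, 0:w]
    src_x = Tinv[0, 0] * xs + Tinv[0, 1] * ys + Tinv[0, 2]
    src_y = Tinv[1, 0] * xs + Tinv[1, 1] * ys + Tinv[1, 2]

    x0 = np.floor(src_x).astype(int)
    y0 = np.floor(src_y).astype(int)
    fx = src_x - x0
    fy = src_y - y0

    out = np.zeros_like(img)
    for dy_i, dx_i, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (0, 1, fx * (1 - fy)),
        (1, 0, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi = x0 + dx_i
        yi = y0 + dy_i
        valid = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        xi_c = np.clip(xi, 0, w - 1)
        yi_c = np.clip(yi, 0, h - 1)
        contrib = img[yi_c, xi_c, :] * (wgt * valid)[:, :, None]
        out += contrib
    return out
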