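"""Rigid motion trajectories and image-domain rigid transforms.

A rigid motion state per time point (TR) is ``(tx_mm, ty_mm, theta_deg)``:
in-plane translation along x (left-right, image columns) and y
(anterior-posterior, image rows) plus rotation about the image center.
Motion is piecewise constant within a TR — one spoke, one motion state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RigidMotionTrajectory",
    "motion_abrupt",
    "motion_sinusoidal",
    "motion_identity",
    "apply_rigid",
]


@dataclass
class RigidMotionTrajectory:
    """Per-time-point rigid motion parameters (length Nt each)."""

    tx_mm: np.ndarray
    ty_mm: np.ndarray
    theta_deg: np.ndarray

    def __post_init__(self) -> None:
        tx = np.asarray(self.tx_mm, dtype=float)
        ty = np.asarray(self.ty_mm, dtype=float)
        th = np.asarray(self.theta_deg, dtype=float)
        if not (tx.shape == ty.shape == th.shape) or tx.ndim != 1:
            raise ValueError("tx, ty, theta must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(tx)) and np.all(np.isfinite(ty)) and np.all(np.isfinite(th))):
            raise ValueError("motion parameters must be finite")
        self.tx_mm, self.ty_mm, self.theta_deg = tx, ty, th

    def __len__(self) -> int:
        return int(self.tx_mm.size)

    def state(self, n: int) -> tuple[float, float, float]:
        return float(self.tx_mm[n]), float(self.ty_mm[n]), float(self.theta_deg[n])

    def is_zero(self) -> bool:
        return not (
            np.any(self.tx_mm) or np.any(self.ty_mm) or np.any(self.theta_deg)
        )

    def as_array(self) -> np.ndarray:
        """Stack to shape (Nt, 3): columns tx_mm, ty_mm, theta_deg."""
        return np.column_stack([self.tx_mm, self.ty_mm, self.theta_deg])


def motion_identity(n_timepoints: int) -> RigidMotionTrajectory:
    z = np.zeros(n_timepoints)
    return RigidMotionTrajectory(tx_mm=z.copy(), ty_mm=z.copy(), theta_deg=z.copy())


def motion_abrupt(
    n_timepoints: int,
    event_timepoint: int,
    tx_px: float,
    ty_px: float,
    theta_deg: float,
    pixel_mm: float,
) -> RigidMotionTrajectory:
    """Step motion: identity before ``event_timepoint``, constant after.

    Translation amplitudes are given in pixels and converted to mm with
    ``pixel_mm``, matching the convention of quoting motion in pixels of the
    acquisition grid.
    """
    if not 1 <= event_timepoint < n_timepoints:
        raise ValueError("event_timepoint must lie in [1, Nt)")
    step = (np.arange(n_timepoints) >= event_timepoint).astype(float)
    return RigidMotionTrajectory(
        tx_mm=step * tx_px * pixel_mm,
        ty_mm=step * ty_px * pixel_mm,
        theta_deg=step * theta_deg,
    )


def motion_sinusoidal(
    n_timepoints: int,
    tx_px: float,
    ty_px: float,
    theta_deg: float,
    n_cycles: float,
    pixel_mm: float,
) -> RigidMotionTrajectory:
    """Sinusoidal motion with the given *peak* amplitudes over ``n_cycles``."""
    s = np.sin(2 * np.pi * n_cycles * np.arange(n_timepoints) / n_timepoints)
    return RigidMotionTrajectory(
        tx_mm=tx_px * pixel_mm * s, ty_mm=ty_px * pixel_mm * s, theta_deg=theta_deg * s
    )


def _rigid_inverse_matrix(theta_deg: float):
    """Inverse rotation in (row, col) index ordering."""
    a = np.deg2rad(theta_deg)
    c, s = np.cos(a), np.sin(a)
    # rotation by theta acting on (x, y) = (col, row); inverse, reordered to
    # (row, col) as used by ndimage
    return np.array([[c, -s], [s, c]])


def apply_rigid(
    image: np.ndarray,
    tx_mm: float,
    ty_mm: float,
    theta_deg: float,
    pixel_mm: float = 1.0,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Rotate about the image center then translate; bilinear, zero fill.

    The forward map of a pixel position ``r`` (in (x, y) = (col, row) axes,
    origin at pixel ``N//2``) is ``A(r) = R(theta) r + t``; the output image is
    ``image(A⁻¹ r)``.  Complex images are transformed component-wise.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    n = img.shape[0]
    c = np.array([n // 2, n // 2], dtype=float)  # (row, col)
    t = np.array([ty_mm, tx_mm], dtype=float) / pixel_mm  # (row, col) pixels
    minv = _rigid_inverse_matrix(theta_deg)
    offset = c - minv @ (c + t)

    def _warp(a):
        return ndimage.affine_transform(
            a, minv, offset=offset, order=order, mode="constant", cval=cval, prefilter=order > 1
        )

    if np.iscomplexobj(img):
        return _warp(img.real) + 1j * _warp(img.imag)
    return _warp(img)
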