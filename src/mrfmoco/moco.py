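"""Rigid motion correction applied directly to the acquired radial k-space.

A rigid in-plane motion of the object rotates its k-space and adds a linear
phase: if the object at TR ``n`` is the reference object rotated by θ_n and
translated by t_n, the acquired spoke satisfies
``K_n(k) = exp(-2πi k·t_n) · K_ref(R(-θ_n) k)``.  The correction inverts this
sample-by-sample: spoke coordinates are rotated by −θ_n and the translation
phase ramp is removed, after which every sample is a sample of the motion-free
object's k-space.  Only phases and coordinates change — sample magnitudes are
preserved exactly (det of a rotation is 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .motion import RigidMotionTrajectory
from .simulate import KSpaceData
from .trajectory import RadialTrajectory

__all__ = ["correct_kspace", "residual_kspace_coverage", "CoverageReport"]


def correct_kspace(
    data: KSpaceData,
    motion: RigidMotionTrajectory,
    pixel_mm: float,
    phase_sign: float = +1.0,
) -> KSpaceData:
    """Motion-correct radial k-space data with a per-TR rigid trajectory.

    Parameters
    ----------
    data : KSpaceData
    motion : RigidMotionTrajectory
        Estimated object pose per time point (image-domain convention of
        :func:`mrfmoco.motion.apply_rigid`).
    pixel_mm : float
        Pixel pitch; converts the motion's mm translations into the pixel
        units of the normalized k-space coordinates.
    phase_sign : {+1, -1}
        Sign of the translation phase ramp ``exp(+s·2πi k·t)``.  The default
        (+1) is the sign that exactly inverts the image-domain forward motion
        model (fixed by the shift-theorem round trip).

    Returns
    -------
    KSpaceData
        New container with rotated coordinates and re-phased samples.  The
        density compensation is invalidated (rotations change the angular
        distribution) and must be recomputed on the corrected trajectory.
    """
    if len(motion) != data.n_timepoints:
        raise ValueError("motion length must equal the number of time points")
    if motion.is_zero():
        return KSpaceData(
            samples=data.samples.copy(),
            traj=replace(data.traj, coords=data.traj.coords.copy(), dcf=data.traj.dcf),
            coils=data.coils,
        )
    coords = data.traj.coords
    theta = np.deg2rad(motion.theta_deg)
    cos, sin = np.cos(-theta), np.sin(-theta)  # rotate coordinates by -theta
    kx, ky = coords[..., 0], coords[..., 1]
    new_coords = np.stack(
        [cos[:, None] * kx - sin[:, None] * ky, sin[:, None] * kx + cos[:, None] * ky],
        axis=-1,
    )
    tx_px = motion.tx_mm / pixel_mm
    ty_px = motion.ty_mm / pixel_mm
    phase = np.exp(
        phase_sign * 2j * np.pi * (kx * tx_px[:, None] + ky * ty_px[:, None])
    )
    samples = data.samples * phase[:, :, None]
    angles = np.mod(data.traj.angles - theta, np.pi)
    traj = RadialTrajectory(
        coords=new_coords, angles=angles, matrix=data.traj.matrix, dcf=None
    )
    return KSpaceData(samples=samples, traj=traj, coils=data.coils)


@dataclass
class CoverageReport:
    """Angular coverage diagnostics of a (corrected) radial trajectory."""

    max_gap_deg: float
    histogram: np.ndarray
    bin_edges_deg: np.ndarray


def residual_kspace_coverage(traj: RadialTrajectory, n_bins: int = 36) -> CoverageReport:
    """Spoke-angle histogram (mod π) and maximum angular gap.

    Rotational correction disturbs the near-uniform golden-angle spacing and
    can open gaps in k-space; this reports the largest gap for QC.
    """
    ang = np.sort(np.mod(traj.angles, np.pi))
    gaps = np.diff(ang)
    wrap = ang[0] + np.pi - ang[-1]
    max_gap = float(np.rad2deg(max(gaps.max(initial=0.0), wrap)))
    hist, edges = np.histogram(np.rad2deg(ang), bins=n_bins, range=(0.0, 180.0))
    return CoverageReport(max_gap_deg=max_gap, histogram=hist, bin_edges_deg=edges)
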