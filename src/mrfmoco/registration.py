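"""Rigid registration of intermediate images and motion-trajectory estimation.

The sliding-window images change contrast throughout the scan (inversion
recovery, variable flip angles), so registration uses normalized mutual
information, which only assumes a statistical relationship between
intensities.  A coarse exhaustive stage seeds a local NMI pattern search:
every candidate rotation in a ±30° sweep is scored with an FFT
cross-correlation translation search on downsampled images, the best
candidate by NMI seeds a finite-difference ascent at full resolution.

Motion over the scan is estimated by registering every window image to
several reference windows (default every 100th).  Each reference's pose trace
is chained into a common frame by exact rigid composition, references are
averaged with deterministic quality weights, the trace is median-filtered
across windows and interpolated from window centers to all time points.  The
absolute pose is unobservable; the result is reported either centered
(zero mean per parameter) or anchored to the first window's pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .motion import RigidMotionTrajectory, apply_rigid
from .recon import SlidingWindowSeries

__all__ = [
    "RigidTransform",
    "nmi",
    "register_rigid",
    "estimate_motion_multireference",
    "anchor_trajectory",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid transform: rotate by theta about center, then translate."""

    tx_mm: float
    ty_mm: float
    theta_deg: float


def nmi(img_a: np.ndarray, img_b: np.ndarray, bins: int = 32) -> float:
    """Normalized mutual information ``(H(A)+H(B))/H(A,B)`` in [1, 2].

    Computed from a joint histogram over the overlap mask (pixels finite in
    both images, so NaN marks invalid/out-of-bounds regions).  A constant
    image carries no information: returns 1.0 with a warning.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    mask = np.isfinite(a) & np.isfinite(b)
    av, bv = a[mask], b[mask]
    if av.size == 0 or av.min() == av.max() or bv.min() == bv.max():
        logger.warning("constant or empty image in NMI; returning 1.0")
        return 1.0
    h, _, _ = np.histogram2d(av, bv, bins=bins)
    p = h / h.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))

    hab = entropy(p.ravel())
    if hab == 0:
        return 1.0
    return float((entropy(pa) + entropy(pb)) / hab)


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1:
        return img
    n = (img.shape[0] // factor) * factor
    return img[:n, :n].reshape(n // factor, factor, n // factor, factor).mean(axis=(1, 3))


def _xcorr_shift(fixed: np.ndarray, moving: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (dx, dy) maximizing the cross-correlation of zero-mean images."""
    f = fixed - fixed.mean()
    m = moving - moving.mean()
    c = np.real(np.fft.ifft2(np.fft.fft2(f) * np.conj(np.fft.fft2(m))))
    c = np.fft.fftshift(c)
    n = c.shape[0]
    ctr = n // 2
    lo, hi = ctr - max_shift, ctr + max_shift + 1
    sub = c[lo:hi, lo:hi]
    iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
    return int(ix - max_shift), int(iy - max_shift)


def _nmi_at(moving: np.ndarray, fixed_shifted: np.ndarray, tx_px, ty_px, theta, bins) -> float:
    """NMI of the candidate alignment, interpolation-symmetrized.

    A constant half-pixel shift is composed into both images (``fixed_shifted``
    is pre-shifted once) so that every evaluation interpolates both images
    equally; otherwise the un-interpolated identity pose sits in a spurious
    local minimum of the NMI (the classic interpolation artifact).
    """
    warped = apply_rigid(
        moving, tx_px + 0.5, ty_px + 0.5, theta, pixel_mm=1.0, cval=np.nan
    )
    return nmi(warped, fixed_shifted, bins)


def _shift_half_pixel(img: np.ndarray) -> np.ndarray:
    return apply_rigid(img, 0.5, 0.5, 0.0, pixel_mm=1.0, cval=np.nan)


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    pixel_mm: float = 1.0,
    bins: int = 32,
    theta_range_deg: float = 30.0,
    theta_step_deg: float = 2.0,
    coarse_size: int = 64,
    fine_steps: tuple = (2.0, 2.0, 1.0),
    min_step: float = 0.05,
    return_score: bool = False,
):
    """Estimate the rigid transform mapping ``moving`` onto ``fixed``.

    Maximizes NMI over (tx, ty, theta).  Magnitudes are taken internally, so
    complex window images can be passed directly; the result is invariant to
    global intensity scaling of either image.
    """
    mov = np.abs(np.asarray(moving, dtype=complex))
    fix = np.abs(np.asarray(fixed, dtype=complex))
    if mov.shape != fix.shape or mov.ndim != 2:
        raise ValueError("moving and fixed must be same-shape 2-D images")
    n = mov.shape[0]

    # --- coarse stage on downsampled images ---
    factor = max(1, int(np.ceil(n / coarse_size)))
    mov_c = _downsample(mov, factor)
    fix_c = _downsample(fix, factor)
    max_shift = max(2, int(0.25 * mov_c.shape[0]))
    thetas = np.arange(-theta_range_deg, theta_range_deg + 1e-9, theta_step_deg)
    fix_c_s = _shift_half_pixel(fix_c)
    best = (-np.inf, 0.0, 0.0, 0.0)
    for th in thetas:
        rot = apply_rigid(mov_c, 0.0, 0.0, th, pixel_mm=1.0)
        dx, dy = _xcorr_shift(fix_c, rot, max_shift)
        score = _nmi_at(mov_c, fix_c_s, dx, dy, th, bins)
        if score > best[0]:
            best = (score, float(dx), float(dy), float(th))

    # --- fine stage: pattern search at full resolution ---
    fix_s = _shift_half_pixel(fix)
    params = np.array([best[1] * factor, best[2] * factor, best[3]])
    steps = np.array(fine_steps, dtype=float)
    score = _nmi_at(mov, fix_s, *params, bins)
    while np.any(steps > min_step):
        improved = False
        for i in range(3):
            if steps[i] <= min_step:
                continue
            for sgn in (+1.0, -1.0):
                cand = params.copy()
                cand[i] += sgn * steps[i]
                s = _nmi_at(mov, fix_s, *cand, bins)
                if s > score:
                    score, params, improved = s, cand, True
                    break
        if not improved:
            steps = steps / 2
    transform = RigidTransform(
        tx_mm=float(params[0] * pixel_mm),
        ty_mm=float(params[1] * pixel_mm),
        theta_deg=float(params[2]),
    )
    if return_score:
        return transform, float(score)
    return transform


def estimate_motion_multireference(
    series: SlidingWindowSeries,
    n_timepoints: int,
    pixel_mm: float = 1.0,
    reference_stride: int = 100,
    trace_median: bool = True,
    gauge: str = "zero-mean",
    signal_gate: float = 0.5,
    **reg_kw,
) -> RigidMotionTrajectory:
    """Multi-reference motion estimate from a sliding-window series.

    References are every ``reference_stride``-th window.  Registering window
    ``t`` onto reference ``r`` yields the transform ``q_{r,t}``; its inverse
    is the pose of the window in that reference's frame.  All references'
    pose traces are chained into a common anchor frame by exact rigid
    composition, averaged across references with deterministic
    quality weights, median-filtered across windows, and linearly
    interpolated from window centers to all ``n_timepoints`` (constant
    extrapolation at the ends).

    ``gauge`` selects the output frame (the absolute pose is unobservable):
    ``"zero-mean"`` subtracts each parameter's mean — the conventional
    centered representation; being a constant shift it preserves all
    parameter differences.  ``"anchor"`` leaves the trace in the first
    window's pose, which is an exactly rigid-consistent trajectory — the
    form the k-space correction should consume.
    """
    nw = series.n_windows
    if nw == 0:
        raise ValueError("empty sliding-window series")
    if nw == 1:
        z = np.zeros(n_timepoints)
        return RigidMotionTrajectory(z.copy(), z.copy(), z.copy())
    mags = np.abs(series.images)

    # Windows near the inversion-recovery signal nulls are dominated by
    # residual aliasing whose structure rotates with the spoke set; their
    # registration is ill-posed.  Gate on window signal level (a property of
    # the data, not of any registration outcome) and interpolate the pose of
    # gated windows from their neighbours.
    level = mags.mean(axis=(1, 2))
    good = level >= signal_gate * np.median(level)
    if good.sum() < 2:
        good[:] = True
    gw = np.where(good)[0]
    ng = gw.size

    # references at every `reference_stride`-th window, moved to the nearest
    # well-conditioned window when gated (deterministic choice)
    refs = np.unique([gw[np.argmin(np.abs(gw - r))] for r in range(0, nw, reference_stride)])
    traces_q = np.zeros((refs.size, ng, 3))
    scores = np.zeros((refs.size, ng))
    for i, r in enumerate(refs):
        for j, t in enumerate(gw):
            if t == r:
                scores[i, j] = 1.0  # self-registration: perfect by definition
                continue
            q, s = register_rigid(
                mags[t], mags[r], pixel_mm=pixel_mm, return_score=True, **reg_kw
            )
            traces_q[i, j] = [q.tx_mm, q.ty_mm, q.theta_deg]
            scores[i, j] = s - 1.0  # NMI above the independence floor
    # references whose registrations scored poorly (low-signal or extreme
    # contrast windows) are down-weighted; the reduction stays deterministic
    ref_w = np.median(scores, axis=1)
    ref_w = np.maximum(ref_w, 0.0)
    if ref_w.sum() == 0:
        ref_w = np.ones(refs.size)
    ref_w = ref_w / ref_w.sum()

    # Chain every reference's measurements into the frame of the first
    # reference by exact rigid composition: the pose of window t in the
    # anchor frame is  (m_t ∘ m_r⁻¹) ∘ (m_r ∘ m_r0⁻¹) = p_{r,t} ∘ p_{r0,r},
    # where p = q⁻¹ and p_{r0,r} comes from the anchor's own trace.  This
    # avoids the rotation–translation cross-talk of parameter-wise centering
    # (subtracting a constant from translations is not a rigid change of
    # frame when the rotation varies).
    p = _rigid_inverse_params(traces_q)  # (refs, ng, 3)
    chained = np.empty_like(p)
    for i, r in enumerate(refs):
        j = int(np.searchsorted(gw, r))
        offset = p[0, j]  # pose of reference window r in the anchor frame
        chained[i] = _rigid_compose_params(p[i], offset)
    mean_trace = np.tensordot(ref_w, chained, axes=(0, 0))
    if trace_median and ng >= 3:
        # windows that straddle an abrupt pose change produce double-exposed
        # images whose registration is an outlier; a 3-window median removes
        # such single-window outliers while leaving plateaus and smooth
        # trajectories untouched (a step edge moves by at most one window)
        mean_trace = ndimage.median_filter(mean_trace, size=(3, 1), mode="nearest")
    centers = series.window_center_timepoint[gw]
    tt = np.arange(n_timepoints)
    out = np.empty((n_timepoints, 3))
    for j in range(3):
        out[:, j] = np.interp(tt, centers, mean_trace[:, j])
    if gauge == "zero-mean":
        out -= out.mean(axis=0, keepdims=True)
    elif gauge != "anchor":
        raise ValueError(f"unknown gauge {gauge!r}")
    return RigidMotionTrajectory(tx_mm=out[:, 0], ty_mm=out[:, 1], theta_deg=out[:, 2])


def anchor_trajectory(
    motion: RigidMotionTrajectory, timepoints: slice | np.ndarray
) -> RigidMotionTrajectory:
    """Re-express a trajectory so the mean pose over ``timepoints`` is zero.

    A motion estimate fixes only relative motion; composing a constant rigid
    transform (gauge) is free.  Anchoring to, e.g., the first window's time
    span puts the corrected reconstruction in that window's pose — the same
    frame an image-based correction registered to the first window uses.
    """
    arr = motion.as_array()
    ref = arr[timepoints].mean(axis=0)
    out = _rigid_compose_params(arr, _rigid_inverse_params(ref))
    return RigidMotionTrajectory(tx_mm=out[:, 0], ty_mm=out[:, 1], theta_deg=out[:, 2])


def _rigid_compose_params(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Parameters of A∘B (apply B, then A) for rigid (tx, ty, theta[deg]).

    Broadcast over leading axes of ``a``; ``b`` may be a single transform.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    tha = np.deg2rad(a[..., 2])
    cos, sin = np.cos(tha), np.sin(tha)
    tx = a[..., 0] + cos * b[..., 0] - sin * b[..., 1]
    ty = a[..., 1] + sin * b[..., 0] + cos * b[..., 1]
    return np.stack([tx, ty, a[..., 2] + b[..., 2]], axis=-1)


def _rigid_inverse_params(a: np.ndarray) -> np.ndarray:
    """Parameters of A⁻¹ for rigid (tx, ty, theta[deg]) transforms."""
    a = np.asarray(a, dtype=float)
    th = np.deg2rad(a[..., 2])
    cos, sin = np.cos(th), np.sin(th)
    tx = -(cos * a[..., 0] + sin * a[..., 1])
    ty = -(-sin * a[..., 0] + cos * a[..., 1])
    return np.stack([tx, ty, -a[..., 2]], axis=-1)
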