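"""Conjugate-gradient reconstructions: iterative SENSE and low-rank inversion.

Both solvers minimize a density-weighted least-squares data consistency
``‖√W (S F C x − k)‖²`` by CG on the normal equations, with zero
initialization and a fixed iteration budget (default 15) so that early
stopping acts as the only regularization and results are deterministic.

The low-rank solver works directly on the R coefficient ("singular") images
of the temporal subspace ``U_R``: the forward operator mixes the coefficient
images with row ``n`` of ``U_R``, coil-weights, and samples spoke ``n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coils import CoilMaps
from .nufft import NUFFT2D
from .trajectory import RadialTrajectory, voronoi_dcf

__all__ = [
    "SlidingWindowSeries",
    "SingularImages",
    "cg_sense",
    "sliding_window_series",
    "low_rank_inversion",
]

logger = logging.getLogger(__name__)


@dataclass
class SlidingWindowSeries:
    """Intermediate images from overlapping spoke windows.

    images : ndarray, complex, (Nw, N, N).
    window_center_timepoint : ndarray, (Nw,) — time point at each window's
    center, ``start + window//2``.
    window_width : int.
    """

    images: np.ndarray
    window_center_timepoint: np.ndarray
    window_width: int

    @property
    def n_windows(self) -> int:
        return self.images.shape[0]


@dataclass
class SingularImages:
    """Coefficient images in the rank-R temporal subspace.

    coeffs : ndarray, complex, (R, N, N); basis : ndarray (Nt, R).
    """

    coeffs: np.ndarray
    basis: np.ndarray

    def __post_init__(self) -> None:
        if self.coeffs.shape[0] != self.basis.shape[1]:
            raise ValueError("coefficient count must match basis rank")

    @property
    def rank(self) -> int:
        return self.coeffs.shape[0]

    def to_timeseries(self, timepoints=None) -> np.ndarray:
        """Expand to time-point images ``I'_t = Σ_r U[t,r]·coeff_r``."""
        u = self.basis if timepoints is None else self.basis[timepoints]
        return np.tensordot(u, self.coeffs, axes=(1, 0))


def _cg(normal_op, rhs, max_iter: int, tol: float = 1e-6):
    """Complex CG on ``normal_op(x) = rhs`` from zero init; returns (x, residuals)."""
    x = np.zeros_like(rhs)
    r = rhs.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    rhs_norm = np.sqrt(rs)
    residuals = []
    if rhs_norm == 0:
        return x, [0.0]
    for _ in range(max_iter):
        ap = normal_op(p)
        alpha = rs / np.vdot(p, ap).real
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = np.vdot(r, r).real
        residuals.append(np.sqrt(rs_new) / rhs_norm)
        if residuals[-1] < tol:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, residuals


def cg_sense(
    kdata: np.ndarray,
    coords: np.ndarray,
    dcf: np.ndarray,
    coils: CoilMaps,
    max_iter: int = 15,
    nufft_width: int = 6,
    tol: float = 1e-6,
) -> np.ndarray:
    """Iterative SENSE image from a subset of radial samples.

    Parameters
    ----------
    kdata : ndarray, complex, (..., Nc)
        Samples; leading axes (e.g. spoke × readout) are flattened.
    coords : ndarray, (..., 2)
        Matching k-space coordinates.
    dcf : ndarray
        Density weights (enter the normal equations as the weighting W).
    coils : CoilMaps
    """
    nc = coils.n_coils
    y = np.asarray(kdata, dtype=complex).reshape(-1, nc)
    if y.size == 0:
        raise ValueError("empty k-space subset")
    pts = np.asarray(coords, dtype=float).reshape(-1, 2)
    w = np.asarray(dcf, dtype=float).reshape(-1)
    op = NUFFT2D(pts, coils.matrix, width=nufft_width)
    cmaps = coils.maps

    def normal(xflat):
        x = xflat.reshape(coils.matrix, coils.matrix)
        out = np.zeros_like(x)
        for c in range(nc):
            s = op.forward(cmaps[c] * x)
            out += np.conj(cmaps[c]) * op.adjoint(w * s)
        return out.ravel()

    rhs = np.zeros((coils.matrix, coils.matrix), dtype=complex)
    for c in range(nc):
        rhs += np.conj(cmaps[c]) * op.adjoint(w * y[:, c])
    x, res = _cg(normal, rhs.ravel(), max_iter, tol)
    logger.debug("cg_sense: %d iters, final rel residual %.2e", len(res), res[-1])
    return x.reshape(coils.matrix, coils.matrix)


def _window_dcf(coords: np.ndarray, angles: np.ndarray, cache: dict) -> np.ndarray:
    """Per-window Voronoi DCF, reusing weights across rotationally congruent
    windows.

    Golden-angle windows at different start indices have spoke-angle sets that
    differ only by a global rotation, so their Voronoi cell areas (hence
    weights) are identical; the relative-angle multiset is the cache key
    check.
    """
    rel = np.sort(np.mod(angles - angles[0], np.pi))
    if "rel" in cache and rel.shape == cache["rel"].shape and np.allclose(
        rel, cache["rel"], atol=1e-12
    ):
        return cache["dcf"]
    dcf = voronoi_dcf(coords)
    cache["rel"], cache["dcf"] = rel, dcf
    return dcf


def sliding_window_series(
    kdata: np.ndarray,
    traj: RadialTrajectory,
    coils: CoilMaps,
    window: int = 50,
    stride: int = 1,
    max_iter: int = 15,
) -> SlidingWindowSeries:
    """CG-SENSE reconstruction of every sliding spoke window.

    Window ``w`` covers spokes ``[w·stride, w·stride + window)``; its image is
    assigned to the center time point ``w·stride + window//2``.
    """
    nt = traj.n_timepoints
    if not 1 <= window <= nt:
        raise ValueError("window must lie in [1, Nt]")
    starts = np.arange(0, nt - window + 1, stride)
    images = np.empty((starts.size, coils.matrix, coils.matrix), dtype=complex)
    cache: dict = {}
    for i, s in enumerate(starts):
        sl = slice(s, s + window)
        dcf = _window_dcf(traj.coords[sl], traj.angles[sl], cache)
        images[i] = cg_sense(kdata[sl], traj.coords[sl], dcf, coils, max_iter)
    centers = starts + window // 2
    return SlidingWindowSeries(
        images=images, window_center_timepoint=centers, window_width=window
    )


def low_rank_inversion(
    kdata: np.ndarray,
    traj: RadialTrajectory,
    dcf: np.ndarray,
    coils: CoilMaps,
    basis: np.ndarray,
    max_iter: int = 15,
    nufft_width: int = 6,
    tol: float = 1e-6,
) -> SingularImages:
    """Subspace-constrained least-squares reconstruction ("low-rank inversion").

    Solves ``min_I ‖√W (S U_R F C I − K)‖²`` for the R coefficient images I,
    where time point ``n`` contributes its own spoke and row ``n`` of ``U_R``.
    """
    nt, ns, nc = kdata.shape
    if basis.shape[0] != nt:
        raise ValueError("basis rows must equal the k-space time dimension")
    rank = basis.shape[1]
    n = coils.matrix
    pts = traj.coords.reshape(-1, 2)
    w = np.asarray(dcf, dtype=float).reshape(-1)
    op = NUFFT2D(pts, n, width=nufft_width)
    # basis value per flattened sample: U[t, r] repeated over the readout
    urep = np.repeat(basis, ns, axis=0)  # (Nt*Ns, R)
    cmaps = coils.maps
    y = kdata.reshape(-1, nc)

    def forward(coeffs):
        out = np.empty((nt * ns, nc), dtype=complex)
        for c in range(nc):
            acc = np.zeros(nt * ns, dtype=complex)
            for r in range(rank):
                acc += urep[:, r] * op.forward(cmaps[c] * coeffs[r])
            out[:, c] = acc
        return out

    def adjoint(samples):
        coeffs = np.zeros((rank, n, n), dtype=complex)
        for c in range(nc):
            z = w * samples[:, c]
            for r in range(rank):
                coeffs[r] += np.conj(cmaps[c]) * op.adjoint(np.conj(urep[:, r]) * z)
        return coeffs

    def normal(xflat):
        coeffs = xflat.reshape(rank, n, n)
        return adjoint(forward(coeffs)).ravel()

    rhs = adjoint(y)
    x, res = _cg(normal, rhs.ravel(), max_iter, tol)
    logger.debug("low_rank_inversion: %d iters, final rel residual %.2e", len(res), res[-1])
    return SingularImages(coeffs=x.reshape(rank, n, n), basis=basis)
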