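"""Golden-angle radial trajectories and Voronoi density compensation.

k-space coordinates are kept in normalized units of cycles/pixel in
``[-0.5, 0.5)`` (0.5 = Nyquist of the reconstruction grid), with spoke samples
spaced ``1/matrix`` apart so that ``Ns = matrix`` samples exactly span the
grid's Nyquist disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import QhullError, Voronoi

__all__ = ["GOLDEN_ANGLE_DEG", "RadialTrajectory", "golden_radial", "voronoi_dcf"]

logger = logging.getLogger(__name__)

#: 2D golden angle: 180° / golden ratio = 111.2461…°
GOLDEN_ANGLE_DEG = 180.0 * (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class RadialTrajectory:
    """Per-time-point radial spokes.

    Attributes
    ----------
    coords : ndarray, (Nt, Ns, 2)
        (kx, ky) per sample in normalized cycles/pixel, ``|k| <= 0.5``.
    angles : ndarray, (Nt,)
        Spoke angle in radians (mod π equivalence).
    dcf : ndarray or None, (Nt, Ns)
        Voronoi density-compensation weight per sample, filled on demand.
    matrix : int
        Nominal reconstruction matrix size.
    """

    coords: np.ndarray
    angles: np.ndarray
    matrix: int
    dcf: np.ndarray | None = None

    @property
    def n_timepoints(self) -> int:
        return self.coords.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coords.shape[1]


def golden_radial(n_timepoints: int, n_samples: int, matrix: int) -> RadialTrajectory:
    """One golden-angle spoke per time point.

    Spoke ``n`` lies at angle ``n·Φ mod π`` (Φ the golden angle, spoke 0
    horizontal) with ``n_samples`` samples at radii
    ``(j - Ns//2)/matrix, j = 0..Ns-1`` passing through DC.
    """
    if n_timepoints < 1 or n_samples < 1:
        raise ValueError("n_timepoints and n_samples must be >= 1")
    radii = (np.arange(n_samples) - n_samples // 2) / matrix
    if np.abs(radii).max() > 0.5:
        raise ValueError("spoke extent exceeds Nyquist: need n_samples <= matrix")
    angles = np.deg2rad(GOLDEN_ANGLE_DEG) * np.arange(n_timepoints) % np.pi
    direction = np.stack([np.cos(angles), np.sin(angles)], axis=-1)  # (Nt, 2)
    coords = radii[None, :, None] * direction[:, None, :]
    return RadialTrajectory(coords=coords, angles=angles, matrix=matrix)


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_dcf(coords: np.ndarray, disk_radius: float | None = None) -> np.ndarray:
    """Voronoi-cell-area density compensation for a set of k-space samples.

    Parameters
    ----------
    coords : ndarray, (..., 2)
        Sample coordinates; leading shape is preserved in the output.
    disk_radius : float, optional
        Radius of the sampled disk to which cells are clipped; defaults to
        the largest sample radius plus half the median radial spacing.

    Returns
    -------
    ndarray
        Per-sample weights.  Coincident samples (e.g. the DC point shared by
        every spoke) split their cell area equally.  Weights are normalized so
        their sum equals the clipped disk area.  Degenerate all-collinear
        input (a single spoke) falls back to ramp ``|k|`` weighting.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 2)
    lead_shape = np.asarray(coords).shape[:-1]
    radius = np.hypot(pts[:, 0], pts[:, 1])
    if disk_radius is None:
        r_sorted = np.unique(np.round(radius, 12))
        spacing = np.median(np.diff(r_sorted)) if r_sorted.size > 1 else 0.0
        disk_radius = float(radius.max() + spacing / 2)
    disk_area = np.pi * disk_radius**2

    uniq, inverse, counts = np.unique(
        np.round(pts, 12), axis=0, return_inverse=True, return_counts=True
    )
    centered = uniq - uniq.mean(axis=0)
    collinear = np.linalg.matrix_rank(centered, tol=1e-10) < 2
    weights = np.empty(uniq.shape[0])
    try:
        if uniq.shape[0] < 4 or collinear:
            raise QhullError("degenerate (collinear or too few) sample set")
        weights = _voronoi_cell_areas(uniq, disk_radius)
    except QhullError:
        logger.warning("degenerate sample set; falling back to ramp |k| DCF")
        w = np.hypot(uniq[:, 0], uniq[:, 1])
        w[w == 0] = w[w > 0].min() / 2 if np.any(w > 0) else 1.0
        weights = w
    weights = weights / counts  # coincident samples share their cell
    out = weights[inverse]
    out *= disk_area / (out.sum())
    return out.reshape(lead_shape)


def _voronoi_cell_areas(points: np.ndarray, disk_radius: float) -> np.ndarray:
    """Areas of Voronoi cells clipped to the disk of ``disk_radius``.

    A ring of ghost sites far outside the disk bounds every real cell, so each
    cell is a finite polygon; cells that protrude beyond the disk are clipped
    exactly (shapely), interior cells use the shoelace formula directly.
    """
    from shapely.geometry import Point, Polygon

    n_ghost = max(64, 4 * int(np.sqrt(points.shape[0])))
    tg = np.linspace(0, 2 * np.pi, n_ghost, endpoint=False)
    ghosts = 3.0 * disk_radius * np.stack([np.cos(tg), np.sin(tg)], axis=-1)
    vor = Voronoi(np.vstack([points, ghosts]))
    disk = Point(0.0, 0.0).buffer(disk_radius, quad_segs=64)
    areas = np.empty(points.shape[0])
    r2 = disk_radius**2
    for i in range(points.shape[0]):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        if len(region) < 3 or -1 in region:
            areas[i] = 0.0
            continue
        if np.all(verts[:, 0] ** 2 + verts[:, 1] ** 2 <= r2 * (1 + 1e-12)):
            areas[i] = _polygon_area(verts)
        else:
            areas[i] = Polygon(verts).intersection(disk).area
    return areas
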