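"""Digital quantitative phantoms: brain-like ellipse composition and vials.

The brain-like phantom is an ellipse composition carrying literature tissue
values — white matter T1/T2 = 738/48 ms, gray matter 1127/69 ms, CSF
4000/2000 ms — plus a few small inclusions for resolution assessment.  The
vial phantom places homogeneous disks with user-chosen (T1, T2) on a grid,
standing in for a standardized relaxometry phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TissueMaps", "brain_phantom", "vial_phantom", "BRAIN_TISSUES"]

#: (name, T1 ms, T2 ms, M0) of the brain-like phantom compartments.
BRAIN_TISSUES = {
    "wm": (738.0, 48.0, 0.77),
    "gm": (1127.0, 69.0, 0.86),
    "csf": (4000.0, 2000.0, 1.0),
}


@dataclass
class TissueMaps:
    """Per-pixel ground-truth tissue parameters.

    t1_ms, t2_ms : ndarray (N, N), positive inside the mask.
    m0 : ndarray, complex amplitude (zero outside the mask).
    mask : ndarray, bool.
    """

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    m0: np.ndarray
    mask: np.ndarray
    fov_mm: float
    matrix: int

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix

    def unique_tissues(self) -> np.ndarray:
        """Unique (T1, T2) pairs inside the mask, shape (K, 2)."""
        pairs = np.column_stack([self.t1_ms[self.mask], self.t2_ms[self.mask]])
        return np.unique(pairs, axis=0)


def _ellipse(matrix: int, cx: float, cy: float, rx: float, ry: float, angle_deg: float = 0.0):
    """Boolean ellipse mask; center/radii in fractions of the matrix."""
    x = (np.arange(matrix) - matrix // 2) / matrix
    xx, yy = np.meshgrid(x, x, indexing="xy")
    a = np.deg2rad(angle_deg)
    xr = np.cos(a) * (xx - cx) + np.sin(a) * (yy - cy)
    yr = -np.sin(a) * (xx - cx) + np.cos(a) * (yy - cy)
    return (xr / rx) ** 2 + (yr / ry) ** 2 <= 1.0


def brain_phantom(matrix: int = 160, fov_mm: float = 320.0) -> TissueMaps:
    """Deterministic brain-like phantom with realistic T1/T2/M0 values.

    Gray-matter head outline, white-matter interior, two CSF ventricles and
    four small inclusions (alternating WM/GM values) for resolution
    assessment.
    """
    if matrix < 32:
        raise ValueError("matrix must be >= 32")
    t1 = np.zeros((matrix, matrix))
    t2 = np.zeros((matrix, matrix))
    m0 = np.zeros((matrix, matrix))

    head = _ellipse(matrix, 0.0, 0.0, 0.36, 0.44)
    wm = _ellipse(matrix, 0.0, 0.02, 0.28, 0.35)
    vent_l = _ellipse(matrix, -0.07, -0.02, 0.045, 0.12, 10)
    vent_r = _ellipse(matrix, 0.07, -0.02, 0.045, 0.12, -10)

    def paint(region, tissue):
        t1v, t2v, m0v = BRAIN_TISSUES[tissue]
        t1[region], t2[region], m0[region] = t1v, t2v, m0v

    paint(head, "gm")
    paint(wm, "wm")
    paint(vent_l, "csf")
    paint(vent_r, "csf")

    # small round inclusions, radii shrinking for resolution assessment
    for i, (cx, cy, r) in enumerate(
        [(-0.16, 0.22, 0.030), (0.16, 0.22, 0.022), (-0.16, -0.25, 0.016), (0.16, -0.25, 0.011)]
    ):
        paint(_ellipse(matrix, cx, cy, r, r), "gm" if i % 2 == 0 else "csf")

    mask = head
    return TissueMaps(
        t1_ms=t1, t2_ms=t2, m0=m0.astype(complex), mask=mask, fov_mm=fov_mm, matrix=matrix
    )


def vial_phantom(matrix: int, fov_mm: float, t1_list, t2_list) -> TissueMaps:
    """Homogeneous vials on a square grid, one per (t1, t2) pair."""
    t1_list = np.atleast_1d(np.asarray(t1_list, dtype=float))
    t2_list = np.atleast_1d(np.asarray(t2_list, dtype=float))
    if t1_list.size == 0 or t2_list.size != t1_list.size:
        raise ValueError("t1_list and t2_list must be equal-length and non-empty")
    n = t1_list.size
    side = int(np.ceil(np.sqrt(n)))
    radius = 0.5 / side * 0.55
    t1 = np.zeros((matrix, matrix))
    t2 = np.zeros((matrix, matrix))
    m0 = np.zeros((matrix, matrix))
    centers = (np.arange(side) + 0.5) / side - 0.5
    for i in range(n):
        cy = centers[i // side] * 0.8
        cx = centers[i % side] * 0.8
        disk = _ellipse(matrix, cx, cy, radius, radius)
        t1[disk], t2[disk], m0[disk] = t1_list[i], t2_list[i], 1.0
    mask = m0 > 0
    return TissueMaps(
        t1_ms=t1, t2_ms=t2, m0=m0.astype(complex), mask=mask, fov_mm=fov_mm, matrix=matrix
    )
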