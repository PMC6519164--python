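"""Analytic multi-channel receive sensitivities.

Real acquisitions estimate coil maps from the data (e.g. with ESPIRiT); the
simulator instead uses smooth analytic sensitivities, which are an input to
every reconstruction operator here.  Maps are deterministic functions of the
channel count and grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoilMaps", "simulate_coil_maps"]


@dataclass
class CoilMaps:
    """Complex receive sensitivities on the image grid.

    maps : ndarray, complex, (Nc, N, N); fov_mm : field of view.
    """

    maps: np.ndarray
    fov_mm: float

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def matrix(self) -> int:
        return self.maps.shape[1]

    def rss(self) -> np.ndarray:
        """Root-sum-of-squares sensitivity magnitude."""
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


def simulate_coil_maps(n_coils: int, matrix: int, fov_mm: float = 320.0) -> CoilMaps:
    """Gaussian-lobe sensitivities on a ring of virtual receive elements.

    Each channel is a broad complex Gaussian centered just outside the FOV at
    equally spaced angles, with a smooth linear phase — a crude but smooth
    stand-in for a head-coil array.  ``n_coils == 1`` returns a uniform unit
    map (sensitivity-blind reconstruction).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if n_coils == 1:
        return CoilMaps(maps=np.ones((1, matrix, matrix), dtype=complex), fov_mm=fov_mm)
    x = np.linspace(-0.5, 0.5, matrix, endpoint=False)
    xx, yy = np.meshgrid(x, x, indexing="xy")
    sigma = 0.55
    ring_r = 0.6
    maps = np.empty((n_coils, matrix, matrix), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cx, cy = ring_r * np.cos(ang), ring_r * np.sin(ang)
        mag = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        phase = np.pi * (np.cos(ang) * xx + np.sin(ang) * yy) + ang / 2
        maps[c] = mag * np.exp(1j * phase)
    return CoilMaps(maps=maps, fov_mm=fov_mm)
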