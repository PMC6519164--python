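"""Sequence timing, flip-angle schedules and slice profiles.

The fingerprinting sequence modelled here is an inversion-prepared,
gradient-spoiled (FISP-type) acquisition with a fixed TR/TE and a flip angle
that varies smoothly from time point to time point.  One golden-angle radial
spoke is acquired per TR, so "time point" and "TR" are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SequenceParams",
    "SliceProfile",
    "default_flip_angles",
    "sinc_slice_profile",
    "load_flip_angles_csv",
    "save_flip_angles_csv",
]


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition schedule of a fixed-TR fingerprinting sequence.

    Parameters
    ----------
    flip_angles : ndarray
        Nominal flip angle per time point, degrees, length ``Nt``.
    tr_ms : float
        Repetition time in milliseconds (constant over the scan).
    te_ms : float
        Echo time in milliseconds; the recorded signal is the spoiled-echo
        amplitude at TE.
    invert : bool
        Apply an ideal 180° inversion immediately before the first TR.
    """

    flip_angles: np.ndarray
    tr_ms: float = 4.3
    te_ms: float = 1.23
    invert: bool = True

    def __post_init__(self) -> None:
        fa = np.asarray(self.flip_angles, dtype=float)
        if fa.ndim != 1 or fa.size < 1:
            raise ValueError("flip_angles must be a non-empty 1-D array")
        if np.any(fa < 0) or np.any(fa > 180):
            raise ValueError("flip angles must lie in [0, 180] degrees")
        if not (0 < self.te_ms < self.tr_ms):
            raise ValueError("require 0 < TE < TR")
        object.__setattr__(self, "flip_angles", fa)

    @property
    def n_timepoints(self) -> int:
        return int(self.flip_angles.size)


def default_flip_angles(
    n_timepoints: int = 1750,
    n_lobes: int = 10,
    peak_min_deg: float = 30.0,
    peak_max_deg: float = 70.0,
    jitter_deg: float = 1.0,
    seed: int = 2701,
) -> np.ndarray:
    """Generate the default variable flip-angle train (0–70°).

    Repeating sinusoidal half-lobes whose peak amplitude ramps linearly from
    ``peak_min_deg`` to ``peak_max_deg`` over ``n_lobes`` lobes, with a small
    deterministic pseudo-random per-time-point jitter.  This reproduces the
    class of smooth lobed flip-angle trains used for FISP fingerprinting; the
    exact waveform is user-overridable (see :func:`load_flip_angles_csv`).
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    n = np.arange(n_timepoints)
    lobe_len = n_timepoints / n_lobes
    lobe_idx = np.minimum((n // lobe_len).astype(int), n_lobes - 1)
    peaks = np.linspace(peak_min_deg, peak_max_deg, n_lobes)[lobe_idx]
    phase = (n % lobe_len) / lobe_len
    fa = peaks * np.sin(np.pi * phase)
    rng = np.random.default_rng(seed)
    fa = fa + jitter_deg * rng.standard_normal(n_timepoints) * (fa > 1.0)
    return np.clip(fa, 0.0, peak_max_deg)


@dataclass(frozen=True)
class SliceProfile:
    """Discretized through-slice flip-angle scale.

    ``scale[i]`` multiplies the nominal flip angle for slice position ``i``;
    the fingerprint is the average of the per-position signals.  ``max(scale)``
    is normalized to 1 so the profile never amplifies the nominal angle.
    """

    positions: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        sc = np.asarray(self.scale, dtype=float)
        if pos.size == 0 or sc.size != pos.size:
            raise ValueError("positions and scale must be equal-length, non-empty")
        if np.any(sc <= 0):
            raise ValueError("profile scales must be positive")
        if not np.isclose(sc.max(), 1.0):
            raise ValueError("profile must be normalized: max(scale) == 1")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "scale", sc)

    def __len__(self) -> int:
        return int(self.scale.size)


def sinc_slice_profile(n_points: int = 50, tbw: float = 4.0) -> SliceProfile:
    """Slice profile of a Hamming-windowed sinc excitation pulse.

    The small-tip slice profile is the Fourier transform of the RF envelope;
    its magnitude across the slice, sampled at ``n_points`` positions spanning
    the nominal slice width, scales the effective flip angle.  ``tbw`` is the
    pulse time-bandwidth product.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_points == 1:
        return SliceProfile(positions=np.zeros(1), scale=np.ones(1))
    # RF envelope: windowed sinc with tbw side lobes, finely sampled.
    t = np.linspace(-tbw / 2, tbw / 2, 512)
    env = np.sinc(t) * np.hamming(t.size)
    # Profile across the slice (frequency axis), sampled inside the nominal
    # slice: positions in [-0.5, 0.5] slice widths.
    pos = np.linspace(-0.5, 0.5, n_points)
    freq = pos * tbw
    profile = np.abs(np.exp(-2j * np.pi * np.outer(freq, t)) @ env)
    profile /= profile.max()
    return SliceProfile(positions=pos, scale=profile)


def save_flip_angles_csv(path, flip_angles: np.ndarray) -> None:
    """Write a flip-angle train as a two-column CSV (index, degrees)."""
    fa = np.asarray(flip_angles, dtype=float)
    arr = np.column_stack([np.arange(fa.size), fa])
    np.savetxt(path, arr, delimiter=",", header="index,flip_angle_deg", comments="")


def load_flip_angles_csv(path) -> np.ndarray:
    """Read a flip-angle train from a two-column CSV (index, degrees)."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    if arr.ndim == 1:
        arr = arr[None, :]
    return np.asarray(arr[:, 1], dtype=float)
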