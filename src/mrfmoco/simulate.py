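"""Forward simulation of multi-coil radial fingerprinting acquisitions.

For every time point ``n`` the contrast image is the tissue M0 map times the
fingerprint value of its (T1, T2) at ``n``; the rigid motion state of that TR
is applied in the image domain, the image is coil-weighted, and spoke ``n`` is
sampled with the NUFFT.  Complex Gaussian noise is added with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coils import CoilMaps
from .dictionary import Dictionary
from .motion import RigidMotionTrajectory, apply_rigid, motion_identity
from .nufft import NUFFT2D
from .phantom import TissueMaps
from .sequence import SequenceParams, SliceProfile
from .trajectory import RadialTrajectory
from .epg import epg_with_slice_profile

__all__ = ["KSpaceData", "simulate_mrf_kspace", "tissue_dictionary"]


@dataclass
class KSpaceData:
    """Acquired radial samples plus the geometry needed to reconstruct them.

    samples : ndarray, complex, (Nt, Ns, Nc).
    traj : RadialTrajectory; coils : CoilMaps.
    """

    samples: np.ndarray
    traj: RadialTrajectory
    coils: CoilMaps

    def __post_init__(self) -> None:
        nt, ns, nc = self.samples.shape
        if (nt, ns) != (self.traj.n_timepoints, self.traj.n_samples):
            raise ValueError("samples and trajectory shapes are inconsistent")
        if nc != self.coils.n_coils:
            raise ValueError("samples and coil maps disagree on channel count")

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[2]


def tissue_dictionary(
    maps: TissueMaps,
    seq: SequenceParams,
    profile: SliceProfile,
    max_states: int | None = None,
) -> Dictionary:
    """Exact-valued fingerprint table for the unique tissues of a phantom."""
    pairs = maps.unique_tissues()
    atoms = epg_with_slice_profile(pairs[:, 0], pairs[:, 1], seq, profile, max_states)
    return Dictionary(atoms=atoms, entries=pairs, seq=seq)


def _fingerprint_lookup(maps: TissueMaps, signal_model: Dictionary) -> tuple:
    """Per-unique-tissue base images b_u = m0·mask_u and fingerprints f_u."""
    pairs = maps.unique_tissues()
    entries = signal_model.entries
    bases, fingerprints = [], []
    for t1, t2 in pairs:
        hit = np.where((entries[:, 0] == t1) & (entries[:, 1] == t2))[0]
        if hit.size == 0:
            raise ValueError(
                f"tissue (T1={t1}, T2={t2}) ms missing from the signal model; "
                "the simulator requires exact dictionary lookup"
            )
        region = maps.mask & (maps.t1_ms == t1) & (maps.t2_ms == t2)
        bases.append(maps.m0 * region)
        fingerprints.append(signal_model.atoms[:, hit[0]])
    return bases, np.stack(fingerprints, axis=1)  # list[(N,N)], (Nt, K)


def simulate_mrf_kspace(
    maps: TissueMaps,
    seq: SequenceParams,
    signal_model: Dictionary,
    traj: RadialTrajectory,
    coils: CoilMaps,
    motion: RigidMotionTrajectory | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    nufft_width: int = 6,
    interp_order: int = 1,
) -> KSpaceData:
    """Simulate the full radial acquisition of a moving quantitative phantom.

    Per TR the motion state is constant (one spoke per time point).  When the
    trajectory contains few distinct motion states (e.g. a step), the
    transformed tissue base images are cached per state rather than warping
    every frame.
    """
    nt = seq.n_timepoints
    if traj.n_timepoints != nt:
        raise ValueError("trajectory and sequence disagree on Nt")
    if motion is None:
        motion = motion_identity(nt)
    if len(motion) != nt:
        raise ValueError("motion trajectory length must equal Nt")
    if maps.matrix != coils.matrix:
        raise ValueError("phantom and coil maps disagree on matrix size")

    bases, fps = _fingerprint_lookup(maps, signal_model)
    n = maps.matrix
    nc = coils.n_coils
    pixel_mm = maps.pixel_mm

    states = motion.as_array()
    uniq_states, state_of = np.unique(states, axis=0, return_inverse=True)
    cache_states = uniq_states.shape[0] <= 8

    warped_bases = None
    if cache_states:
        warped_bases = []
        for tx, ty, th in uniq_states:
            if tx == 0 and ty == 0 and th == 0:
                warped_bases.append(bases)
            else:
                warped_bases.append(
                    [
                        apply_rigid(b, tx, ty, th, pixel_mm=pixel_mm, order=interp_order)
                        for b in bases
                    ]
                )

    out = np.empty((nt, traj.n_samples, nc), dtype=complex)
    # one NUFFT per time point; operators share the grid so build per spoke
    for t in range(nt):
        if cache_states:
            bs = warped_bases[state_of[t]]
            img = np.zeros((n, n), dtype=complex)
            for b, f in zip(bs, fps[t]):
                img = img + b * f
        else:
            img = np.zeros((n, n), dtype=complex)
            for b, f in zip(bases, fps[t]):
                img = img + b * f
            tx, ty, th = states[t]
            if tx or ty or th:
                img = apply_rigid(img, tx, ty, th, pixel_mm=pixel_mm, order=interp_order)
        op = NUFFT2D(traj.coords[t], n, width=nufft_width)
        for c in range(nc):
            out[t, :, c] = op.forward(coils.maps[c] * img)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + noise_sd * (
            rng.standard_normal(out.shape) + 1j * rng.standard_normal(out.shape)
        )
    return KSpaceData(samples=out, traj=traj, coils=coils)
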