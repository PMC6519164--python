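"""Extended phase graph (EPG) simulation of FISP-type fingerprints.

The EPG formalism tracks the magnetization of a voxel as a small set of
dephasing configuration states ``(F+_k, F-_k, Z_k)`` instead of a continuum of
isochromats.  For an unbalanced (gradient-spoiled) sequence the spoiler shifts
every transverse state by one configuration order per TR, and the acquired
echo is the ``F0`` state.  Each TR is modelled as:

1. instantaneous RF rotation by ``fa_scale * FA_n`` (constant RF phase),
2. echo readout: ``signal_n = F0 * exp(-TE/T2)``,
3. T1/T2 relaxation and Mz recovery over the full TR,
4. unit gradient-spoiler shift of the configuration ladder.

An ideal (unscaled) 180° inversion may precede the first TR.  All routines are
vectorized over a batch of ``(T1, T2, fa_scale)`` tuples.
"""

from __future__ import annotations

import logging

import numpy as np

from .sequence import SequenceParams, SliceProfile

__all__ = ["epg_fisp_signal", "epg_fisp_signal_batch", "epg_with_slice_profile"]

logger = logging.getLogger(__name__)


def _rf_matrix(alpha_rad: np.ndarray) -> np.ndarray:
    """EPG rotation mixing matrix for flip ``alpha`` at RF phase 0.

    Returns an array of shape (3, 3, B) acting on stacked ``(F+, F-, Z)``.
    """
    a = np.asarray(alpha_rad, dtype=float)
    ca2 = np.cos(a / 2) ** 2
    sa2 = np.sin(a / 2) ** 2
    sa = np.sin(a)
    ca = np.cos(a)
    z = np.zeros_like(a)
    m = np.array(
        [
            [ca2 + z * 1j, sa2 + z * 1j, -1j * sa],
            [sa2 + z * 1j, ca2 + z * 1j, 1j * sa],
            [-0.5j * sa, 0.5j * sa, ca + z * 1j],
        ]
    )
    return m


def epg_fisp_signal_batch(
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    seq: SequenceParams,
    fa_scale: np.ndarray | float = 1.0,
    max_states: int | None = None,
) -> np.ndarray:
    """Simulate fingerprints for a batch of (T1, T2, fa_scale) tuples.

    Parameters
    ----------
    t1_ms, t2_ms : array_like
        Relaxation times in ms, broadcast to a common batch shape.
    seq : SequenceParams
        Flip-angle train and timing.
    fa_scale : array_like or float
        Multiplicative flip-angle scale per batch element, in (0, 1].  The
        inversion pulse, when present, is ideal and not scaled.
    max_states : int, optional
        Configuration-order truncation; default ``min(Nt, 100)``.

    Returns
    -------
    ndarray, complex, shape (Nt, B)
        One fingerprint column per batch element.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    scale = np.atleast_1d(np.asarray(fa_scale, dtype=float))
    t1, t2, scale = np.broadcast_arrays(t1, t2, scale)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("T1 and T2 must be positive")
    if np.any(scale <= 0) or np.any(scale > 1):
        raise ValueError("fa_scale must lie in (0, 1]")
    if np.any(t2 > t1):
        logger.warning("dictionary contains entries with T2 > T1 (kept)")

    nt = seq.n_timepoints
    n_states = max_states if max_states is not None else min(nt, 100)
    n_states = max(2, int(n_states))
    batch = t1.size

    e1 = np.exp(-seq.tr_ms / t1)  # (B,)
    e2 = np.exp(-seq.tr_ms / t2)
    ete = np.exp(-seq.te_ms / t2)

    fp = np.zeros((n_states, batch), dtype=complex)
    fm = np.zeros((n_states, batch), dtype=complex)
    zz = np.zeros((n_states, batch), dtype=complex)
    zz[0] = -1.0 if seq.invert else 1.0

    alphas = np.deg2rad(seq.flip_angles)
    out = np.empty((nt, batch), dtype=complex)
    for n in range(nt):
        r = _rf_matrix(alphas[n] * scale)  # (3, 3, B)
        fp_new = r[0, 0] * fp + r[0, 1] * fm + r[0, 2] * zz
        fm_new = r[1, 0] * fp + r[1, 1] * fm + r[1, 2] * zz
        zz_new = r[2, 0] * fp + r[2, 1] * fm + r[2, 2] * zz
        fp, fm, zz = fp_new, fm_new, zz_new

        out[n] = fp[0] * ete

        fp *= e2
        fm *= e2
        zz *= e1
        zz[0] += 1.0 - e1

        # spoiler: F+ ladder up, F- ladder down; F+_0 refills from F-_0.
        fp[1:] = fp[:-1]
        fm[:-1] = fm[1:]
        fm[-1] = 0.0
        fp[0] = np.conj(fm[0])
    return out


def epg_fisp_signal(
    t1_ms: float,
    t2_ms: float,
    seq: SequenceParams,
    fa_scale: float = 1.0,
    max_states: int | None = None,
) -> np.ndarray:
    """Single-voxel FISP fingerprint; see :func:`epg_fisp_signal_batch`."""
    return epg_fisp_signal_batch(t1_ms, t2_ms, seq, fa_scale, max_states)[:, 0]


def epg_with_slice_profile(
    t1_ms,
    t2_ms,
    seq: SequenceParams,
    profile: SliceProfile,
    max_states: int | None = None,
) -> np.ndarray:
    """Slice-profile-corrected fingerprint(s).

    Averages :func:`epg_fisp_signal` over the profile's flip-angle scales,
    modelling the flip-angle variation across the excited slice.  Accepts
    scalar or equal-shape arrays of T1/T2; returns shape ``(Nt,)`` for scalars
    or ``(Nt, B)`` for arrays.
    """
    if len(profile) == 0:
        raise ValueError("slice profile is empty")
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    if t1.shape != t2.shape:
        raise ValueError("t1 and t2 must have the same shape")
    npts = len(profile)
    b = t1.size
    # batch layout: (voxel, slice point) flattened
    t1b = np.repeat(t1, npts)
    t2b = np.repeat(t2, npts)
    scb = np.tile(profile.scale, b)
    sig = epg_fisp_signal_batch(t1b, t2b, seq, scb, max_states)
    sig = sig.reshape(seq.n_timepoints, b, npts).mean(axis=2)
    if np.isscalar(t1_ms) or np.asarray(t1_ms).ndim == 0:
        return sig[:, 0]
    return sig
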