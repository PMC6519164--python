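"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: the isochromat
simulator integrates Bloch rotations over an ensemble of dephased spins, and
the dense encoding matrices evaluate the exact DFT sums.
"""

import numpy as np


def isochromat_fingerprint(t1_ms, t2_ms, seq, n_spins=401, fa_scale=1.0):
    """Bloch-rotation ensemble simulation of a gradient-spoiled fingerprint.

    ``n_spins`` isochromats uniformly dephased over 2π per TR; the signal is
    the ensemble-mean transverse magnetization right after each RF pulse,
    attenuated by exp(-TE/T2).
    """
    phis = 2 * np.pi * np.arange(n_spins) / n_spins
    m = np.zeros((3, n_spins))
    m[2] = -1.0 if seq.invert else 1.0
    e1 = np.exp(-seq.tr_ms / t1_ms)
    e2 = np.exp(-seq.tr_ms / t2_ms)
    ete = np.exp(-seq.te_ms / t2_ms)
    out = np.empty(seq.n_timepoints, complex)
    for n in range(seq.n_timepoints):
        a = np.deg2rad(seq.flip_angles[n] * fa_scale)
        my = m[1] * np.cos(a) - m[2] * np.sin(a)
        mz = m[1] * np.sin(a) + m[2] * np.cos(a)
        m[1], m[2] = my, mz
        out[n] = (m[0] + 1j * m[1]).mean() * ete
        mxy = (m[0] + 1j * m[1]) * e2 * np.exp(1j * phis)
        m[0], m[1] = mxy.real, mxy.imag
        m[2] = 1 + (m[2] - 1) * e1
    return out


def dense_dft_matrix(coords, matrix):
    """Exact DFT encoding matrix: (Nsamples, matrix²), center-origin."""
    pts = np.asarray(coords, dtype=float).reshape(-1, 2)
    p = np.arange(matrix) - matrix // 2
    px, py = np.meshgrid(p, p, indexing="xy")
    return np.exp(
        -2j
        * np.pi
        * (
            pts[:, 0, None] * px.ravel()[None, :]
            + pts[:, 1, None] * py.ravel()[None, :]
        )
    )


def dense_sense_matrix(coords, coil_maps):
    """Stacked per-coil encoding matrix: (Nc·Nsamples, matrix²)."""
    matrix = coil_maps.shape[-1]
    e = dense_dft_matrix(coords, matrix)
    return np.vstack([e * c.ravel()[None, :] for c in coil_maps])


def dense_lowrank_matrix(coords_per_tp, coil_maps, basis):
    """Dense forward matrix of the subspace reconstruction.

    Rows: all samples of all time points and coils; columns: R·matrix²
    coefficient-image unknowns.
    """
    nt, ns = coords_per_tp.shape[:2]
    nc = coil_maps.shape[0]
    matrix = coil_maps.shape[-1]
    rank = basis.shape[1]
    blocks = []
    for c in range(nc):
        rows = np.empty((nt * ns, rank * matrix * matrix), complex)
        for t in range(nt):
            e = dense_dft_matrix(coords_per_tp[t], matrix) * coil_maps[c].ravel()[None, :]
            for r in range(rank):
                rows[t * ns : (t + 1) * ns, r * matrix**2 : (r + 1) * matrix**2] = (
                    basis[t, r] * e
                )
        blocks.append(rows)
    return np.vstack(blocks)
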