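"""Fingerprint dictionaries: grid parsing, simulation, SVD compression, I/O.

A dictionary is the matrix of simulated fingerprints over a Cartesian grid of
(T1, T2) pairs.  Fingerprint dictionaries are highly compressible in time: the
rank-R truncated left singular basis ``U_R`` of the atom matrix spans almost
all signal energy and is reused both for matching and as the temporal subspace
of the low-rank reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .epg import epg_with_slice_profile
from .sequence import SequenceParams, SliceProfile

__all__ = [
    "Dictionary",
    "CompressedDictionary",
    "parse_grid",
    "build_dictionary",
    "compress_dictionary",
    "save_dictionary",
    "load_dictionary",
    "PHANTOM_T1_GRID",
    "PHANTOM_T2_GRID",
    "BRAIN_T1_GRID",
    "BRAIN_T2_GRID",
]

logger = logging.getLogger(__name__)

# (start, step, stop) segments of the reference dictionaries, in ms.
PHANTOM_T1_GRID = [(0, 30, 200), (200, 10, 600), (600, 20, 1200), (1200, 30, 1600)]
PHANTOM_T2_GRID = [(0, 2, 70), (70, 10, 120), (120, 5, 270)]
BRAIN_T1_GRID = [(0, 10, 800), (800, 40, 1400), (1400, 300, 6000)]
BRAIN_T2_GRID = [(0, 5, 100), (100, 10, 500), (500, 50, 1000), (1000, 300, 2600)]


@dataclass
class Dictionary:
    """Fingerprint atoms over a (T1, T2) grid.

    Attributes
    ----------
    atoms : ndarray, complex, (Nt, Na)
        One fingerprint per column, T1-major / T2-minor ordering.
    entries : ndarray, float, (Na, 2)
        (T1_ms, T2_ms) per atom.
    atom_norms : ndarray, float, (Na,)
        Euclidean norm of each atom.
    seq : SequenceParams
    """

    atoms: np.ndarray
    entries: np.ndarray
    seq: SequenceParams
    atom_norms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.atoms.ndim != 2 or self.entries.shape != (self.atoms.shape[1], 2):
            raise ValueError("atoms (Nt,Na) and entries (Na,2) are inconsistent")
        if np.any(self.entries <= 0):
            raise ValueError("all T1/T2 entries must be positive")
        uniq = np.unique(self.entries, axis=0)
        if uniq.shape[0] != self.entries.shape[0]:
            raise ValueError("duplicate (T1, T2) entries")
        self.atom_norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(self.atom_norms <= 0):
            raise ValueError("zero-norm atom encountered")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.atoms.shape[0]


@dataclass
class CompressedDictionary:
    """Rank-R SVD subspace of a dictionary.

    ``basis`` holds the first R left singular vectors ``U_R`` (orthonormal
    columns, Nt × R); ``compressed_atoms = U_Rᴴ · atoms`` (R × Na).
    ``energy_fraction`` is the captured squared-Frobenius-norm fraction.
    """

    basis: np.ndarray
    compressed_atoms: np.ndarray
    parent: Dictionary
    energy_fraction: float

    @property
    def rank(self) -> int:
        return self.basis.shape[1]


def parse_grid(segments) -> np.ndarray:
    """Expand (start, step, stop) segments into sorted unique grid values.

    Each segment enumerates ``start, start+step, …`` up to the largest value
    not exceeding ``stop`` (inclusive when it lands exactly), the usual
    colon-range convention; segments are concatenated, deduplicated and sorted.
    """
    values = []
    for start, step, stop in segments:
        if step <= 0:
            raise ValueError("grid step must be positive")
        if stop < start:
            raise ValueError("grid stop must be >= start")
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        values.append(start + step * np.arange(n))
    vals = np.concatenate(values)
    return np.unique(np.round(vals, 6))


def build_dictionary(
    t1_grid,
    t2_grid,
    seq: SequenceParams,
    profile: SliceProfile,
    exclude_t2_ge_t1: bool = False,
    max_states: int | None = None,
    chunk: int = 4096,
) -> Dictionary:
    """Simulate the dictionary for the Cartesian product of two grids.

    Zero T1/T2 values (present in the printed grids) are dropped before
    simulation — zero relaxation times are non-physical and would produce
    undefined normalized atoms.  Pairs with T2 ≥ T1 are kept by default,
    mirroring the printed grids; ``exclude_t2_ge_t1`` prunes them.
    """
    t1g = np.asarray(t1_grid, dtype=float)
    t2g = np.asarray(t2_grid, dtype=float)
    if np.any(t1g == 0) or np.any(t2g == 0):
        logger.info(
            "dropping %d zero T1 and %d zero T2 grid values",
            int(np.sum(t1g == 0)),
            int(np.sum(t2g == 0)),
        )
    t1g = np.unique(t1g[t1g > 0])
    t2g = np.unique(t2g[t2g > 0])
    if t1g.size == 0 or t2g.size == 0:
        raise ValueError("empty grid after zero removal")
    tt1, tt2 = np.meshgrid(t1g, t2g, indexing="ij")  # T1-major ordering
    entries = np.column_stack([tt1.ravel(), tt2.ravel()])
    if exclude_t2_ge_t1:
        entries = entries[entries[:, 1] < entries[:, 0]]
    na = entries.shape[0]
    atoms = np.empty((seq.n_timepoints, na), dtype=complex)
    for lo in range(0, na, chunk):
        hi = min(lo + chunk, na)
        atoms[:, lo:hi] = epg_with_slice_profile(
            entries[lo:hi, 0], entries[lo:hi, 1], seq, profile, max_states
        )
    return Dictionary(atoms=atoms, entries=entries, seq=seq)


def compress_dictionary(dictionary: Dictionary, rank: int) -> CompressedDictionary:
    """Truncated-SVD temporal compression of a dictionary."""
    nt, na = dictionary.atoms.shape
    if not 1 <= rank <= min(nt, na):
        raise ValueError(f"rank must lie in [1, {min(nt, na)}]")
    u, s, _ = np.linalg.svd(dictionary.atoms, full_matrices=False)
    basis = u[:, :rank]
    energy = float(np.sum(s[:rank] ** 2) / np.sum(s**2))
    return CompressedDictionary(
        basis=basis,
        compressed_atoms=basis.conj().T @ dictionary.atoms,
        parent=dictionary,
        energy_fraction=energy,
    )


def save_dictionary(path, cdict: CompressedDictionary) -> None:
    """Store a compressed dictionary (atoms, entries, basis, sequence) in HDF5."""
    d = cdict.parent
    with h5py.File(path, "w") as f:
        f.create_dataset("atoms", data=d.atoms)
        f.create_dataset("entries", data=d.entries)
        f.create_dataset("basis", data=cdict.basis)
        f.create_dataset("flip_angles", data=d.seq.flip_angles)
        f.attrs["tr_ms"] = d.seq.tr_ms
        f.attrs["te_ms"] = d.seq.te_ms
        f.attrs["invert"] = d.seq.invert
        f.attrs["energy_fraction"] = cdict.energy_fraction


def load_dictionary(path) -> CompressedDictionary:
    """Load a compressed dictionary written by :func:`save_dictionary`."""
    with h5py.File(path, "r") as f:
        seq = SequenceParams(
            flip_angles=f["flip_angles"][:],
            tr_ms=float(f.attrs["tr_ms"]),
            te_ms=float(f.attrs["te_ms"]),
            invert=bool(f.attrs["invert"]),
        )
        d = Dictionary(atoms=f["atoms"][:], entries=f["entries"][:], seq=seq)
        basis = f["basis"][:]
        energy = float(f.attrs["energy_fraction"])
    return CompressedDictionary(
        basis=basis,
        compressed_atoms=basis.conj().T @ d.atoms,
        parent=d,
        energy_fraction=energy,
    )
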