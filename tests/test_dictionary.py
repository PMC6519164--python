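"""Grid parsing, dictionary building and SVD compression."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from mrfmoco.dictionary import (
    BRAIN_T1_GRID,
    BRAIN_T2_GRID,
    PHANTOM_T2_GRID,
    build_dictionary,
    compress_dictionary,
    load_dictionary,
    parse_grid,
    save_dictionary,
)
from mrfmoco.epg import epg_with_slice_profile
from mrfmoco.sequence import SequenceParams, default_flip_angles


def _enumerate(segments):
    vals = set()
    for start, step, stop in segments:
        v = start
        while v <= stop + 1e-9:
            vals.add(round(v, 6))
            v += step
    return sorted(vals)


class TestParseGrid:
    def test_single_segment_stops_before_overshoot(self):
        assert parse_grid([(0, 30, 200)]).tolist() == [0, 30, 60, 90, 120, 150, 180]

    def test_single_point_segment(self):
        assert parse_grid([(100, 50, 100)]).tolist() == [100]

    @pytest.mark.parametrize("segments", [PHANTOM_T2_GRID, BRAIN_T1_GRID, BRAIN_T2_GRID])
    def test_matches_brute_force_enumeration(self, segments):
        assert parse_grid(segments).tolist() == _enumerate(segments)

    def test_invalid_segments_rejected(self):
        with pytest.raises(ValueError):
            parse_grid([(0, -1, 10)])
        with pytest.raises(ValueError):
            parse_grid([(10, 1, 5)])

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 500),
                st.integers(1, 60),
                st.integers(0, 400),
            ).map(lambda s: (s[0], s[1], s[0] + s[2])),
            min_size=1,
            max_size=4,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_property_matches_enumeration(self, segments):
        """Any colon-range spec expands to its brute-force enumeration."""
        assert parse_grid(segments).tolist() == _enumerate(segments)


class TestBuildDictionary:
    def test_single_pair_equals_direct_simulation(self, short_seq, tiny_profile):
        d = build_dictionary([500.0], [50.0], short_seq, tiny_profile)
        assert d.n_atoms == 1
        direct = epg_with_slice_profile(500, 50, short_seq, tiny_profile)
        assert np.allclose(d.atoms[:, 0], direct)

    def test_atom_count_matches_enumeration(self, tiny_profile):
        """Product of deduplicated positive grid values, zeros dropped."""
        seq = SequenceParams(flip_angles=default_flip_angles(3))
        t1 = parse_grid(BRAIN_T1_GRID)
        t2 = parse_grid(BRAIN_T2_GRID)
        d = build_dictionary(t1, t2, seq, tiny_profile, max_states=3)
        expected = len([v for v in _enumerate(BRAIN_T1_GRID) if v > 0]) * len(
            [v for v in _enumerate(BRAIN_T2_GRID) if v > 0]
        )
        assert d.n_atoms == expected

    def test_duplicate_grid_values_deduplicated(self, short_seq, tiny_profile):
        d = build_dictionary([500.0, 500.0], [50.0], short_seq, tiny_profile)
        assert d.n_atoms == 1

    def test_t2_exclusion_switch(self, short_seq, tiny_profile):
        d_all = build_dictionary([100.0, 300.0], [50.0, 200.0], short_seq, tiny_profile)
        d_phys = build_dictionary(
            [100.0, 300.0], [50.0, 200.0], short_seq, tiny_profile, exclude_t2_ge_t1=True
        )
        assert d_all.n_atoms == 4
        assert d_phys.n_atoms == 3  # (100, 200) pruned

    def test_ordering_is_t1_major(self, short_seq, tiny_profile):
        d = build_dictionary([100.0, 300.0], [30.0, 60.0], short_seq, tiny_profile)
        assert d.entries.tolist() == [[100, 30], [100, 60], [300, 30], [300, 60]]


@pytest.fixture(scope="module")
def small_dict(short_seq, tiny_profile):
    return build_dictionary(
        np.arange(200.0, 1800.0, 200.0),
        np.arange(20.0, 260.0, 40.0),
        short_seq,
        tiny_profile,
    )


class TestCompression:

    def test_full_rank_reconstructs_exactly(self, small_dict):
        full = min(small_dict.atoms.shape)
        c = compress_dictionary(small_dict, full)
        recon = c.basis @ (c.basis.conj().T @ small_dict.atoms)
        assert np.linalg.norm(recon - small_dict.atoms) < 1e-8

    def test_energy_fraction_matches_independent_svd(self, small_dict):
        c = compress_dictionary(small_dict, 10)
        s = scipy.linalg.svdvals(small_dict.atoms)
        assert c.energy_fraction == pytest.approx(np.sum(s[:10] ** 2) / np.sum(s**2), rel=1e-10)

    def test_basis_orthonormal(self, small_dict):
        c = compress_dictionary(small_dict, 10)
        g = c.basis.conj().T @ c.basis
        assert np.abs(g - np.eye(10)).max() < 1e-10

    def test_residual_monotone_in_rank(self, small_dict):
        res = []
        for r in (2, 4, 8, 12):
            c = compress_dictionary(small_dict, r)
            proj = c.basis @ c.compressed_atoms
            res.append(np.linalg.norm(proj - small_dict.atoms))
        assert all(a >= b - 1e-12 for a, b in zip(res, res[1:]))

    def test_rank_one_dictionary_exact_at_r1(self, short_seq):
        atom = np.exp(-np.arange(short_seq.n_timepoints) / 40) + 0j
        atoms = np.outer(atom, [1.0, 2.0, 0.5])
        from mrfmoco.dictionary import Dictionary

        d = Dictionary(
            atoms=atoms,
            entries=np.array([[100.0, 10.0], [200.0, 20.0], [300.0, 30.0]]),
            seq=short_seq,
        )
        c = compress_dictionary(d, 1)
        proj = c.basis @ c.compressed_atoms
        assert np.linalg.norm(proj - atoms) < 1e-10

    def test_rank_bounds(self, small_dict):
        with pytest.raises(ValueError):
            compress_dictionary(small_dict, 0)
        with pytest.raises(ValueError):
            compress_dictionary(small_dict, 10_000)

    def test_hdf5_round_trip(self, small_dict, tmp_path):
        c = compress_dictionary(small_dict, 6)
        p = tmp_path / "dict.h5"
        save_dictionary(p, c)
        c2 = load_dictionary(p)
        assert np.allclose(c2.basis, c.basis)
        assert np.allclose(c2.parent.atoms, small_dict.atoms)
        assert c2.rank == 6
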