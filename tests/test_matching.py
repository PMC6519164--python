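"""Dictionary matching: exact matches, invariances, vial null test, IBMC."""

import numpy as np
import pytest

from mrfmoco.coils import simulate_coil_maps
from mrfmoco.dictionary import build_dictionary, compress_dictionary
from mrfmoco.matching import ibmc_pipeline, match, match_timeseries
from mrfmoco.phantom import vial_phantom
from mrfmoco.recon import SingularImages, SlidingWindowSeries, low_rank_inversion, sliding_window_series
from mrfmoco.sequence import SequenceParams, default_flip_angles
from mrfmoco.simulate import simulate_mrf_kspace, tissue_dictionary
from mrfmoco.trajectory import golden_radial, voronoi_dcf


@pytest.fixture(scope="module")
def cdict(short_seq, tiny_profile):
    d = build_dictionary(
        np.arange(200.0, 1600.0, 200.0),
        np.arange(20.0, 200.0, 30.0),
        short_seq,
        tiny_profile,
    )
    return compress_dictionary(d, 6)


class TestMatch:
    def test_exact_atom_returns_its_entry(self, cdict):
        j = 17
        sig = cdict.compressed_atoms[:, j]
        coeffs = np.tile(sig[:, None, None], (1, 2, 2))
        maps = match(SingularImages(coeffs=coeffs, basis=cdict.basis), cdict)
        assert np.all(maps.t1_ms == cdict.parent.entries[j, 0])
        assert np.all(maps.t2_ms == cdict.parent.entries[j, 1])
        assert maps.m0_magnitude[0, 0] == pytest.approx(1.0, rel=1e-9)
        assert maps.match_correlation[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_global_phase_flip_same_match(self, cdict):
        j = 5
        sig = -cdict.compressed_atoms[:, j]  # global sign/phase flip
        coeffs = sig[:, None, None]
        maps = match(SingularImages(coeffs=coeffs, basis=cdict.basis), cdict)
        assert maps.t1_ms[0, 0] == cdict.parent.entries[j, 0]
        assert maps.match_correlation[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_complex_scaling_changes_only_m0(self, cdict):
        j = 11
        sig = cdict.compressed_atoms[:, j]
        for scale in (0.5, 2.0 * np.exp(1j * 0.7)):
            coeffs = (scale * sig)[:, None, None]
            maps = match(SingularImages(coeffs=coeffs, basis=cdict.basis), cdict)
            assert maps.t1_ms[0, 0] == cdict.parent.entries[j, 0]
            assert maps.t2_ms[0, 0] == cdict.parent.entries[j, 1]
            assert maps.m0_magnitude[0, 0] == pytest.approx(abs(scale), rel=1e-9)

    def test_zero_signal_pixel_unmatched(self, cdict):
        coeffs = np.zeros((cdict.rank, 2, 2), complex)
        maps = match(SingularImages(coeffs=coeffs, basis=cdict.basis), cdict)
        assert np.all(maps.t1_ms == 0) and np.all(maps.match_correlation == 0)

    def test_basis_mismatch_rejected(self, cdict):
        other = np.linalg.qr(np.random.default_rng(0).standard_normal(cdict.basis.shape))[0]
        si = SingularImages(coeffs=np.zeros((cdict.rank, 2, 2), complex), basis=other)
        with pytest.raises(ValueError):
            match(si, cdict)

    def test_timeseries_matching_mirrors_compressed(self, cdict):
        j = 9
        d = cdict.parent
        imgs = np.tile(d.atoms[:, j][:, None, None], (1, 2, 2))
        maps = match_timeseries(imgs, d)
        assert np.all(maps.t1_ms == d.entries[j, 0])
        assert np.all(maps.t2_ms == d.entries[j, 1])


class TestEndToEndVials:
    def test_noiseless_grid_aligned_vials_match_exactly(self, tiny_profile):
        """Motion-free pipeline returns exact T1/T2 on dictionary nodes."""
        n, nt = 64, 300
        seq = SequenceParams(flip_angles=default_flip_angles(nt))
        t1s = [300.0, 700.0, 1100.0, 1500.0]
        t2s = [40.0, 80.0, 140.0, 200.0]
        maps = vial_phantom(n, 320.0, t1s, t2s)
        tdict = tissue_dictionary(maps, seq, tiny_profile)
        # matching dictionary contains the vial nodes plus distractors
        d = build_dictionary(
            np.concatenate([t1s, [200.0, 500.0, 900.0, 1300.0]]),
            np.concatenate([t2s, [20.0, 60.0, 110.0, 170.0]]),
            seq,
            tiny_profile,
        )
        cd = compress_dictionary(d, 8)
        traj = golden_radial(nt, n, n)
        coils = simulate_coil_maps(4, n, 320.0)
        kd = simulate_mrf_kspace(maps, seq, tdict, traj, coils)
        si = low_rank_inversion(
            kd.samples, traj, voronoi_dcf(traj.coords), coils, cd.basis
        )
        matched = match(si, cd)
        # exactness is asserted at each vial's center (away from edges)
        from scipy.ndimage import center_of_mass, binary_erosion

        for t1, t2 in maps.unique_tissues():
            vial = maps.mask & (maps.t1_ms == t1) & (maps.t2_ms == t2)
            r, c = (int(round(v)) for v in center_of_mass(vial))
            assert matched.t1_ms[r, c] == t1
            assert matched.t2_ms[r, c] == t2
        # and the bulk of every vial matches both values exactly
        core = binary_erosion(maps.mask, iterations=2)
        frac = np.mean(
            (matched.t1_ms[core] == maps.t1_ms[core])
            & (matched.t2_ms[core] == maps.t2_ms[core])
        )
        assert frac > 0.9


class TestIBMC:
    def test_static_series_matches_plain_matching(self, cdict, tiny_profile):
        """With no motion, IBMC reduces to window matching (same argmax)."""
        n = 32
        seq = cdict.parent.seq
        nt = seq.n_timepoints
        maps = vial_phantom(n, 320.0, [600.0, 1000.0], [50.0, 110.0])
        tdict = tissue_dictionary(maps, seq, tiny_profile)
        traj = golden_radial(nt, n, n)
        coils = simulate_coil_maps(2, n, 320.0)
        kd = simulate_mrf_kspace(maps, seq, tdict, traj, coils)
        series = sliding_window_series(kd.samples, traj, coils, window=30, stride=10)
        ib = ibmc_pipeline(series, cdict.parent)
        plain = match_timeseries(
            series.images, cdict.parent, timepoints=series.window_center_timepoint
        )
        from scipy.ndimage import binary_erosion

        core = binary_erosion(maps.mask, iterations=2)
        # static data: registration is (near-)identity, so IBMC reduces to
        # plain matching of the same window series on almost every pixel
        agree = (ib.t1_ms[core] == plain.t1_ms[core]) & (
            ib.t2_ms[core] == plain.t2_ms[core]
        )
        assert np.mean(agree) > 0.95
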