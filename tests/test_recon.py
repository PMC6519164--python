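"""CG reconstructions against dense-matrix oracles and exact recoveries."""

import numpy as np
import pytest
import scipy.sparse.linalg

from mrfmoco.coils import simulate_coil_maps
from mrfmoco.recon import (
    SingularImages,
    cg_sense,
    low_rank_inversion,
    sliding_window_series,
)
from mrfmoco.trajectory import RadialTrajectory, golden_radial, voronoi_dcf

from _oracles import dense_lowrank_matrix, dense_sense_matrix


def _cartesian_coords(n):
    g = (np.arange(n) - n // 2) / n
    kx, ky = np.meshgrid(g, g, indexing="xy")
    return np.stack([kx, ky], -1).reshape(-1, 2)


def _dense_cg(a_mat, w, k, iters):
    """Independent CG on the dense weighted normal equations (scipy)."""
    ah_w = a_mat.conj().T * w[None, :]
    normal = ah_w @ a_mat
    rhs = ah_w @ k
    x, _ = scipy.sparse.linalg.cg(normal, rhs, maxiter=iters, rtol=1e-30, x0=np.zeros_like(rhs))
    return x


class TestCgSense:
    def test_cartesian_single_coil_recovers_image(self, rng):
        n = 16
        img = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        coords = _cartesian_coords(n)
        coils = simulate_coil_maps(1, n)
        from mrfmoco.nufft import NUFFT2D

        y = NUFFT2D(coords, n, width=8).forward(img)[:, None]
        rec = cg_sense(y, coords, np.ones(len(coords)), coils, max_iter=15, nufft_width=8)
        assert np.linalg.norm(rec - img) / np.linalg.norm(img) < 1e-6

    def test_matches_dense_matrix_oracle(self, rng):
        """8×8 grid, 20 spokes: operator CG equals dense-DFT CG at equal
        iteration count, and converges to the dense pseudo-inverse."""
        n, nc = 8, 2
        traj = golden_radial(20, n, n)
        coils = simulate_coil_maps(nc, n)
        x = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        pts = traj.coords.reshape(-1, 2)
        e = dense_sense_matrix(pts, coils.maps)
        dcf = voronoi_dcf(traj.coords).ravel()
        w = np.tile(dcf, nc)
        k_stacked = e @ x.ravel()
        kdata = k_stacked.reshape(nc, -1).T
        # (a) equal-iteration comparison isolates operator correctness
        rec15 = cg_sense(kdata, pts, dcf, coils, max_iter=15)
        ref15 = _dense_cg(e, w, k_stacked, 15)
        assert np.linalg.norm(rec15.ravel() - ref15) / np.linalg.norm(ref15) < 1e-3
        # (b) un-capped CG converges to the dense weighted least-squares sol.
        rec = cg_sense(kdata, pts, dcf, coils, max_iter=500, tol=0.0)
        ref = np.linalg.lstsq(np.sqrt(w)[:, None] * e, np.sqrt(w) * k_stacked, rcond=None)[0]
        assert np.linalg.norm(rec.ravel() - ref) / np.linalg.norm(ref) < 1e-3

    def test_data_residual_non_increasing(self, rng):
        """The weighted data residual decreases monotonically with the CG
        iteration count (CG minimizes it over nested Krylov spaces; with zero
        init the k-iteration run is a prefix of the (k+1)-iteration run)."""
        n, nc = 8, 2
        traj = golden_radial(12, n, n)
        coils = simulate_coil_maps(nc, n)
        pts = traj.coords.reshape(-1, 2)
        dcf = voronoi_dcf(traj.coords).ravel()
        e = dense_sense_matrix(pts, coils.maps)
        w = np.tile(dcf, nc)
        x = rng.standard_normal(n * n) + 1j * rng.standard_normal(n * n)
        noise = 0.1 * (rng.standard_normal(e.shape[0]) + 1j * rng.standard_normal(e.shape[0]))
        k_stacked = e @ x + noise
        kdata = k_stacked.reshape(nc, -1).T
        res = []
        for iters in (1, 3, 6, 10, 15, 25):
            rec = cg_sense(kdata, pts, dcf, coils, max_iter=iters)
            res.append(np.linalg.norm(np.sqrt(w) * (e @ rec.ravel() - k_stacked)))
        assert all(a >= b - 1e-10 for a, b in zip(res, res[1:]))

    def test_linearity_at_convergence(self, rng):
        """The converged least-squares map data → image is linear.  (At a
        small fixed iteration count CG itself is not exactly linear in the
        data, so linearity is asserted at convergence.)"""
        n = 8
        traj = golden_radial(10, n, n)
        coils = simulate_coil_maps(2, n)
        pts = traj.coords.reshape(-1, 2)
        dcf = voronoi_dcf(traj.coords).ravel()
        k1 = rng.standard_normal((len(pts), 2)) + 1j * rng.standard_normal((len(pts), 2))
        k2 = rng.standard_normal((len(pts), 2)) + 1j * rng.standard_normal((len(pts), 2))
        a, b = 1.7, -0.4 + 0.2j
        r1 = cg_sense(k1, pts, dcf, coils, max_iter=500, tol=0.0)
        r2 = cg_sense(k2, pts, dcf, coils, max_iter=500, tol=0.0)
        r12 = cg_sense(a * k1 + b * k2, pts, dcf, coils, max_iter=500, tol=0.0)
        ref = a * r1 + b * r2
        assert np.linalg.norm(r12 - ref) / np.linalg.norm(ref) < 1e-6

    def test_empty_data_rejected(self):
        coils = simulate_coil_maps(1, 8)
        with pytest.raises(ValueError):
            cg_sense(np.empty((0, 1)), np.empty((0, 2)), np.empty(0), coils)


@pytest.fixture(scope="module")
def small_acq():
    rng = np.random.default_rng(0)
    n, nt = 16, 40
    traj = golden_radial(nt, n, n)
    coils = simulate_coil_maps(2, n)
    kdata = rng.standard_normal((nt, n, 2)) + 1j * rng.standard_normal((nt, n, 2))
    return n, nt, traj, coils, kdata


class TestSlidingWindow:

    def test_full_window_single_image(self, small_acq):
        n, nt, traj, coils, kdata = small_acq
        s = sliding_window_series(kdata, traj, coils, window=nt, stride=1)
        assert s.n_windows == 1
        ref = cg_sense(
            kdata.reshape(-1, 2), traj.coords.reshape(-1, 2),
            voronoi_dcf(traj.coords), coils,
        )
        assert np.allclose(s.images[0], ref)

    def test_non_overlapping_tiling(self, small_acq):
        n, nt, traj, coils, kdata = small_acq
        s = sliding_window_series(kdata, traj, coils, window=10, stride=10)
        assert s.n_windows == nt // 10
        assert s.window_center_timepoint.tolist() == [5, 15, 25, 35]

    def test_window_count_stride_one(self, small_acq):
        n, nt, traj, coils, kdata = small_acq
        s = sliding_window_series(kdata, traj, coils, window=30, stride=1)
        assert s.n_windows == nt - 30 + 1


class TestLowRankInversion:
    def test_exact_subspace_r1(self, rng):
        """Static object whose fingerprint is the basis vector is recovered.

        Each time point samples one Cartesian k-space row, so the union of
        all TRs covers k-space completely and the R=1 solution is unique.
        """
        from mrfmoco.nufft import NUFFT2D

        n = 16
        nt = n
        g = (np.arange(n) - n // 2) / n
        coords = np.empty((nt, n, 2))
        for t in range(nt):
            coords[t, :, 0] = g
            coords[t, :, 1] = g[t]
        traj = RadialTrajectory(coords=coords, angles=np.zeros(nt), matrix=n)
        coils = simulate_coil_maps(1, n)
        basis = np.ones((nt, 1), complex) / np.sqrt(nt)
        obj = np.zeros((n, n), complex)
        obj[4:12, 5:11] = 1.0 + 0.5j
        kdata = np.empty((nt, n, 1), complex)
        for t in range(nt):
            kdata[t, :, 0] = NUFFT2D(coords[t], n).forward(obj * basis[t, 0])
        si = low_rank_inversion(
            kdata, traj, np.ones((nt, n)), coils, basis, max_iter=50
        )
        err = np.linalg.norm(si.coeffs[0] - obj) / np.linalg.norm(obj)
        assert err < 1e-4

    def test_matches_dense_matrix_oracle(self, rng):
        """8×8 grid, Nt=24, R=3 against the assembled dense forward matrix."""
        n, nt, rank, nc = 8, 24, 3, 2
        traj = golden_radial(nt, n, n)
        coils = simulate_coil_maps(nc, n)
        basis = np.linalg.qr(
            rng.standard_normal((nt, rank)) + 1j * rng.standard_normal((nt, rank))
        )[0]
        coeffs = rng.standard_normal((rank, n, n)) + 1j * rng.standard_normal((rank, n, n))
        a = dense_lowrank_matrix(traj.coords, coils.maps, basis)
        k_stacked = a @ coeffs.ravel()
        kdata = k_stacked.reshape(nc, nt, n).transpose(1, 2, 0)
        dcf = voronoi_dcf(traj.coords)
        w = np.tile(dcf.ravel(), nc)
        # equal-iteration dense CG comparison
        si15 = low_rank_inversion(kdata, traj, dcf, coils, basis, max_iter=15)
        ref15 = _dense_cg(a, w, k_stacked, 15)
        assert np.linalg.norm(si15.coeffs.ravel() - ref15) / np.linalg.norm(ref15) < 1e-3
        # converged comparison against dense weighted least squares
        si = low_rank_inversion(kdata, traj, dcf, coils, basis, max_iter=500, tol=0.0)
        ref = np.linalg.lstsq(np.sqrt(w)[:, None] * a, np.sqrt(w) * k_stacked, rcond=None)[0]
        assert np.linalg.norm(si.coeffs.ravel() - ref) / np.linalg.norm(ref) < 1e-3

    def test_forward_adjoint_pair(self, rng):
        """Adjoint identity of the subspace-encoding operator (unit weights)."""
        from mrfmoco.nufft import NUFFT2D

        n, nt, rank, nc = 8, 12, 2, 2
        traj = golden_radial(nt, n, n)
        coils = simulate_coil_maps(nc, n)
        basis = np.linalg.qr(
            rng.standard_normal((nt, rank)) + 1j * rng.standard_normal((nt, rank))
        )[0]
        a = dense_lowrank_matrix(traj.coords, coils.maps, basis)
        x = rng.standard_normal(rank * n * n) + 1j * rng.standard_normal(rank * n * n)
        y = rng.standard_normal(a.shape[0]) + 1j * rng.standard_normal(a.shape[0])
        lhs = np.vdot(y, a @ x)
        rhs = np.vdot(a.conj().T @ y, x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_rank_mismatch_rejected(self, rng):
        n, nt = 8, 12
        traj = golden_radial(nt, n, n)
        coils = simulate_coil_maps(1, n)
        kdata = np.zeros((nt, n, 1), complex)
        basis = np.ones((nt + 1, 2))
        with pytest.raises(ValueError):
            low_rank_inversion(kdata, traj, np.ones((nt, n)), coils, basis)

    def test_timeseries_expansion(self, rng):
        basis = np.linalg.qr(rng.standard_normal((10, 3)))[0]
        coeffs = rng.standard_normal((3, 4, 4)) + 0j
        si = SingularImages(coeffs=coeffs, basis=basis)
        ts = si.to_timeseries()
        assert ts.shape == (10, 4, 4)
        assert np.allclose(ts[2], np.tensordot(basis[2], coeffs, axes=(0, 0)))
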