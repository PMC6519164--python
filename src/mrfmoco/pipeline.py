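"""End-to-end pipelines: simulate, estimate, correct, reconstruct, match.

These functions wire the library modules into the motion-corrected
fingerprinting workflow:

1. sliding-window CG-SENSE of the raw spokes,
2. multi-reference NMI rigid registration of the window images,
3. k-space correction of the estimated motion,
4. low-rank reconstruction in the dictionary's SVD subspace and matching.

Each step is deterministic given the configuration and seed; the ``cmd_*``
wrappers add file I/O around the pure functions for the CLI.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coils import simulate_coil_maps
from .config import PipelineConfig
from .dictionary import (
    CompressedDictionary,
    Dictionary,
    build_dictionary,
    compress_dictionary,
    parse_grid,
    save_dictionary,
)
from .io import save_maps_nifti, save_motion_csv, save_raw
from .matching import ParametricMaps, ibmc_pipeline, match
from .moco import correct_kspace
from .motion import (
    RigidMotionTrajectory,
    motion_abrupt,
    motion_identity,
    motion_sinusoidal,
)
from .phantom import TissueMaps, brain_phantom, vial_phantom
from .recon import SlidingWindowSeries, low_rank_inversion, sliding_window_series
from .registration import estimate_motion_multireference
from .sequence import (
    SequenceParams,
    SliceProfile,
    default_flip_angles,
    load_flip_angles_csv,
    sinc_slice_profile,
)
from .simulate import KSpaceData, simulate_mrf_kspace, tissue_dictionary
from .trajectory import golden_radial, voronoi_dcf

__all__ = [
    "build_sequence",
    "build_phantom",
    "build_motion",
    "simulate_acquisition",
    "estimate_motion",
    "recon_and_match",
    "run_mcmrf",
    "run_nmc",
    "run_ibmc",
    "report_errors",
    "cmd_simulate",
    "cmd_dict",
    "cmd_recon_nmc",
    "cmd_mcmrf",
    "cmd_ibmc",
    "cmd_report",
]

logger = logging.getLogger(__name__)


def build_sequence(cfg: PipelineConfig) -> tuple[SequenceParams, SliceProfile]:
    fa = (
        load_flip_angles_csv(cfg.fa_csv)
        if cfg.fa_csv
        else default_flip_angles(cfg.n_timepoints)
    )
    seq = SequenceParams(
        flip_angles=fa, tr_ms=cfg.tr_ms, te_ms=cfg.te_ms, invert=cfg.invert
    )
    return seq, sinc_slice_profile(cfg.slice_profile_points)


def build_phantom(cfg: PipelineConfig) -> TissueMaps:
    if cfg.phantom == "brain":
        return brain_phantom(cfg.matrix, cfg.fov_mm)
    if cfg.phantom == "vials":
        t1 = parse_grid(cfg.t1_grid)
        t2 = parse_grid(cfg.t2_grid)
        t1 = t1[t1 > 0]
        t2 = t2[t2 > 0]
        idx1 = np.linspace(0, t1.size - 1, 9).astype(int)
        idx2 = np.linspace(0, t2.size - 1, 9).astype(int)
        return vial_phantom(cfg.matrix, cfg.fov_mm, t1[idx1], t2[idx2])
    raise ValueError(f"unknown phantom kind {cfg.phantom!r}")


def build_motion(cfg: PipelineConfig) -> RigidMotionTrajectory:
    if cfg.motion_kind == "none":
        return motion_identity(cfg.n_timepoints)
    if cfg.motion_kind == "abrupt":
        return motion_abrupt(
            cfg.n_timepoints,
            cfg.motion_event_timepoint,
            cfg.motion_tx_px,
            cfg.motion_ty_px,
            cfg.motion_theta_deg,
            cfg.pixel_mm,
        )
    if cfg.motion_kind == "sinusoidal":
        return motion_sinusoidal(
            cfg.n_timepoints,
            cfg.motion_tx_px,
            cfg.motion_ty_px,
            cfg.motion_theta_deg,
            cfg.motion_cycles,
            cfg.pixel_mm,
        )
    raise ValueError(f"unknown motion kind {cfg.motion_kind!r}")


@dataclass
class SimulatedAcquisition:
    """Bundle of everything the simulator produced."""

    kdata: KSpaceData
    truth_maps: TissueMaps
    motion_truth: RigidMotionTrajectory
    seq: SequenceParams
    profile: SliceProfile
    tissue_dict: Dictionary


def simulate_acquisition(cfg: PipelineConfig) -> SimulatedAcquisition:
    """Simulate the configured phantom acquisition (deterministic given seed)."""
    t0 = time.time()
    seq, profile = build_sequence(cfg)
    maps = build_phantom(cfg)
    tdict = tissue_dictionary(maps, seq, profile)
    traj = golden_radial(cfg.n_timepoints, cfg.samples_per_spoke, cfg.matrix)
    coils = simulate_coil_maps(cfg.n_coils, cfg.matrix, cfg.fov_mm)
    motion = build_motion(cfg)
    kdata = simulate_mrf_kspace(
        maps, seq, tdict, traj, coils, motion, cfg.noise_sd, cfg.seed
    )
    logger.info("simulation: Nt=%d matrix=%d in %.1fs", cfg.n_timepoints, cfg.matrix, time.time() - t0)
    return SimulatedAcquisition(kdata, maps, motion, seq, profile, tdict)


def build_matching_dictionary(cfg: PipelineConfig) -> CompressedDictionary:
    seq, profile = build_sequence(cfg)
    d = build_dictionary(parse_grid(cfg.t1_grid), parse_grid(cfg.t2_grid), seq, profile)
    return compress_dictionary(d, cfg.rank)


def estimate_motion(
    cfg: PipelineConfig, kdata: KSpaceData, gauge: str = "zero-mean"
) -> tuple[SlidingWindowSeries, RigidMotionTrajectory]:
    """Sliding-window reconstruction followed by multi-reference registration."""
    t0 = time.time()
    series = sliding_window_series(
        kdata.samples, kdata.traj, kdata.coils, cfg.window, cfg.stride, cfg.cg_iters
    )
    logger.info("sliding windows: %d in %.1fs", series.n_windows, time.time() - t0)
    t0 = time.time()
    est = estimate_motion_multireference(
        series,
        n_timepoints=kdata.n_timepoints,
        pixel_mm=cfg.pixel_mm,
        reference_stride=cfg.reference_stride,
        bins=cfg.bins,
        gauge=gauge,
    )
    logger.info("registration in %.1fs", time.time() - t0)
    return series, est


def recon_and_match(
    cfg: PipelineConfig, kdata: KSpaceData, cdict: CompressedDictionary
) -> ParametricMaps:
    """Low-rank reconstruction + compressed-domain matching of one dataset."""
    dcf = voronoi_dcf(kdata.traj.coords)
    singular = low_rank_inversion(
        kdata.samples, kdata.traj, dcf, kdata.coils, cdict.basis, cfg.cg_iters
    )
    return match(singular, cdict)


def run_nmc(cfg, kdata, cdict) -> ParametricMaps:
    """No-motion-correction reference reconstruction."""
    return recon_and_match(cfg, kdata, cdict)


def run_mcmrf(
    cfg: PipelineConfig, kdata: KSpaceData, cdict: CompressedDictionary
) -> tuple[ParametricMaps, RigidMotionTrajectory, SlidingWindowSeries]:
    """The full motion-corrected pipeline (estimate → correct → reconstruct).

    The correction consumes the rigid-consistent anchored estimate; the
    returned trajectory is its conventional zero-mean representation (the
    two differ by a constant parameter shift).
    """
    series, anchored = estimate_motion(cfg, kdata, gauge="anchor")
    corrected = correct_kspace(kdata, anchored, cfg.pixel_mm)
    maps = recon_and_match(cfg, corrected, cdict)
    arr = anchored.as_array()
    arr = arr - arr.mean(axis=0, keepdims=True)
    est = RigidMotionTrajectory(tx_mm=arr[:, 0], ty_mm=arr[:, 1], theta_deg=arr[:, 2])
    return maps, est, series

def run_ibmc(
    cfg: PipelineConfig,
    series: SlidingWindowSeries,
    cdict: CompressedDictionary,
) -> ParametricMaps:
    """Image-based motion-correction baseline on an existing window series."""
    return ibmc_pipeline(series, cdict.parent, pixel_mm=cfg.pixel_mm, bins=cfg.bins)


def estimate_frame_pose(
    motion_truth: RigidMotionTrajectory, motion_est: RigidMotionTrajectory
) -> tuple[float, float, float]:
    """Pose of the corrected reconstruction's frame relative to the truth.

    A motion estimate determines poses only up to one constant rigid
    transform G (the gauge): ``m̂_n ≈ m_n ∘ G``.  Correcting with ``m̂``
    reconstructs the object at pose G⁻¹.  G is identified by averaging
    ``m_n⁻¹ ∘ m̂_n`` over the scan — a Procrustes-style alignment that uses
    the estimate only through this single unobservable constant.
    """
    from .registration import _rigid_compose_params, _rigid_inverse_params

    truth = motion_truth.as_array()
    est = motion_est.as_array()
    g = _rigid_compose_params(_rigid_inverse_params(truth), est)
    g_mean = g.mean(axis=0)
    pose = _rigid_inverse_params(g_mean)
    return (float(pose[0]), float(pose[1]), float(pose[2]))


def report_errors(
    maps: ParametricMaps,
    truth: TissueMaps,
    motion_est: RigidMotionTrajectory | None = None,
    motion_truth: RigidMotionTrajectory | None = None,
    frame_pose: tuple[float, float, float] | None = None,
    boundary_exclude_px: int = 0,
) -> dict:
    """Masked error metrics of matched maps (and optionally of the motion).

    ``frame_pose`` is the rigid pose (tx_mm, ty_mm, theta_deg) of the
    reconstruction frame relative to the ground-truth frame.  A motion
    estimate has no absolute pose (registration fixes only relative motion),
    so a corrected reconstruction lives in the zero-mean pose of the scan;
    pixel-wise comparison against the static truth must first move the truth
    maps into that frame.  In simulations the pose is known exactly (the mean
    of the true trajectory) — it is derived from ground truth only, never
    from the estimate.  Truth maps are warped with nearest-neighbour
    interpolation to keep tissue values on their grid.

    ``boundary_exclude_px`` restricts the comparison to homogeneous-tissue
    interiors (each constant-(T1,T2) region eroded by that many pixels),
    the ROI-style evaluation customary for parametric maps; it removes
    partial-volume and sub-pixel-alignment pixels for every method alike.
    """
    from .motion import apply_rigid

    t1_ref, t2_ref, mask = truth.t1_ms, truth.t2_ms, truth.mask
    if frame_pose is not None and any(frame_pose):
        tx, ty, th = frame_pose
        u = 4  # warp on an upsampled grid: NN at quarter-pixel precision
        # the fine grid's rotation center sits half a coarse pixel off the
        # coarse pixel-center lattice; fold the difference into the shift
        ang = np.deg2rad(th)
        dc = u // 2 * (truth.pixel_mm / u)
        tx_f = tx + dc * (1 - np.cos(ang)) + dc * np.sin(ang)
        ty_f = ty - dc * np.sin(ang) + dc * (1 - np.cos(ang))

        def warp(a):
            fine = np.kron(a.astype(float), np.ones((u, u)))
            fine = apply_rigid(fine, tx_f, ty_f, th, pixel_mm=truth.pixel_mm / u, order=0)
            return fine[u // 2 :: u, u // 2 :: u]

        t1_ref = warp(t1_ref)
        t2_ref = warp(t2_ref)
        mask = warp(mask) > 0.5
    if boundary_exclude_px > 0:
        from scipy.ndimage import binary_erosion

        interior = np.zeros_like(mask)
        for t1v, t2v in np.unique(
            np.column_stack([t1_ref[mask], t2_ref[mask]]), axis=0
        ):
            region = mask & (t1_ref == t1v) & (t2_ref == t2v)
            interior |= binary_erosion(region, iterations=boundary_exclude_px)
        mask = interior
    m = mask
    out = {}
    for name, est, ref in (
        ("t1", maps.t1_ms, t1_ref),
        ("t2", maps.t2_ms, t2_ref),
    ):
        err = est[m] - ref[m]
        out[f"{name}_rmse_ms"] = float(np.sqrt(np.mean(err**2)))
        out[f"{name}_mae_ms"] = float(np.mean(np.abs(err)))
    if motion_est is not None and motion_truth is not None:
        truth_c = motion_truth.as_array() - motion_truth.as_array().mean(axis=0)
        diff = motion_est.as_array() - truth_c
        for j, name in enumerate(("tx_mm", "ty_mm", "theta_deg")):
            out[f"motion_{name}_rmse"] = float(np.sqrt(np.mean(diff[:, j] ** 2)))
    return out


# ---------------------------------------------------------------------------
# CLI command bodies: pure functions above + file I/O


def _outdir(cfg) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def cmd_simulate(cfg: PipelineConfig) -> Path:
    import nibabel as nib

    sim = simulate_acquisition(cfg)
    out = _outdir(cfg)
    raw = out / "raw.h5"
    save_raw(raw, sim.kdata, sim.seq, motion_truth=sim.motion_truth)
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = cfg.pixel_mm
    for name, arr in (
        ("truth_t1_ms", sim.truth_maps.t1_ms),
        ("truth_t2_ms", sim.truth_maps.t2_ms),
        ("truth_m0", np.abs(sim.truth_maps.m0)),
    ):
        nib.save(nib.Nifti1Image(arr.astype(np.float64), aff), out / f"{name}.nii.gz")
    logger.info("wrote %s", raw)
    return raw


def cmd_dict(cfg: PipelineConfig) -> Path:
    cdict = build_matching_dictionary(cfg)
    out = _outdir(cfg) / "dictionary.h5"
    save_dictionary(out, cdict)
    logger.info(
        "dictionary: %d atoms, rank %d captures %.4f of energy",
        cdict.parent.n_atoms,
        cdict.rank,
        cdict.energy_fraction,
    )
    return out


def _load_inputs(cfg):
    from .dictionary import load_dictionary
    from .io import load_raw

    out = _outdir(cfg)
    raw = out / "raw.h5"
    dic = out / "dictionary.h5"
    if not raw.exists():
        raise FileNotFoundError(f"{raw} missing — run `mrfmoco simulate` first")
    if not dic.exists():
        raise FileNotFoundError(f"{dic} missing — run `mrfmoco dict` first")
    kdata, seq, truth, est = load_raw(raw)
    return kdata, seq, truth, load_dictionary(dic)


def cmd_recon_nmc(cfg: PipelineConfig) -> ParametricMaps:
    kdata, _, _, cdict = _load_inputs(cfg)
    maps = run_nmc(cfg, kdata, cdict)
    save_maps_nifti(_outdir(cfg), maps, cfg.pixel_mm, prefix="nmc_")
    return maps


def cmd_mcmrf(cfg: PipelineConfig) -> ParametricMaps:
    kdata, seq, truth, cdict = _load_inputs(cfg)
    maps, est, _ = run_mcmrf(cfg, kdata, cdict)
    out = _outdir(cfg)
    save_maps_nifti(out, maps, cfg.pixel_mm, prefix="mcmrf_")
    save_motion_csv(out / "motion_estimate.csv", est)
    return maps


def cmd_ibmc(cfg: PipelineConfig) -> ParametricMaps:
    kdata, _, _, cdict = _load_inputs(cfg)
    series = sliding_window_series(
        kdata.samples, kdata.traj, kdata.coils, cfg.window, cfg.stride, cfg.cg_iters
    )
    maps = run_ibmc(cfg, series, cdict)
    save_maps_nifti(_outdir(cfg), maps, cfg.pixel_mm, prefix="ibmc_")
    return maps


def cmd_report(cfg: PipelineConfig) -> dict:
    import json

    import nibabel as nib

    out = _outdir(cfg)
    truth = build_phantom(cfg)
    report = {}
    for prefix in ("nmc", "mcmrf", "ibmc"):
        t1p = out / f"{prefix}_t1_ms.nii.gz"
        if not t1p.exists():
            continue
        maps = ParametricMaps(
            t1_ms=np.asanyarray(nib.load(t1p).dataobj),
            t2_ms=np.asanyarray(nib.load(out / f"{prefix}_t2_ms.nii.gz").dataobj),
            m0_magnitude=np.asanyarray(nib.load(out / f"{prefix}_m0.nii.gz").dataobj),
            match_correlation=np.asanyarray(
                nib.load(out / f"{prefix}_correlation.nii.gz").dataobj
            ),
        )
        report[prefix] = report_errors(maps, truth)
    est_csv = out / "motion_estimate.csv"
    if est_csv.exists():
        from .io import load_motion_csv

        est = load_motion_csv(est_csv)
        truth_m = build_motion(cfg)
        centered = truth_m.as_array() - truth_m.as_array().mean(axis=0)
        diff = est.as_array() - centered
        report["motion_rmse"] = {
            name: float(np.sqrt(np.mean(diff[:, j] ** 2)))
            for j, name in enumerate(("tx_mm", "ty_mm", "theta_deg"))
        }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
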