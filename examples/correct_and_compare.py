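"""Motion-corrupt a scan, correct it in k-space, and compare T1/T2 errors.

Runs the three-way comparison on one simulated sinusoidal-motion scan:
no correction (NMC), the image-based baseline (IBMC), and k-space motion
correction (MC-MRF), reporting masked T1/T2 RMSE against the ground truth.
Takes a couple of minutes at this desk scale.
"""

import numpy as np

from mrfmoco import PipelineConfig, correct_kspace
from mrfmoco.matching import ibmc_pipeline
from mrfmoco.pipeline import (
    build_matching_dictionary,
    estimate_frame_pose,
    estimate_motion,
    recon_and_match,
    report_errors,
    run_nmc,
    simulate_acquisition,
)

cfg = PipelineConfig.preset(
    "desk",
    matrix=64,
    n_timepoints=500,
    stride=10,
    n_coils=4,
    slice_profile_points=5,
    rank=6,
    reference_stride=10,
    motion_kind="sinusoidal",
    motion_tx_px=8.0,
    motion_ty_px=2.0,
    motion_theta_deg=24.0,
    motion_cycles=1.0,
)

cdict = build_matching_dictionary(cfg)
sim = simulate_acquisition(cfg)
truth_pose = sim.motion_truth.as_array()
w0 = tuple(truth_pose[: cfg.window].mean(axis=0))

nmc = run_nmc(cfg, sim.kdata, cdict)
series, anchored = estimate_motion(cfg, sim.kdata, gauge="anchor")
mc = recon_and_match(cfg, correct_kspace(sim.kdata, anchored, cfg.pixel_mm), cdict)
ib = ibmc_pipeline(series, cdict.parent, pixel_mm=cfg.pixel_mm)

rep_n = report_errors(nmc, sim.truth_maps)
rep_i = report_errors(ib, sim.truth_maps, frame_pose=w0)
rep_m = report_errors(
    mc, sim.truth_maps, frame_pose=estimate_frame_pose(sim.motion_truth, anchored)
)
print(f"{'method':8s} {'T1 RMSE [ms]':>12s} {'T2 RMSE [ms]':>12s}")
for name, rep in (("NMC", rep_n), ("IBMC", rep_i), ("MC-MRF", rep_m)):
    print(f"{name:8s} {rep['t1_rmse_ms']:12.1f} {rep['t2_rmse_ms']:12.1f}")
# Uncorrected maps carry heavy ghosting; the image-based baseline removes
# most of it; correcting the k-space itself recovers the sharpest maps.
# Each method is scored in its own reconstruction frame (see docs/methods.md).
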