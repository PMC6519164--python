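# mrfmoco

Rigid-motion-corrected MR fingerprinting (MRF) for 2D golden-angle radial
acquisitions, with a digital-phantom simulator.

MRF estimates quantitative tissue maps (T1, T2, M0) by matching each pixel's
transient signal evolution — its *fingerprint* — against a dictionary of
simulated evolutions.  Because one scan spreads signal encoding over
thousands of undersampled readouts, subject motion corrupts every time point
at once and ghosts all of the maps.  This package implements retrospective
k-space motion correction for that setting:

1. **Sliding-window reconstruction** — intermediate images
   `Î_t = argmin_I ‖S F C I − K_t‖²` by CG-SENSE over a 50-spoke window
   around each time point;
2. **Motion estimation** — rigid registration of the window images with
   normalized mutual information (robust to the varying MRF contrast),
   repeated against multiple reference windows, chained into a common frame
   and averaged;
3. **k-space correction** — per TR the spoke coordinates are rotated by
   −θ_n and a translation phase ramp `exp(+2πi k·t_n)` is removed
   (`K_n(k) = exp(−2πi k·t_n)·K_ref(R(−θ_n)k)` for rigid motion);
4. **Low-rank reconstruction and matching** — the corrected data is
   reconstructed directly in the rank-R SVD subspace `U_R` of the
   dictionary, `Î = argmin_I ‖S U_R F C I − K′‖²`, and the singular images
   are matched by normalized inner product to give T1/T2/M0 maps.

An image-based correction baseline (IBMC: align the window images, then
match) and an uncorrected route (NMC) are included for comparison, as is a
forward simulator (EPG fingerprints, brain-like and vial phantoms, rigid
motion trajectories, multi-coil radial sampling) so every experiment runs
without scanner data.  The intended users are MR physicists prototyping
motion-robust quantitative imaging and anyone needing a self-contained,
testable radial-MRF sandbox.

## Worked example

`examples/estimate_step_motion.py` simulates a brain-like phantom whose pose
jumps by (8 px, 2 px, 12°) at time point 150 of 500, reconstructs the
sliding-window series and estimates the motion:

```
windows reconstructed : 46
recovered step tx     : 7.93 px (true 8)
recovered step ty     : 2.00 px (true 2)
recovered step theta  : 11.68 deg (true 12)
```

The estimate is centered (only pose *changes* are observable), so the
plateau difference across the jump is the meaningful readout; it recovers
the programmed amplitudes to a fraction of a pixel/degree.

`examples/dictionary_and_matching.py` shows the dictionary workflow:

```
atoms                 : 608
rank-8 energy fraction: 0.999990
probe (T1, T2)        : (850.0, 101.0) ms
matched (T1, T2)      : (880, 110) ms
match correlation     : 0.9996
```

An off-grid probe fingerprint matches to the nearest dictionary node with
near-unit correlation.  `examples/correct_and_compare.py` runs the
NMC / IBMC / MC-MRF comparison on a sinusoidal-motion scan:

```
method   T1 RMSE [ms] T2 RMSE [ms]
NMC            1115.5        636.2
IBMC            463.2        369.1
MC-MRF          382.2        253.3
```

Uncorrected maps carry heavy ghosting, the image-based baseline removes
most of it, and correcting the k-space itself recovers the most accurate
maps.

## Command line

The same pipelines are scriptable via a thin CLI:

```bash
mrfmoco simulate  --preset desk          # raw HDF5 container + truth NIfTI
mrfmoco dict      --preset desk          # dictionary + rank-R basis
mrfmoco recon-nmc --preset desk          # uncorrected maps
mrfmoco mcmrf     --preset desk          # motion-corrected maps + motion CSV
mrfmoco ibmc      --preset desk          # image-based baseline maps
mrfmoco report    --preset desk          # error metrics vs ground truth
```

All protocol numbers (matrix 160 at 320 mm FOV, TR/TE 4.3/1.23 ms, 1750
time points, window 50, 15 CG iterations, rank 10, references every 100
windows) are YAML-overridable defaults; `--preset desk` selects a small fast
configuration.  The raw container layout is `/kdata` (Nt × Ns × Nc complex),
`/traj`, `/angles`, `/dcf`, `/coilmaps`, `/motion_truth`, `/motion_estimate`
and a `/seq` group.

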