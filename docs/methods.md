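# Methods

`mrfmoco` implements retrospective rigid-motion correction for 2D
golden-angle radial MR fingerprinting (MRF), together with a digital-phantom
simulator that reproduces the motion experiments without scanner data.  This
note records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Signal model and dictionary

Fingerprints are simulated with the extended phase graph (EPG) formalism for
an inversion-prepared, gradient-spoiled (FISP-type) sequence with constant
TR/TE and a variable flip-angle train.  Per TR: instantaneous RF rotation at
constant RF phase, echo readout `signal = F0 · exp(-TE/T2)`, T1/T2 relaxation
over the TR, and a unit spoiler shift of the configuration ladder.  The
inversion is modelled as an ideal 180° pulse, unscaled by the slice profile,
with no gap before the first TR.  Configuration orders are truncated at
`min(Nt, 100)`; RF phase is constant (no spoiling phase cycle is assumed —
the full EPG shift handles the unbalanced gradient).  The implementation is
validated against a brute-force isochromat ensemble (401 spins uniformly
dephased over 2π per TR) to ~1e-15 relative.

Defaults follow the modelled protocol: TR/TE = 4.3/1.23 ms, 1750 time
points, flip angles 0–70°.  The published protocol shows its flip-angle
train only graphically, so the generator produces the same class of
waveform: 10 sinusoidal half-lobes with peaks ramping 30°→70° and a small
fixed-seed jitter (σ = 1°); any schedule can be substituted from a
two-column CSV.

Slice-profile correction averages the EPG signal over 50 positions across
the slice, scaled by the magnitude small-tip profile of a Hamming-windowed
sinc pulse (time-bandwidth 4).  Both the count and the shape are
configurable; a rectangular profile reduces exactly to the uncorrected
signal.

Dictionaries are built over colon-range (start:step:stop) T1/T2 grids.
Zero relaxation times present in the printed grids are dropped (non-physical,
and their atoms could not be normalized); T2 ≥ T1 pairs are kept by default,
mirroring the grids, with a switch to prune them.  The rank-R temporal
subspace `U_R` is the truncated left singular basis of the atom matrix
(default R = 10; at desk scale R = 6 captures >99.99% of dictionary energy).

## Encoding

One golden-angle spoke (Φ = 180°/φ ≈ 111.246°) is acquired per TR, with
samples spaced 1/matrix apart in normalized k-space (cycles/pixel, |k| ≤
0.5).  Density compensation is the Voronoi cell area of each sample, cells
clipped to the sampled disk, coincident samples (the shared DC point)
splitting their cell equally, and weights normalized to the disk area; a
single collinear spoke falls back to ramp |k| weights.  For uncorrected
golden-angle sliding windows every window's spoke set is a global rotation
of the first window's, so the Voronoi weights are reused after an exact
relative-angle check — rotated (corrected) trajectories fail the check and
are recomputed.

The NUFFT is Kaiser-Bessel gridding: 2× oversampled FFT, kernel width 6
(Beatty β), analytic roll-off correction, with spreading/interpolation as a
precomputed sparse matrix per coordinate set.  Accuracy against the direct
DFT is ~8e-6 relative at width 6 (~8e-8 at width 8, used by a few oracle
tests to keep discretization error out of the quantity under test); the
forward/adjoint pair is exact to round-off by construction.

Coil sensitivities are analytic: broad complex Gaussian lobes on a ring of
virtual elements with smooth phase, deterministic in (Nc, matrix).  Real
acquisitions would estimate maps from data; map estimation is out of scope
and maps are an input everywhere.

## Reconstruction

Both solvers minimize the density-weighted least squares
`‖√W (S F C x − k)‖²` by CG on the normal equations, zero-initialized, with
a fixed budget of 15 iterations (early stopping is the only regularization;
the relative-residual exit of 1e-6 rarely triggers first).  The DCF enters
as the weighting W — the standard pairing of Voronoi weights with CG, which
makes 15 iterations sufficient in practice.  Fixed-count CG from zero is
deterministic but not exactly linear in the data; linearity holds at
convergence and is tested there.

The sliding-window series reconstructs every block of `window` (default 50)
consecutive spokes by CG-SENSE, assigning each image to its center time
point; stride is configurable (10 in the motion experiments) and motion at
skipped time points is interpolated from window centers.

The low-rank ("subspace") reconstruction solves for R coefficient images:
the forward operator mixes them with row n of `U_R`, coil-weights, and
samples spoke n.  It is implemented with one oversampled FFT per
(coefficient, coil) pair per application and a single global sparse
interpolation, so cost scales with R·Nc FFTs, not with Nt.

## Motion estimation

Window magnitudes are registered with normalized mutual information
(32 bins, joint histogram over the overlap only), which tolerates the
contrast changes across the scan.  Registration is two-stage: a coarse
exhaustive rotation sweep (±30°, 2° steps, on ≤64² block-averaged images)
with an FFT cross-correlation translation search per candidate angle, scored
by NMI — the same search space as a full exhaustive grid at a fraction of
the cost — followed by NMI pattern search at full resolution (steps halving
from 2 px/1° to 0.05).  Every metric evaluation composes a constant
half-pixel shift into *both* images so both are bilinearly interpolated
equally; without this the un-interpolated identity pose sits in a spurious
local NMI minimum (the classic interpolation artifact, worth ~1.2° of
rotation bias on static window images here).

Windows whose mean magnitude falls below half the median window level —
inversion-null windows dominated by aliasing whose structure rotates with
the spoke set — are excluded from registration, and their poses are
interpolated from neighbouring windows (the same interpolation that covers
skipped windows at stride > 1).  The gate looks only at the data's signal
level, never at a registration outcome.

The multi-reference estimate registers every window to references placed
every `reference_stride` windows.  Each reference's pose trace is chained
into the first reference's frame by exact rigid composition — subtracting a
parameter mean is not a rigid change of frame once rotations vary, and the
naive centered average leaves the corrected k-space inconsistent by over a
pixel at the simulated amplitudes.  References are averaged with
deterministic quality weights (median over windows of final NMI − 1), which
suppresses references that fall on inversion-null or extreme-contrast
windows; a 3-point median across windows removes the outlier poses of
windows that straddle an abrupt motion (double-exposed images), moving a
step edge by at most one window.  The trace is interpolated linearly from
window centers to all TRs.

The absolute pose is unobservable (a constant rigid gauge).  Two output
gauges are provided: `"zero-mean"` subtracts each parameter's mean — the
conventional centered representation, difference-preserving — and
`"anchor"` leaves the trace in the first window's pose, which is an exactly
rigid-consistent trajectory.  The k-space correction consumes the anchored
form; reports and CSV output use the centered form.

## k-space correction

A rigid object motion (θ_n, t_n) at TR n relates the acquired spoke to the
reference object by `K_n(k) = exp(-2πi k·t_n) · K_ref(R(-θ_n) k)`.  The
correction rotates the spoke coordinates by −θ_n and multiplies by
`exp(+2πi k·t_n)`; sample magnitudes are untouched (rotations have unit
Jacobian).  The signs are fixed by the requirement that the correction
exactly invert the simulator's image-domain transform, verified by the
shift-theorem round trip (integer-pixel translations agree with the
motion-free simulation to ~1e-6).  Rotation correction disturbs the
golden-angle spacing and can open angular gaps; a coverage report
(histogram + maximum gap) is provided for QC, and density compensation is
always recomputed on corrected coordinates.

Coil maps do not move with the object, so corrected data corresponds to
slightly inconsistent sensitivities — inherent to retrospective rigid
correction and accepted here as in practice.

## Matching and the IBMC baseline

Matching maximizes |⟨atom, signal⟩| over unit-normalized atoms, in the
R-dimensional compressed domain for singular images (equivalent to
time-domain matching since `U_R` has orthonormal columns), by brute-force
argmax with lowest-index tie-breaking.  M0 is the modulus of the
unnormalized inner product divided by the squared atom norm; matching is
invariant to global complex scaling of the signal.

The image-based motion correction (IBMC) baseline registers every window
image to the first window, resamples it to that pose, assigns it to its
center time point and matches the aligned series against the dictionary
rows at those time points.  "Summing" of aligned images is interpreted as
this per-center assignment.  Matching against boxcar-window-averaged atoms
(compensating the windowed contrast) is available as an optional
enhancement but is off by default, since the enhanced variant is no longer
the plain baseline.

## Simulator

The brain-like phantom is an ellipse composition with literature values
(WM 738/48 ms, GM 1127/69 ms, CSF 4000/2000 ms; M0 0.77/0.86/1.0) plus four
shrinking inclusions for resolution assessment; the vial phantom places
homogeneous disks with chosen (T1, T2).  Per TR the contrast image is an
exact per-tissue dictionary lookup; the rigid motion state (piecewise
constant per TR — one spoke per time point) is applied in the image domain
with bilinear interpolation, then coil weighting and NUFFT sampling of that
TR's spoke; complex Gaussian noise is seeded.  Printed pixel amplitudes are
interpreted as pixels of the simulation grid.  Sinusoidal amplitudes are
peak values, with 3 cycles per full-length scan by default (the source
protocol does not print the frequency).

By default the simulator and the matcher share the same EPG model; a finer
slice-profile discretization (or spline interpolation order) can be set on
the simulator side to create inverse-crime-free tests.  What the synthetic
tests cannot show: B0/B1 effects, through-plane motion (a slice-content
replacement diagnostic only; its correction is out of scope), coil-map
estimation errors, physiological noise, and gradient imperfections.

## Study-condition scaling

The full-scale motion experiments run the printed protocol at matrix 128
(320 mm FOV, hence 2.5 mm pixels), Nt = 1750, window 50, stride 10,
4 coils, noiseless, with references every 100 windows; the recovered step
amplitudes are reported in grid pixels.  The error-ordering comparison
(no correction ≥ image-based ≥ k-space-corrected, masked T1/T2 RMSE) keeps
the protocol's full temporal design — Nt = 1750, abrupt events at time
points 250 and 1500, three sinusoid cycles, rank 10 — and scales down only
the matrix (64).  Shorter scans distort the comparison: at Nt = 500 the
50-TR window spans 20% of the scan around an abrupt event (vs 5.7% at full
length) and transition-window mis-correction dominates both corrections.

The thinnest margins sit on the continuous-rotation simulation: corrected
k-space is coil-inconsistent under large rotations (receive profiles do not
rotate with the object — inherent to retrospective k-space correction, and
more visible with 4 analytic coils than with a 12-channel array), and
pixelwise RMSE barely penalizes the image-based baseline's hallmark defect,
spatial blur.  The complementary spectral comparison (high-spatial-
frequency energy of the T1 maps above 0.25 Nyquist) shows the k-space
corrected maps retain more detail on the same run.

Each method is evaluated in its own reconstruction frame: the uncorrected
reconstruction in the truth frame; IBMC at the first window's true pose
(its registration target); the k-space-corrected reconstruction, anchored
to the first window, at its exact constant gauge, identified by averaging
`m_n⁻¹ ∘ m̂_n` over the scan (a Procrustes-style alignment that uses the
estimate only through the single unobservable constant).  Ground-truth maps
are warped into the evaluation frame by nearest-neighbour interpolation so
tissue values stay on their grid.

## Known limitations

- Through-plane motion is neither corrected nor claimed; B0/B1 are not
  modelled.
- The rigid estimate has ~200 ms temporal resolution (the window); abrupt
  motion within a window is unrecoverable and the affected spokes remain
  mis-corrected.
- The plateau-difference readout of translation steps in the centered
  parameter convention carries a small rotation-induced offset (≤1 px at
  the simulated amplitudes) that is a property of the representation, not
  of the estimator; the anchored gauge is exact.
- Fixed-count CG is only approximately linear; quantitative maps inherit
  the usual undersampling bias of early-stopped reconstructions.
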