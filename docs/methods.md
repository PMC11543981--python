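# Methods

## Model and procedure

Each segmented tissue compartment of a 4D DCE series — tumor-suspicious
lesion (TSL), perilesional tissue (PLT) and normal-appearing tissue
(NAT) — is reduced to one time–intensity curve by arithmetic voxel
averaging per frame (NaN voxels excluded with a logged count; an all-NaN
frame is an error). Curves are then normalized by the mean of the first
`baseline_frames` values (default 2), making them dimensionless with
baseline ≈ 1. Normalization is required for the reference tissue's fitted
maximum to sit near 1.0 and for all tissue-pair ratios to be invariant to
global intensity scaling; the test suite asserts this invariance exactly.

The semi-quantitative features follow the two-line construction: an
ordinary least-squares *wash-in* line fit on frames `[onset, peak]` and a
*wash-out* line on `[peak, last]`, with the peak frame shared by both
windows and `onset` equal to the last baseline frame. The **fitted
maximum** is the intensity at the intersection of the two lines; the
**fMCR** for a tissue pair is the ratio of their fitted maxima. Wash-in
and wash-out ratios are plain ratios of the corresponding slopes with the
operands' signs propagating (a negative lesion wash-out over a positive
reference wash-out is negative). Curves are classified by the wash-out
slope against a tolerance ε (default 0.01 normalized units per time unit):
persistent above +ε, plateau within ±ε, washout below −ε.

**Peak location.** The peak is the maximum of the (optionally
moving-average-smoothed; window default 1 = off) curve, ties breaking to
the earliest frame. A persistently rising curve has its maximum on the
last frame, leaving no wash-out window; in that case the wash-in/wash-out
transition is located by two-segment least squares — the breakpoint
minimizing the summed squared residuals of the two line fits, ties to the
earliest frame. On noiseless piecewise-linear input the true knee has zero
residual, so recovery stays exact; this is the construction the line
intersection implies for type-1 curves, whose fitted maximum is the knee
value.

**Degenerate inputs** are bounded and flagged rather than extrapolated:
if the lines do not converge forward in time (wash-in slope ≤ wash-out
slope) the fitted maximum falls back to the observed curve maximum; a peak
on the last frame yields a flat wash-out line through the peak value; a
wash-in window with fewer than two points widens toward frame 0. All such
paths set `degenerate=True` in the output.

**DL-PIRADS calibration.** A voxelwise lesion-probability map is reduced
to the maximum voxel probability inside the evaluation region (whole map,
or a prostate mask when given) and thresholded at the packaged operating
points 0.033/0.074/0.186/0.646 for categories 2–5. Bounds are inclusive:
a prediction exactly on a cut-off receives that category, which is the
only reading consistent with a prediction of 0.05 mapping to category 2
under a 0.033 cut-off. Predictions below 0.033 map to a sentinel
category 1 ("below DL-PIRADS 2"), reported distinctly because the
calibration defines no category there. Threshold recalibration and network
inference are out of scope; maps arrive as inputs.

**Segmentation agreement.** DICE is computed volumetrically as
`2|A∩B|/(|A|+|B|)`; two empty masks are defined to give 0 with a warning
flag, avoiding the 0/0 division while still surfacing the pathology.
Manual T2w and ADC lesion masks are OR-combined before comparison with the
automatic mask (order-independent). Cohort mean DICE excludes patients
without an automatic segmentation. The fitted-maximum/fMCR consistency
check recomputes each cohort fMCR cell from the stored fitted maxima and
flags cells deviating by more than half a unit in the last printed decimal
(0.005 at two decimals); flagged deviations indicate the source carried
more precision internally than its two-decimal print, and are reported
with their magnitude rather than absorbed.

## Synthetic phantom

The phantom emulates the enhancement kinetics the features are built to
measure, not MR physics: a spherical lesion (radius 4 voxels) inside a
24×24×14 grid, a perilesional shell 2 voxels thick directly adjacent, and
normal tissue filling the rest. Each compartment's noiseless voxel
trajectory is flat baseline → linear wash-in ramp → linear wash-out ramp,
scaled by a raw baseline intensity (default 100), with optional i.i.d.
additive Gaussian noise. Because the downstream features are themselves
piecewise-linear fits, noiseless phantoms admit exact recovery, which the
suite asserts to 1e-9.

Defaults encode the three curve archetypes with the fitted-maximum
triplet typical of a clearly discriminable clinically significant lesion:
TSL type 3 (wash-in 0.40/frame from frame 1 to 9, wash-out −0.05, apex
4.2), PLT type 2 (wash-in 0.15, plateau, apex 2.2), NAT type 1 (wash-in
0.02 to frame 5, late slope 0.011, fitted maximum 1.08). The series has 30
frames at per-frame time units — the acquisition's true frame count and
temporal resolution are a convention here, so all slopes are reported per
frame. Noise for robustness runs is 5% of baseline (sd 5 raw units).
All randomness flows from a single integer seed per call
(`numpy.random.default_rng`); identical spec + seed is bit-identical.
A Gaussian noise model was chosen over Rician as the simplest sufficient
to exercise estimator robustness at the SNR of interest.

What the phantom does **not** model: anatomy, coil/B1 bias, motion,
k-space sampling, Rician magnitude bias at low SNR, arterial input
variability, or pharmacokinetic (Tofts-type) exchange. Passing phantom
tests therefore demonstrates correctness of the estimators on curves of
the assumed shape, not robustness to those real-data effects.

Mask-pair fixtures place two equal-size random voxel sets with an exact
shared count, so DICE has a closed form (`k/n`); probability-map fixtures
pin one lesion voxel at the requested level so the max-voxel prediction is
exact by construction.

## Problem sizes and numerical choices

Phantom-based checks use the 24×24×14×30 default grid (~8k voxels,
~250 lesion voxels); stochastic recovery uses 200 replicates at 5% noise,
asserting median relative slope error < 10% (observed ≈ 0.2% for the
lesion wash-in slope, since averaging ~250 voxels suppresses the curve
noise to ~0.003 normalized units). Oracle-equivalence checks use 100
random 8×8×8 mask pairs against literal voxel loops. Line fits use
`numpy.polyfit` (degree 1), integration `numpy.trapezoid`. Reported
values are rounded half-to-even to 2 decimals at report time only; full
precision is kept internally.

## Known limitations

- Curves are tissue-averaged; no voxelwise parametric maps.
- No registration or resampling: series and masks must share a voxel grid,
  enforced with an explicit error.
- The patient-level probability statistic is the voxel maximum; lesion-level
  pooling alternatives are not implemented.
- The wash-in/wash-out ratio conventions are plain slope ratios; other
  published conventions (e.g. normalizing wash-out by the wash-in scale)
  would change sub-unit values but not the sign structure.
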