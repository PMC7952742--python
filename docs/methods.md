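# Methods

`wt2map` estimates the transverse relaxation time of the water
compartment of muscle (wT2) from multi-echo spin-echo (MESE) magnitude
images. In fat-infiltrated muscle a naive exponential fit of the echo
train conflates three confounders: the long-T2 fat signal, transmit
(B1) inhomogeneity, and the flip-angle variation across the slice
profile. The package addresses all three by simulating the full
acquisition physics and matching each voxel against a dictionary of
simulated signals.

## Signal model

Each voxel is modeled as a two-compartment mixture,

    S_n = (1 - FF) * sat_w * W_n(wT2, B1) + FF * sat_f * F_n(B1),

where `W_n` and `F_n` are the n-th echo amplitudes of the water and fat
compartments, `FF` is the fat fraction, and `sat_c = 1 - exp(-TR/T1_c)`
accounts for incomplete longitudinal recovery between repetitions
(`apply_tr_saturation`, default on; at TR = 4100 ms the water factor is
≈ 0.95 vs ≈ 1.00 for fat, which slightly rescales the apparent FF —
disabling the flag assumes full recovery instead).

Compartment echo trains come from an extended phase graph (EPG)
simulation of the CPMG sequence: excitation about x, refocusing about
y, one unit of crusher dephasing per half echo spacing, configuration
orders up to K = 2·n_echoes + 1 (overflow-free by construction).
Relaxation constants are fixed at T1 water = 1400 ms, T1 fat = 365 ms,
fat T2 = 151 ms (single-peak fat model); the fat T2 can instead be
estimated from a pure-fat (subcutaneous) ROI via single-compartment
matching with T1 = 365 ms, aggregating per-voxel best matches with the
median for robustness to ROI contamination. The slice profile enters as
an unweighted average of EPG trains over positions across the slice,
with the local excitation and refocusing flips both scaled by the B1
factor. Signals are magnitudes in units of M0; non-CPMG phase trains,
diffusion, magnetization transfer and multi-peak fat spectra are not
modeled.

The EPG engine is validated two ways, with no shared code: a closed
form (exact 180° refocusing gives echo n = exp(-n·esp/T2) independently
of T1, matched to < 1e-9) and a brute-force isochromat Bloch simulation
(256 isochromats uniformly spanning 2π of crusher dephasing per half
interval; agreement to < 1e-6, in practice machine precision, across
flips 0.4π–1.4π). A consequence of real CPMG physics worth noting: with
sub-180° refocusing the individual echoes alternate below/above the
pure-T2 decay (even/odd oscillation) while the train as a whole decays
more slowly — so the validated property is the prolonged apparent
decay, not a per-echo inequality.

## Slice profiles

RF pulses are hanning-windowed sincs; the flip-angle profile across the
slice is computed with the forward Shinnar-LeRoux recursion
(hard-pulse approximation; flip = 2·arcsin|b|, clamped to [0, π]). The
pulse time-bandwidth product defaults to 2.0 (128 hard-pulse samples);
the vendor's true TBW/apodization is generally unknown, and small
profile changes can bias absolute wT2 by a few milliseconds, so both
the TBW and a fully custom tabulated profile are accepted as inputs.
With TBW = 2 the underlying sinc is truncated exactly at its first
zeros (the pulse edges). The refocusing slice is modeled 1.2× wider
than the excitation slice (`refocusing_width_factor`, a property of the
sequence implementation), by stretching its spatial axis. Profiles are
tabulated on 64 midpoint-sampled positions spanning ±1 excitation slice
thickness; midpoint sampling makes the unweighted spatial mean a
second-order quadrature (doubling the sampling changes voxel signals by
< 0.5%). In the small-tip limit the SLR profile converges to the scaled
magnitude Fourier transform of the waveform (checked to 2%).

## Dictionary and matching

The default grid is 60 linearly spaced wT2 values in [20, 80] ms × 101
fat fractions in [0, 1] × 20 B1 factors in [0.4, 1.4] — 121,200
entries. Because the mixture is linear in FF, only |wT2|·|B1| water
trains and |B1| fat trains are simulated; columns are L2-normalized and
stored FF-major (each FF value occupies one contiguous column range).
The dictionary is rebuilt at every run; construction is a few seconds
on one CPU, so there is no cache layer.

Matching maximizes the cosine similarity between the normalized voxel
signal and the dictionary columns, computed as a batched matrix product
C = S × D followed by a per-row argmax. No mean-centering is applied —
the metric is the normalized inner product exactly as the matrix
formulation implies. Ties break to the lowest entry index (FF-major,
then B1, then wT2), making results deterministic and batch-size
invariant (the parameter maps are bitwise identical across batch sizes;
the stored correlation scores agree to ~1e-15, the limit of BLAS
reordering). Matching the dictionary's own columns recovers 100% of
triples except the analytically degenerate FF = 1 columns, where wT2 is
unidentifiable and the tie-break applies.

When an external fat-fraction volume is supplied, it is resampled onto
the MESE grid purely through the two affines (voxel centers, RAS mm,
linear interpolation by default, nearest for label-like maps; no image
registration), the per-voxel FF is quantized to the nearest grid value,
and the argmax is restricted to that FF's contiguous range — the output
FF map therefore equals the quantized constraint by construction.
Voxels outside the FF volume's field of view fall back to unconstrained
matching with a logged count. Percent-scaled FF maps (max > 1.5) are
auto-detected and divided by 100. Echo truncation (e.g. to 8/5/3
echoes) drops later rows and re-normalizes columns; truncating to the
full length is an exact no-op.

Background is excluded by thresholding the first-echo image at a
fraction (default 0.05) of its 99th-percentile intensity, or by a
user-supplied mask; out-of-mask voxels are NaN in every output map.

## Exponential fallbacks

The double-exponential model
`A·[(1-ff)·exp(-t/wT2) + ff·exp(-t/fatT2)]` (fat T2 fixed) is fitted by
bounded trust-region least squares with wT2 ∈ [1, 100] ms, ff ∈ [0, 1],
A ≥ 0, starting from A = first echo, wT2 = 35 ms, ff = 0.2 (or the
fixed constraint). These starts are mid-range physiological choices;
the fit is scale-equivariant and recovers noiseless in-model signals to
< 1e-5 ms. The mono-exponential variant fits `A·exp(-t/T2)` with T2 ∈
[1, 10000] ms; degenerate inputs that drive T2 to the bound are flagged
non-converged. Neither fit corrects for B1 or the slice profile — by
design, mirroring their role as fallbacks when the sequence details are
unknown — so with imperfect refocusing the mono-exponential T2
overestimates the true T2 (at B1 = 0.7 by ≈ 8 ms for wT2 = 40 ms).
Non-converging voxels are reported and skipped rather than aborting a
volume fit.

## Digital phantom

The phantom emulates a desk-scale version of a thigh protocol: 3 slices
of 64×64 voxels (1.2 mm in-plane, 40 mm slice pitch), eight circular
inserts with wT2 between 25 and 45 ms and FF between 0 and 0.6, a
linear left-right B1 gradient from 0.8 to 1.2, 17 echoes at 10.9 ms,
TR 4100 ms. Noiseless voxel signals are exactly the forward model;
Rician noise (|S + n1 + i·n2|, i.i.d. Gaussian) is then applied
per echo, with sigma set either directly or from a first-echo object
SNR (default 50, defined as the mean in-object first-echo amplitude
over sigma). A companion fat-fraction volume stores the true FF and can
be deliberately mis-registered by an integer voxel shift of its affine
to exercise header-based alignment. Overlapping regions resolve
last-listed-wins; a Gaussian noise model is available behind a flag.

What the phantom does not emulate: anatomy, partial-volume mixing
beyond the two-compartment model, spatially varying receive coil
profiles, multi-peak fat chemistry, chemical-shift displacement of the
fat slice, or motion. Passing phantom tests therefore demonstrates the
estimator's correctness and noise behavior under its own forward model,
not the absolute in-vivo accuracy, which additionally depends on how
well the assumed slice profile matches the scanner's.

At SNR 50 with the full 60-step wT2 grid, the voxelwise median |wT2
error| in regions with FF ≤ 0.4 is ≈ 2.2 ms — the noise floor of the
three-parameter match at this SNR; on the desk-scale reduced grid
(15 × 10 × 26, wT2 step ≈ 4.3 ms) the same error is well under one grid
step. The package's central qualitative behavior reproduces at desk
scale: with only 5 echoes the ROI-mean wT2 error grows strongly with
fat fraction (regression slope ≈ +25 ms per unit FF), and constraining
FF from the companion volume shrinks that trend by a factor of ≈ 5.

## ROI indicators

Per-ROI rows carry the voxel mean and sample SD (n−1 everywhere) of
wT2 and FF over non-NaN voxels. Aggregation is nested and unweighted:
voxels → ROI, ROIs → subject, subjects → population, so subjects with
more ROIs (or larger ROIs) do not dominate. On top of the table:

* FF error — population nested-mean FF difference between the MESE
  estimate and the reference water-fat map, in percentage points
  (positive = MESE higher);
* pooled SD — sqrt of the nested mean of squared within-ROI SDs
  (small-scale variability; equals the common SD when all ROI SDs
  agree). The square root is applied so the indicator carries the same
  units (ms) as the map;
* intrasubject SD — sqrt of the mean across subjects of the squared SD
  of a subject's ROI means (large-scale variability, e.g. field
  inhomogeneity); subjects with < 2 ROIs are excluded with a warning;
* group means — per-group mean and SD of subject-level means (SD is NaN
  for single-subject groups).

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own defaults for fast, deterministic checks:
the 121,200-entry default grid for combinatorial and matching
contracts (hard-pulse profile where the physics allows it), a reduced
15 × 10 × 26 grid with the full slice-profile model for phantom
recovery and the few-echo comparison, 1000 random voxels × 10,000
entries for the argmax cross-check, and 256 isochromats for the Bloch
oracle. Dictionary construction is exactly deterministic (pure
elementwise numpy); matching argmaxes are deterministic by the
tie-break rule. All randomness (phantom noise, random test signals)
flows from explicit integer seeds.
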