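# Methods

## Acquisition model

A volume is a (Z, Y, X) grid of linear attenuation coefficients with unit
voxels.  Projections over `N_a` equally spaced angles on [0, π) are
slice-wise 2D parallel-beam line integrals; detector rows coincide with Z
slices and the detector width equals the slice width (no magnification).
A point at slice coordinates (x₀, y₀) relative to the rotation center
(n−1)/2 traces the sinusoid t(θ) = x₀ cos θ + y₀ sin θ.  Forward
projection rotates the whole volume per angle (linear interpolation, zero
outside) and sums along the beam axis — vectorized over Z, which is what
makes 128³ test scans affordable on one CPU core.

Reconstruction is filtered back projection: the Ram-Lak filter in its
standard discretization (the real-space kernel with f(0) = 1/4,
f(n) = −1/(πn)² for odd n, transformed on a ≥2N zero-padded grid),
linear-interpolation back projection, and a π/(2 N_a) normalization so
amplitudes round-trip.  No circular mask is applied; values whose rays
leave the detector contribute zero.  FBP is linear, so additive
projection-domain artifacts map to additive reconstruction-domain
artifacts — the decomposition that motivates treating each artifact in
its natural domain.  The filter choice affects absolute PSNR baselines
mildly; windowed variants (Hann etc.) are deliberately out of scope.

A half-turn subtlety that shaped the tests: measurements satisfy
s(θ + π, t) = s(θ, −t), so only the mirror-even part of an angle-constant
detector-offset pattern is a *consistent* [0, π) sinogram.  A single
one-sided constant stripe reconstructs to a half-arc, not a closed ring
(scikit-image's `iradon` behaves identically); the rotational-symmetry
checks therefore use mirror-symmetrized stripe patterns.

## Foam phantom

The test object is a cylinder (axis along Z, radius 0.9 of the half-width)
of uniform attenuation μ = 1 containing non-overlapping spherical bubbles
of zero attenuation.  Bubble centers are uniform over the cylinder
cross-section (radially contained), radii log-uniform over a configurable
range — small bubbles dominate in number, as in physical foams; the
published protocol does not state a radius distribution, so this is the
package's choice.  Placement is rejection sampling with a budget of
1000·n attempts; voxel values are exactly binary {0, μ}.  Desk-scale
defaults keep roughly the full-scale bubble volume density: 120 bubbles of
radius 2–8 voxels in a 64³ grid, 400 of radius 3–14 in 128³.

## Artifact simulation

All corruption parameters live in one `ArtifactConfig`; "percentage"
parameters are fractions (P_ring = 0.1 means 10% of detector pixels).

* **Absorption calibration.** Before adding noise, projections are scaled
  by a single global factor c, found by bisection, so that the mean of
  1 − exp(−c·p) over object-intersecting rays (p > 0) equals the target
  absorbed fraction γ = 0.5 ("absorb about half the photons" read as
  exactly one half).
* **Poisson noise.** Counts k ~ Poisson(I₀·e^(−p)) per pixel, clipped
  below at one count (a zero count has no log), then p′ = −ln(k/I₀).
  I₀ is the dose knob: 30 and 100 are the severe and moderate conditions.
* **Ring offsets.** Exactly round(P_ring·M·N) detector pixels, drawn
  without replacement, receive a N(0, σ_ring²) offset (σ_ring = 0.005)
  added identically to every projection — exact counts rather than
  per-pixel Bernoulli so tests can assert them.
* **Zingers.** Exactly round(P_proj·N_a) projections are selected; in
  each, round(P_zinger·M·N) pixels are overwritten with v = 5,
  positions independent across projections.

Composition order is noise → rings → zingers: offsets model the detector's
systematic response on top of the counting statistics, and zingers model
saturation, overwriting whatever is underneath.  The order is
configurable via the per-artifact enable flags plus manual composition;
nothing downstream depends on it.  Rings and zingers are applied in the
post-log attenuation domain (offsets of order 0.005 and the value 5 are
attenuation-scale numbers).

## MS-D stage networks

Each stage is a width-1 mixed-scale dense network: layer i applies one
3×3 convolution with dilation ((i−1) mod 10) + 1 over the input and all
previous layer outputs, adds a scalar bias and a ReLU; a final 1×1 linear
layer maps all channels to the output.  Reflection padding preserves
spatial size.  Parameter count is therefore
Σᵢ [9·(c_in + i − 1) + 1] + (c_in + depth)·c_out + c_out, independent of
the dilation schedule.  Convolution weights are He-initialized from the
spec seed; the final layer starts at zero, so an untrained stage outputs
the target mean once normalization constants are attached.

Forward and backward passes are written directly on NumPy (tap-wise
tensordot over the dense channel stack; the reflection-padding adjoint
folds border gradients back inward).  The backward pass is verified
against numerical differentiation in the test suite.  Optimization is
Adam (lr 10⁻³ unless stated).  Per-stage input channels are standardized
with training-set means/stds; the output is de-standardized with the
target's statistics — stages therefore exchange data in physical units,
and the constants travel with the checkpoint.

## Training protocol

One corrupted low-quality scan (N_a angles) and one clean high-quality
scan (4·N_a angles) of the same phantom supply all supervision: LQ angle i
is exactly HQ angle 4i, so HQ projections are selected directly as stage-1
targets; the HQ sinogram and HQ reconstruction are the stage-2 and
stage-3 targets.  Both stage-2 input channels are angle-upsampled
(linear, wrap-aware at π through s(θ+π, n) = s(θ, N−1−n)) *before* the
network, and the stage-3 raw/enhanced channels are reconstructed from the
upsampled sinograms — upsample-then-refine, so the sinogram network can
also correct interpolation error and all three reconstruction channels
share one grid.

Stages train strictly in order 1 → 2 → 3; a stage is frozen (at its
lowest-validation-loss checkpoint) before the next stage's inputs are
computed from it, and no gradient crosses stage boundaries.  Whole images,
no patching or augmentation; 10% of images per stage are held out for
validation; early stopping after 10 stalled epochs.  Full-protocol epoch
budgets are (200, 200, 500) — the reconstruction stage sees the richest
image content — scaled to (30, 30, 45) for the desk-scale runs in the
test suite.  A configurable wall-clock cap replaces the original
multi-day training limit.

## Evaluation

PSNR = 10·log₁₀(range²/MSE) and SSIM (11×11 Gaussian window, σ 1.5,
C₁ = (0.01·range)², C₂ = (0.03·range)², no sample-covariance correction)
are computed per slice against the high-quality reference, with the
*reference volume's* global max − min as the range, and averaged along Z.
SSIM delegates to scikit-image with exactly these settings; the tests
check it against an independently written sliding-window implementation.
A uniform 7×7 window (another common default) would change the third
decimal; the Gaussian window is the package's convention.

## Classical baselines

* **Median zinger removal** (projection domain): pixels exceeding their
  size-3 local median by more than `dif` are replaced by that median.
  One-sided by design — zingers are saturation events, always positive.
* **Wavelet-Fourier ring suppression** (sinogram domain): per sinogram, a
  multilevel 2D DWT; in each level the vertical-detail band (which holds
  angle-constant stripes) is Fourier-transformed along the angle axis and
  multiplied by g(k) = 1 − exp(−k²/(2σ²)), suppressing low angular
  frequencies; then inverse transforms.  Reference parameters:
  level 4, sym5, σ = 8.

Two quantitative caveats, both verified in the tests: (i) because g(0)=0
at any σ, the filter always removes the angle-DC of the detail bands —
on data whose "legitimate" content includes such components (a
rotationally symmetric object is the extreme case: its entire sinogram is
angle-constant) the filter damages the object, so baseline comparisons
use structured objects; (ii) the filter is not exactly idempotent
(mid-band components are scaled by 0 < g < 1 per pass), but it is a
contraction — the second pass changes far less than the first.

`grid_search` tunes (dif, size, level, wavelet, σ) by exhaustively
applying zinger removal → ring removal → FBP for every combination and
returning the first-encountered argmax of mean SSIM against a clean
reference, together with the full score table.

## Scaled-down study sizes

All end-to-end checks run at desk scale, as the package's own protocol:
128³ phantoms with 64 corrupted / 256 clean angles for the
dose-degradation and classical-baseline checks, and 64³ phantoms with
32/128 angles and depth-20 networks for the stage-ablation study (seven
stage trainings: the shared projection stage, three single-stage
variants, and the sinogram/reconstruction stages of both chain
variants).  At these sizes the qualitative claims — monotone PSNR/SSIM
degradation with dose, strict improvement from classical pre-processing,
and the ordering single-projection ≤ single-sinogram ≤
single-reconstruction ≤ chain-without-bypass ≤ chain-with-bypass —
reproduce robustly; absolute PSNR values differ from full-scale runs
(fewer angles, coarser grids), and nothing in the suite asserts them.

## What the synthetic data does and does not show

The generator reproduces the structural essentials: binary foam contrast,
exact Beer-Lambert count statistics, strictly angle-constant detector
offsets and saturation-valued zingers.  Real scans add effects that are
deliberately out of scope — detector point-spread and crosstalk, beam
hardening, phase contrast, flat-field drift, partially correlated ring
offsets that vary slowly with angle, and multi-material contrast.
Passing tests therefore demonstrate the method's mechanics (information
flow, trainability, the value of bypass connections) under the stated
artifact models, not performance on any particular beamline's data.

## Numerical choices and degenerate inputs

* float32 storage everywhere; float64 inside FBP filtering and metric
  accumulation.
* Bisection tolerances: 10⁻⁶ (absorption calibration).
* Zero Poisson counts clipped to one count before the log.
* `angle_upsample(s, 1)` returns an identical copy; affine sequences are
  interpolated exactly in the interior.
* Networks require spatial dims ≥ 3 and reject channel mismatches;
  normalization stds are floored at 10⁻⁶.
* Training requires ≥ 2 pairs (one validation image is always held out)
  and aborts on non-finite loss.
* Ties in the classical grid search break toward the earlier grid entry.
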