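# Methods

## Forward model and conventions

The forward model is the standard Fourier-domain dipole relation for
the Lorentz-corrected local field: ΔB(k) = D(k)·X(k) with
D(k) = 1/3 − kp²/k², kp = k·b̂₀.  Everything downstream fixes the same
set of conventions:

* **Centered k-space.**  The DC sample sits at the geometric array
  center (`shape // 2` per axis); `fft_volume` is
  `fftshift(fftn(·))`, with numpy's default normalization (Parseval:
  `Σ|v|² = Σ|V|²/N`).  All FFT work is double precision.
* **D(0) := 0.**  The mean susceptibility is unobservable from the
  local field; the DC term of the kernel is pinned to zero, so forward
  fields are zero-mean and every inversion leaves the mean
  undetermined.  Reconstructions are therefore compared up to DC.
* **Continuous-form kernel on physical frequencies.**  D is evaluated
  at cycles/mm coordinates derived from the voxel size (not the
  discrete-Laplacian variant), so anisotropic voxels tilt the cone
  correctly.
* **Kernel evenness is enforced.**  On even-sized axes the Nyquist
  plane has no mirror partner, and for a tilted b̂₀ the sampled kernel
  would not satisfy D(−k) = D(k) there; the kernel is symmetrized,
  `D ← (D(k) + D(−k))/2`, which only touches Nyquist samples and
  guarantees a real forward field for every orientation.
* **Rotations.**  `rotation_to_b0(ax, ay)` applies right-handed
  intrinsic rotations about x then y to the default b̂₀ = (0,0,1).
  This is a documented convention, not an inferred one.
* **Units.**  χ is in ppm everywhere; the field maps carry the same
  ppm scale (relative offset × 10⁶).

## Analytic inversions

TKD divides pointwise by `sign(D)·max(|D|, thr)`; `sign(0)` is taken
as +1.  Valid thresholds are 0 < thr < 1/3 (at 1/3 and above nothing
in the cone-exterior plane survives untruncated; at 0 nothing is
truncated).  Both thr = 0.1 and thr = 0.2 are first-class: 0.2 is the
classic artifact-suppression choice, 0.1 keeps more native signal.
Note |D| itself ranges up to 2/3 (on-axis), so the non-ill-posed mask
|D| ≥ thr empties only above 2/3.

COSMOS fuses n orientations as `X = Σ ΔBᵢDᵢ / Σ Dᵢ²` and zeroes the
output where `Σ Dᵢ² < eps` (default 1e-8) — the joint null space,
which always contains DC and, for fewer than three generic
orientations, the intersections of the magic-angle cones.  With three
noiseless consistent orientations the round trip is exact to
floating-point (max abs error < 1e-6 ppm on a 64³ phantom, DC
excluded).

## The Fourier-domain correction network

Inputs: three k-space channels — the dipole kernel D and the real and
imaginary parts of FFT(χ_TKD).  Topology (all convs 3×3×3, stride 1,
padding 1): ConvBlock → 8 × ResBlock(ConvBlock → Dropout(0.2) →
Conv, + skip) → ConvBlock → ConvBlock → Conv(→ 2 channels);
LeakyReLU slope 0.1.  Output: corrected two-channel k-space; the map
is `|c|·sign(Re c)` of the inverse transform `c` (zero where Re c = 0).
Dropout is active only during training.

Losses: `ω₁·MSE + ω₂·L1` with ω₁ = ω₂ = 1.  The MSE is the mean over
k-points of the squared complex modulus of the error against the label
k-space; the L1 term is the mean complex-modulus deviation from the
TKD *input* over the non-ill-posed mask |D| ≥ thr.  The |·| of the
consistency term is read as a complex modulus (a channelwise absolute
value is the obvious alternative; the modulus is rotation-invariant in
the complex plane and was adopted).  Optimizer: Adam, learning rate
decayed to 90% every 25 epochs.  Training patches are cubes cut in the
Fourier domain with 50% overlap, clamped to the boundary so every
k-sample is covered; inference is a single fully-convolutional pass by
default (the architecture is shape-agnostic), with overlap-averaged
patch stitching available for volumes too large for one pass.

Two choices the architecture description leaves open:

* **k-space normalization.**  Raw k-space is DC-dominated with a huge
  dynamic range.  Each volume's TKD k-space (and its label, with the
  *same* factor) is divided by the volume's RMS k-space magnitude,
  recorded in the input stack; a max-based scale was rejected as
  unstable under single-sample outliers.
* **Identity-preserving initialization.**  The closing convolution of
  every residual branch starts at zero (each ResBlock is an exact skip
  at initialization), and the trunk routes the TKD channels through as
  ±pairs — LeakyReLU maps the pair (x, −x) to a pair whose difference
  is (1 + s^m)·x after m activations, so the signal survives the
  nonlinearities undistorted and the readout convolution compensates
  the (1 + s³) factor.  Small seeded Gaussian noise on all trunk
  kernels breaks symmetry.  The untrained network therefore already
  reproduces its TKD input, and optimization only has to learn the
  cone repair — the architectural expression of "correct only the
  ill-posed signals".  This also makes desk-scale training meaningful:
  any learned correction immediately improves on the TKD baseline
  rather than first having to rediscover the identity.

The network engine itself (`nnops.py`) is a small numpy implementation
— offset-major im2col convolutions, LeakyReLU, inverted dropout,
residual blocks, Adam — sufficient for single-sample CPU training at
desk scale.  Feature width is configurable: 64 for a full-scale run,
8–16 at desk scale.

### Desk-scale training profile

The tests and the demo pipeline train a width-8 network on 32³
phantoms (four training volumes × 50 epochs = 200 optimizer steps,
fixed seed, one CPU, ≈ 3 minutes).  At this scale the initial learning
rate is 1e-3; the 1e-4 default of `TrainingConfig` is tuned to
full-scale runs, and a tiny network taking a few hundred steps
benefits from the larger rate (both settle and both beat TKD at desk
scale; 1e-3 converges further).  Loss logs are per-epoch means;
training aborts on a non-finite loss.

## Synthetic data

`phantom_sim` stands in for multi-orientation in-vivo acquisitions:

* Phantoms are piecewise-constant spheres/cylinders plus smooth
  Gaussian blobs and a band-limited background texture, with χ in the
  brain-plausible ±1 ppm range (deep-nuclei values ~0.1 ppm, a
  vein-like cylinder at 0.3 ppm).  The default suite mimics a small
  study: 6 training / 1 validation / 1 test subject, 64³.
* Field maps come from the dipole forward model per orientation, plus
  additive white Gaussian noise (sd in ppm; the noise model is a
  choice — real field maps carry structured residuals of phase
  processing that white noise does not emulate).
* The **sphere oracle** is the closed-form magnetostatic solution:
  external field (Δχ/3)(a/r)³(3cos²θ − 1), zero inside (the same
  Lorentz convention as the kernel), mean-subtracted to match the
  pinned DC.  Because the FFT model is a circular convolution — it
  computes the field of a *lattice* of spheres — the oracle can
  optionally superpose shells of lattice-image spheres
  (`periodic_images`); with one shell the FFT field agrees to 2.4%
  relative L2 outside a 2-voxel interface shell (64³, radius 8),
  discretization-limited.
* **Anisotropy** is injected as a scalar orientation-dependent
  apparent susceptibility, χ_iso + χ_aniso·(3cos²ψ − 1)/2 with ψ the
  fiber-to-b̂₀ angle.  This is a deliberate stand-in for the full
  susceptibility-tensor picture: it produces the orientation-dependent
  ROI means the statistics need, but fits no tensor and its effect
  size is not calibrated to in-vivo white matter.

What passing tests on these phantoms do *not* show: robustness to
phase-processing residuals, background-field leakage, partial-volume
anatomy, or vendor-specific noise — all absent from the generator.

## Metrics

NRMSE = 100·‖x−ref‖₂/‖ref‖₂; PSNR = 10·log₁₀(peak²/MSE) with peak the
reference range over the mask (identical volumes report a 200 dB cap);
HFEN is the NRMSE of Laplacian-of-Gaussian-filtered volumes (15³
kernel, σ = 1.5, the QSM reconstruction-challenge convention); SSIM is
the masked mean of the local similarity map (Gaussian window σ = 1.5,
standard stabilization, dynamic range from the reference over the
mask).  All are computed within the brain/phantom mask.  Line profiles
sample a segment by nearest-voxel rounding of max(Δ∞)+1 equally spaced
points and are compared by MAE, RMSE and Pearson's r (undefined, and
rejected, for constant profiles).

## ROI statistics

Orientation-variation protocol per ROI: Levene's test
(median-centered, i.e. Brown–Forsythe) gates the omnibus test — ANOVA
is valid iff the Levene p > 0.05, otherwise Kruskal–Wallis; the valid
test's p < 0.05 is an anisotropy call.  Degenerate all-identical data
report p = 1 by convention.  The sampling unit is whatever the caller
supplies; the package's own pipelines use per-voxel values within the
ROI per orientation (per-subject means are equally valid input).  Group
comparison uses the equal-variance two-sample t-test by default (Welch
switchable), reports percent change 100·(m₂−m₁)/|m₁| and absolute
means (susceptibility levels compare on magnitude), and tiers
significance as ⋆⋆ (p < 0.01) / ⋆ (0.01 ≤ p < 0.05).  No
multiple-testing correction is applied by default; a Bonferroni factor
is available.

On synthetic ROIs the protocol's false-call rate with zero injected
anisotropy stays at or below nominal over seeded replicates, and its
detection rate rises monotonically with χ_aniso, reaching 1 at 3× the
within-ROI noise sd over five orientations.

## Numerical and degenerate-input choices

* TKD at D = 0 uses sign +1 (the numerator is zero for consistent
  data, so only the convention matters).
* COSMOS guard eps = 1e-8; the zeroed set is logged when larger than
  the DC sample alone.
* `sign(Re c) = 0` zeroes the output voxel (documented tie rule).
* Overlapping phantom shapes: the later shape wins, with a warning;
  shapes fully overwritten drop out of the label table.
* Empty consistency mask: L1 loss is 0 with a warning.
* PSNR of identical volumes: capped sentinel instead of +∞.

## Limitations

* The network engine is CPU-bound numpy; full-scale (width 64, 224³
  in-vivo volumes) training is out of reach here — the desk-scale
  profile demonstrates the mechanism, not in-vivo performance.
* COSMOS is treated as exact ground truth in synthetic training; real
  COSMOS labels carry their own artifacts.
* The anisotropy generator is scalar, not a tensor model.
* NIfTI affines are carried through but only voxel size is honored
  (no resampling or reorientation).
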