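# Methods

`dwimoco` implements motion-tolerant acquisition design and model-based
retrospective motion correction for multi-shell diffusion MRI of the
fetal brain, validated end to end on a synthetic phantom with known
ground truth.  This note records the models, the numerical choices, and
what the synthetic validation does and does not establish.

## Signal representation

The diffusion signal E(q) over q-space is expanded in the
simple-harmonic-oscillator (SHORE) basis

    E(q) = sum_{l even}^{N} sum_{n=l}^{N} sum_{m=-l}^{l}
           c_nlm X_nl(|q|, zeta) Y_lm(u),

with generalized-Laguerre radial functions

    X_nl(q, zeta) = sqrt(2 (n-l)! / (zeta^{3/2} Gamma(n+3/2)))
                    (q^2/zeta)^{l/2} e^{-q^2/(2 zeta)}
                    L_{n-l}^{l+1/2}(q^2/zeta),

orthonormal under q^2 dq for each degree l, and real, orthonormal
spherical harmonics of even degree.  Two truncation conventions
circulate for this family; the wider one adopted here keeps every
radial order l <= n <= N and yields 72 basis functions at N = 6
(versus 50 for the even-(n-l) alternative).  The extra radial
resolution matters for multi-shell data.

**q–b mapping.** q = sqrt(b)·u with b in s/mm^2.  Diffusion timings
(delta, Delta) are not modeled; their effect is absorbed into the scale
parameter zeta.  This is a unit convention, not physics: the default
zeta = 700 is calibrated for this mapping and for b-values in the
hundreds-to-thousands range.

**Defaults.** N = 6, zeta = 700, lambda_l = lambda_n = 1e-8.

## Weighted regularized fit

Per voxel, coefficients solve

    min_c ||W (Phi c - E)||^2 + lambda_l ||L c||^2 + lambda_n ||N c||^2,

with diag(L) = l(l+1), diag(N) = n(n+1) penalizing angular and radial
roughness, through the normal equations with a Cholesky solve.  W is
diagonal, built from slice weights (all voxels of a slice share one
weight per volume) and optionally voxel weights.  With two shells plus
b = 0 the radial part of the design is rank-deficient at order 6 (at
most three distinct radii); the small l2 penalties make the problem
well-posed, and prediction is only ever required at the sampled radii.
Voxels in the same axial slice share the weight vector, so one
factorization serves a whole slice; the voxel-weighted final pass uses
batched per-voxel normal equations.

## Outlier weighting

Three tiers populate W, all scale-free in the input intensities:

* **Modified Z-score** (bootstrap, no prediction needed): per shell,
  slice-mean intensities are standardized against the shell median with
  1.4826·MAD; the weight ramps linearly from 1 at Z = eta_l to 0 at
  Z = eta_u.  The thresholds are not dictated by theory; the defaults
  eta_l = 3, eta_u = 10 start the ramp at the conventional modified-Z
  outlier cut and reach zero only for gross dropouts.  Slices with no
  brain coverage are excluded from the statistics (their means are
  mask-dependent constants that would otherwise collapse the MAD).
* **Bayesian GMM**: per shell, a two-component Bayesian Gaussian
  mixture (weight-concentration prior 1e-2, covariance floor 1e-6) on
  log slice-RMSE between acquired and predicted data; the weight is the
  posterior probability of the lower-mean component.  Degenerate cases
  (identical series, merged components, fewer than 4 informative
  slices) fall back to all-ones.
* **Voxel-wise**: z = residual / (1.4826·MAD) per volume over brain
  voxels, mapped through w = 1/(z^2+1)^2 — a redescending weight that
  is 1 at z = 0, 1/4 at z = 1 and 1/100 at z = 3.

The ramp of the modified-Z weight is clamped to [0, 1] (the raw linear
form exceeds that range outside the thresholds).

## Intensity corrections

**Rician bias.**  Magnitude data at SNR theta = eta/sigma satisfies the
moment identity <M>^2 = eta^2 + (2 - xi(theta)) sigma^2, where
xi(theta) = Var(M)/sigma^2 is evaluated stably for all theta through
exponentially scaled Bessel functions (xi(0) = 2 - pi/2, xi -> 1 at
high SNR).  The unbiased intensity solves the fixed point
E_c^2 = <M>^2 + (xi(E_c/sigma) - 2) sigma^2, initialized at
theta_0 = <M>/sigma, iterated to a relative tolerance of 1e-6 and
clamped at zero (pure noise maps to ~0).  Note the sign: the correction
*subtracts* the bias, so E_c <= <M> always; a Monte-Carlo oracle in the
tests pins this down.  sigma is an input (scalar or map); a MAD-based
fallback estimator from b = 0 repeats is provided.

**B1 bias.**  A multiplicative receive-field beta is divided out while
preserving the global scale via the ratio of the masked mean b = 0
intensity after/before field correction.  Estimating beta itself (e.g.
N4) is out of scope; the field is an input.

## Scheme design and ordering

Directions minimize an antipodally symmetric Coulomb energy
E(S) = sum_{i<j} 1/|u_i-u_j| + 1/|u_i+u_j|, combined as
w·E(pooled) + (1-w)·mean_shell E(shell) with w = 0.5, by multi-start
(20 restarts) projected gradient descent on the product of spheres with
an adaptive step.  Coincident/antipodal pairs report the largest finite
float rather than infinity so refinement can escape them.  Temporal
ordering then (a) spreads the b = 0 volumes evenly, (b) keeps every
prefix's shell counts within one volume of the target ratio, and (c)
picks, within a shell, the direction farthest (antipodal angle) from
all same-shell directions already placed (greedy farthest point).  Any
early termination of an acquisition ordered this way still contains a
near-uniform multi-shell sample.

## Registration

Rigid transforms are parameterized as translations (mm) plus intrinsic
z-y-x Euler angles (degrees) about the image center; resampling maps
the output grid through the inverse transform.  Registration maximizes
global normalized cross-correlation over a 3-level pyramid
(downsampling 4/2/1, Gaussian smoothing 2/1/0) with Powell's method
(xtol 0.005, 12 iterations per level).  The metric interpolates the
moving image trilinearly on the coarse levels and with an exact cubic
B-spline at full resolution, which smooths the cost surface near the
optimum; inside the correction loop the metric stays trilinear
throughout, because spline overshoot at sharp tissue boundaries biases
rotations when the target is a smooth model prediction.  Powell alone has a limited
capture range, so the coarsest level is first scanned over a
deterministic grid of Euler angles (+-30 deg in 15-deg steps per axis)
with the translation initialized from the intensity centroids; the
warm-start estimate from the previous epoch competes with the grid.
The metric is evaluated on the bounding box of the fixed image's
support, which both tightens it and keeps each evaluation cheap.

## The iterative correction loop

Five epochs by default.  Epoch 1 bootstraps with modified-Z slice
weights, fits SHORE to the acquired data, predicts every volume's
contrast in the original q-space, registers each acquired volume to its
prediction, and rotates each b-vector by the estimated rotation.
Epochs 2–4 recompute the basis on the rotated q-space, re-fit on the
re-registered data (transforms always applied to the original volumes,
never compounded), re-weight with the GMM against the current
prediction, re-register and re-rotate.  The final epoch applies the
refined transforms, adds voxel-wise weights on top of the GMM slice
weights, and produces the final fit and prediction.  Registrations that
leave the plausible range (50 mm / 60 deg) flag the volume; flagged
volumes keep their previous transform and are zero-weighted.  After
each registration pass the median estimated transform is composed out
of every estimate, anchoring the (otherwise arbitrary) consensus frame
of the corrected series at the dominant rest pose.

The working registered series is resampled with a cubic spline each
epoch (not just the final output): the sharper kernel keeps the refit
data's point-spread function close to the original volumes', and a
measurable pose-dependent rotation bias appears when a blurrier
trilinear working resample feeds the predictions that the sharp
originals are then registered against.

Two further details matter in practice:

* **Leave-one-out registration targets.**  The SHORE fit is a linear
  smoother; its prediction for volume v leans on volume v's own —
  possibly mis-posed — data with substantial leverage (72 coefficients
  against 95 samples).  Registering against that prediction anchors
  each volume to its current pose.  The registration target therefore
  removes each volume's own contribution through the exact rank-1
  leave-one-out identity y0_loo = y0 - g·(E - yk)/(1 - h), computed per
  slice from the already-factorized normal equations.  The leverage h
  is capped at 0.35: beyond that a sample's direction has too little
  angular coverage from its neighbours for full removal to give a
  reliable target (the cap is inactive for the reference 95-volume
  scheme, whose leverages stay below ~0.3).  Weighting and the final
  reconstruction use the ordinary prediction.
* **Prediction support.**  Outside the brain mask the prediction is
  basis ripple, not anatomy; it is zeroed (after a 2-voxel dilation of
  the mask) before being used as a registration target.

On motion-free input the loop is a fixed point: weights stay near 1,
registration returns near-identity, and the corrected series equals the
input up to interpolation.

## Synthetic phantom

The phantom emulates a fetal brain at desk scale: a 32^3 grid at 2.5 mm
isotropic (80 mm field of view), an anisotropic ellipsoidal "brain"
(48 x 42 x 35 mm) with two unequal CSF-filled ventricle-like cavities,
two coherent single-fiber regions (principal diffusivity 1.7e-3 mm^2/s,
radial 0.3e-3), a crossing-fiber region (two equal-fraction tensors),
isotropic parenchyma (1.0e-3) and CSF (2.8e-3), region-dependent S0
levels plus a smooth 12% texture.  The asymmetric geometry is essential:
rigid pose must be identifiable from every diffusion contrast, and the
brain must be small enough relative to the field of view that 20 mm
excursions do not push it out of frame.

The forward model per volume: the multi-tensor signal is evaluated on
the motion-rotated encoding direction (the moving object sees R^T u),
the volume is resampled under the ground-truth rigid transform, slice
corruptions are applied (dropout attenuation in (0,1); spin-history
hyperintensity as a gain > 1), and Rician noise is formed exactly as
|S + n1 + i·n2|.  Opposed-blip susceptibility distortion is simulated
as a 1-D displacement along the phase-encode axis with mass-preserving
linear splatting, so stretching in one blip appears as pile-up in the
other; estimating the field from such a pair is out of scope.

**Motion model.**  Ground-truth traces are piecewise-constant with
short bursts: the fetus rests near a baseline pose and repositions
abruptly for a few volumes at a time (each burst pose drawn from
40–100% of the per-axis bounds, 20 mm / 24 deg by default), with small
jitter throughout.  This excursion-and-return pattern matches observed
fetal traces and leaves a substantial fraction of volumes near
baseline — the working assumption of outlier-weighted reconstruction.
A motion model in which every segment sits at an independent extreme
pose has no dominant mode and is not correctable by this (or any
consensus-seeking) volume-to-prediction scheme; the loop then converges
to a self-consistent blend.  This boundary of applicability is worth
knowing.

**Reference experiment.**  95 volumes (11 interleaved b = 0, 28 @
b = 400, 56 @ b = 900 s/mm^2), 3 bursts, 10% of brain-covered slices
dropped out at attenuation 0.2, Rician sigma = 2 (b = 0 SNR ~50 in
parenchyma, ~10–25 at b = 900).  The problem size (32^3 grid) keeps a
full five-epoch run in the minutes range on one CPU while leaving the
estimation problem genuinely ill-posed in the same ways as the real one
(two shells, 72 coefficients, low DW SNR).

## Evaluation

SSIM uses the standard constants (K1 = 0.01, K2 = 0.03, 7-voxel uniform
window) with the dynamic range taken from the image pair, computed
slice-wise and aggregated per slice across volumes (mirroring how
slice distributions are usually reported); PSNR is 10·log10(range^2 /
MSE) with an infinity sentinel for identical images.  Motion-trace
error is the Euclidean translation difference (mm) and the geodesic
angle of R_true R_est^T (degrees).  A global rigid offset common to
both traces cancels only when composed on the same side; the
consensus frame of a correction run is anchored by the baseline
volumes, so residual frame offset shows up honestly in these errors.

## What passing the synthetic suite does and does not show

The phantom validates the estimation machinery: basis correctness
(quadrature orthonormality), exact recovery in the noiseless
well-conditioned regime, weight formulas, Rician statistics, and
motion recovery under the stated motion model.  It does not emulate:
maternal tissue surrounding the brain, intra-volume (slice-level)
motion (handled only by down-weighting, as in the volume-registration
design), eddy-current distortion, partial-volume and gestational-age
contrast variation, or multi-coil noise correlation (noise is
single-coil Rician).  Numbers obtained here therefore bound the
method's behavior under its own assumptions, not its clinical
performance.

## Known limitations

* Volume-to-volume registration only; a volume corrupted by within-
  volume motion is rejected, not repaired.
* The consensus frame is defined by the data themselves; absolute pose
  with respect to an external anatomical frame is unidentifiable.
* The electrostatic optimizer is a local method with restarts; designed
  schemes are very good but not certified global optima.
* The LOO registration target assumes slice-shared weights (exact in
  epochs 1–4); the voxel-weighted final epoch performs no registration,
  so this never approximates.
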