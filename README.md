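# dwimoco

Motion-tolerant acquisition design and retrospective motion correction
for multi-shell diffusion MRI of the moving (fetal) brain.

Fetal diffusion MRI is corrupted by unpredictable rigid head motion:
volumes are mis-posed, slices drop out when motion coincides with
diffusion encoding, and spin-history effects leave hyperintense slices.
`dwimoco` addresses this with a model-based, registration-to-prediction
loop: the diffusion signal E(**q**) is represented per voxel in the
SHORE basis (generalized-Laguerre radial functions times real spherical
harmonics, 72 functions at order 6, scale ζ = 700 for the q = √b·u
mapping), coefficients **c** are estimated by weighted ℓ2-regularized
least squares

&nbsp;&nbsp;&nbsp;&nbsp;min_c ‖W(Φc − E)‖² + λ_l‖Lc‖² + λ_n‖Nc‖²,&nbsp;&nbsp;
diag(L) = l(l+1), diag(N) = n(n+1), λ = 10⁻⁸,

and each acquired volume is rigidly registered to the signal the model
predicts for its own diffusion contrast.  Corrupted slices and voxels
are down-weighted by a three-tier scheme (modified Z-score on slice
means; a Bayesian Gaussian mixture on log slice-RMSE against the
prediction; voxel-wise redescending weights w = 1/(z²+1)²).  Weighting,
fitting, prediction, registration and gradient-table rotation alternate
over five epochs.  The package also designs the acquisition itself —
multi-shell direction sets by antipodal electrostatic repulsion with an
incremental, shell-interleaved temporal order — and provides Rician
noise-bias and B1 receive-field intensity corrections, a synthetic
multi-tensor phantom simulator with ground-truth motion/corruptions,
and SSIM/PSNR/trace-error scoring.

Everything is exercised on synthetic phantoms with known ground truth;
see `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate a small two-shell acquisition of a fetal-brain-like phantom in
which three volumes are displaced (8, −5, 3 mm; 10, −6, 12°), then
recover the motion:

```python
import numpy as np
import dwimoco as dm

phantom = dm.make_phantom(dm.PhantomSpec())
scheme = dm.design_scheme(
    n_b0=3, shells=[(400.0, 6), (900.0, 12)], seed=7, n_restarts=3,
).in_temporal_order()

motion = np.zeros((len(scheme), 6))
motion[[4, 9, 15]] = [8.0, -5.0, 3.0, 10.0, -6.0, 12.0]
series, truth = dm.simulate_series(
    phantom, scheme, dm.CorruptionSpec(motion=motion, sigma=1.0, seed=5))

model = dm.MotionCorrection(series, mask=phantom.mask,
                            config=dm.CorrectionConfig(n_epochs=3))
res = model.fit()
print(res.summary())

report = dm.trace_error(dm.MotionTrace(truth["trace"]), res.motion_trace)
print(f"median translation error: {report.median_translation:.2f} mm")
print(f"median rotation error:    {report.median_rotation:.2f} deg")
```

Output:

```
Motion correction results
====================================================
volumes:              21
epochs:               3
flagged volumes:      0
median |t| (mm):      0.138
max |t| (mm):         9.427
median |r| (deg):     0.255
max |r| (deg):        16.615
mean slice weight:    0.868
----------------------------------------------------
epoch  weighting   weighted RMSE
    1  zscore           3.2033
    2  gmm              1.4524
    3  gmm+voxel        1.9293
median translation error: 0.14 mm
median rotation error:    0.25 deg
```

The summary shows the estimated per-volume motion (`max |t|` ≈ 9.4 mm
and `max |r|` ≈ 16.6° correspond to the three injected poses, whose
rigid magnitudes are 9.9 mm and ~16.6°), how much of the data the
weighting trusts, and the per-epoch weighted residual between the data
and the model prediction.  The trace errors at the end compare the
estimated motion with the simulator's ground truth volume by volume:
both the displaced and the still volumes are recovered to a fraction of
a voxel (2.5 mm) and of a degree.  The weighted RMSE is not monotone
across epochs because the final epoch swaps in the harsher voxel-level
weighting and resamples the data.

`MotionCorrectionResults` also carries the corrected series
(`res.corrected`), the rotated gradient table (`res.rotated_scheme`),
the final slice/voxel weights (`res.weights`) and the per-voxel SHORE
coefficients (`res.coefficients`).

## Command line

The same functionality is exposed as a thin CLI:

```bash
dwimoco design-scheme --b0 11 --shell 400:28 --shell 900:56 --seed 1 --out-prefix scheme
dwimoco simulate --seed 2 --out-dir sim/
dwimoco correct --input sim/dwi.nii.gz --bval sim/dwi.bval --bvec sim/dwi.bvec \
                --mask sim/mask.nii.gz --epochs 5 --seed 0 --out-dir corrected/
dwimoco evaluate --corrected corrected/corrected.nii.gz --reference sim/clean.nii.gz \
                 --true-trace sim/true_trace.tsv --est-trace corrected/motion_trace.tsv \
                 --out report.json
```

Further subcommands: `fit-shore`, `weights`, `rician-correct`,
`b1-correct`.

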