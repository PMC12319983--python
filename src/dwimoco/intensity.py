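"""Intensity corrections: Rician noise bias and B1 receive-field bias.

Magnitude MRI at low SNR is Rician distributed, so the measured mean
overestimates the underlying signal eta.  With theta = eta/sigma the
Rician moments give  <M>^2 = eta^2 + (2 - xi(theta)) sigma^2, where
xi(theta) is the Koay-Basser correction factor (the ratio Var(M)/sigma^2).
Inverting this moment identity,

    E_c^2 = <M>^2 + (xi(theta) - 2) sigma^2,   theta = E_c / sigma,

is solved as a fixed point for the unbiased intensity E_c.  Note the
subtraction of the bias: xi -> 1 at high SNR, so E_c^2 -> <M>^2 - sigma^2.

B1 receive-field inhomogeneity is removed by dividing out a multiplicative
bias field beta (e.g. from N4) while preserving the global intensity scale
through the ratio of the mean b=0 intensity after/before field correction.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e, i1e

from .io import DWISeries

__all__ = [
    "xi_factor",
    "rician_correct",
    "b1_correct",
    "estimate_sigma_mad",
]


def xi_factor(theta):
    """Rician variance correction factor xi(theta), theta = eta/sigma >= 0.

    xi = 2 + theta^2 - (pi/8) exp(-theta^2/2)
         [(2 + theta^2) I0(theta^2/4) + theta^2 I1(theta^2/4)]^2.

    Evaluated with exponentially scaled Bessel functions, which cancel the
    exp(-theta^2/2) factor exactly, so the expression is stable for any
    theta.  xi(0) = 2 - pi/2 (Rayleigh); xi -> 1 as theta -> inf.
    """
    t = np.asarray(theta, dtype=float)
    if np.any(t < 0):
        raise ValueError("theta (SNR) must be non-negative")
    x = t * t / 4.0
    bracket = (2.0 + t * t) * i0e(x) + t * t * i1e(x)
    out = 2.0 + t * t - (np.pi / 8.0) * bracket ** 2
    return out if out.ndim else float(out)


def rician_correct(mean_magnitude, sigma, tol: float = 1e-6,
                   max_iter: int = 100):
    """Unbiased signal intensity E_c from the measured magnitude mean.

    Solves E_c^2 = <M>^2 + (xi(theta) - 2) sigma^2 with theta = E_c/sigma
    by fixed-point iteration from theta_0 = <M>/sigma, to relative
    tolerance ``tol``.  sigma = 0 returns the input unchanged; a
    pure-noise magnitude (<M> ~ sigma sqrt(pi/2)) maps to ~0.

    Accepts scalars or arrays (sigma may be scalar or voxel-wise).
    """
    M = np.asarray(mean_magnitude, dtype=float)
    if np.any(M < 0):
        raise ValueError("mean magnitude must be non-negative")
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), M.shape).copy()
    if np.any(sig < 0):
        raise ValueError("sigma must be non-negative")
    shape = M.shape
    scalar = M.ndim == 0
    M = np.atleast_1d(M).ravel().copy()
    sig = np.atleast_1d(sig).ravel()
    ec = M.copy()
    active = sig > 0
    residual = 0.0
    for _ in range(max_iter):
        if not np.any(active):
            break
        theta = ec[active] / sig[active]
        ec2 = M[active] ** 2 + (xi_factor(theta) - 2.0) * sig[active] ** 2
        new = np.sqrt(np.maximum(ec2, 0.0))
        delta = np.abs(new - ec[active])
        ec[active] = new
        conv = delta <= tol * np.maximum(new, sig[active])
        residual = float(delta.max())
        idx = np.flatnonzero(active)
        active[idx[conv]] = False
    if np.any(active):
        raise RuntimeError(
            "Rician correction did not converge after "
            f"{max_iter} iterations; max residual {residual:.3e}"
        )
    return float(ec[0]) if scalar else ec.reshape(shape)


def estimate_sigma_mad(series: DWISeries, mask=None) -> float:
    """Fallback noise-sigma estimate from b=0 repeat variability.

    Uses 1.4826 * MAD of voxel-wise deviations of each b=0 volume from
    the median b=0 volume, scaled for pairwise differencing.  Intended
    when no externally estimated sigma map is available.
    """
    b0 = series.intensities[..., series.scheme.b0_mask]
    if b0.shape[-1] < 2:
        raise ValueError("need at least two b=0 volumes to estimate sigma")
    med = np.median(b0, axis=-1, keepdims=True)
    resid = b0 - med
    if mask is not None:
        resid = resid[np.asarray(mask, dtype=bool)]
    mad = np.median(np.abs(resid))
    return float(1.4826 * mad)


def b1_correct(series: DWISeries, beta: np.ndarray,
               mean_b0_raw: float | None = None,
               mean_b0_corrected: float | None = None,
               mask=None) -> DWISeries:
    """Divide out a multiplicative B1 bias field.

    E_c(q) = E(q) * mean_b0_corrected / (beta * mean_b0_raw), where the
    means are brain-masked averages of the mean b=0 volume before and
    after field correction.  When the means are not supplied they are
    computed from the series itself (raw) and from the field-corrected
    b=0 mean, so the default call preserves the global intensity scale.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != series.intensities.shape[:3]:
        raise ValueError("bias field shape must match the volume grid")
    m = np.asarray(mask, dtype=bool) if mask is not None else np.ones(
        beta.shape, dtype=bool)
    if np.any(beta[m] <= 0):
        raise ValueError("bias field must be positive inside the mask")
    if mean_b0_raw is None or mean_b0_corrected is None:
        b0 = series.intensities[..., series.scheme.b0_mask].mean(axis=-1)
        mean_b0_raw = float(b0[m].mean())
        mean_b0_corrected = float((b0 / beta)[m].mean())
    if mean_b0_raw == 0:
        raise ValueError("mean b=0 intensity is zero")
    scale = mean_b0_corrected / mean_b0_raw
    corrected = series.intensities * (scale / beta)[..., None]
    return DWISeries(np.maximum(corrected, 0.0), series.affine, series.scheme)
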