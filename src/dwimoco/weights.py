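"""Slice- and voxel-level outlier weighting.

Three complementary schemes populate the diagonal weighting matrix W of
the regularized SHORE fit:

* a modified Z-score on per-slice mean intensities within each shell
  (needs no prediction; used to bootstrap the first fit),
* a two-component Bayesian Gaussian mixture on log slice RMSE between the
  acquired data and the current model prediction (inlier-posterior
  probability becomes the weight),
* voxel-wise standardized residuals mapped through w = 1/(z^2 + 1)^2 for
  localized artifacts (spin history, physiological motion).

All weights live in [0, 1]; 1 means fully trusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import BayesianGaussianMixture

from .gradients import GradientScheme
from .io import DWISeries

__all__ = [
    "WeightSet",
    "zscore_slice_weights",
    "gmm_slice_weights",
    "voxel_weights",
    "DEFAULT_ETA_LOWER",
    "DEFAULT_ETA_UPPER",
]

log = logging.getLogger(__name__)

#: Soft ramp of the modified-Z slice weight: weight 1 at Z <= eta_l,
#: 0 at Z >= eta_u (the conventional modified-Z outlier cut is ~3.5).
DEFAULT_ETA_LOWER = 3.0
DEFAULT_ETA_UPPER = 10.0

_MAD_SCALE = 1.4826


@dataclass
class WeightSet:
    """Per-slice and optional per-voxel weights for one series.

    ``slice_weights`` is (Z, N) over (slice, volume); ``voxel_weights``
    is (X, Y, Z, N) or None.  ``method`` tags the producing scheme.
    """

    slice_weights: np.ndarray
    voxel_weights: np.ndarray | None = None
    method: str = ""

    def __post_init__(self):
        sw = np.asarray(self.slice_weights, dtype=float)
        if np.any(sw < 0) or np.any(sw > 1):
            raise ValueError("slice weights must lie in [0, 1]")
        self.slice_weights = sw
        if self.voxel_weights is not None:
            vw = np.asarray(self.voxel_weights, dtype=float)
            if np.any(vw < 0) or np.any(vw > 1):
                raise ValueError("voxel weights must lie in [0, 1]")
            self.voxel_weights = vw

    def per_sample(self, shape4d) -> np.ndarray:
        """Expand to a full (X, Y, Z, N) weight array (slice x voxel)."""
        w = np.broadcast_to(
            self.slice_weights[None, None, :, :], shape4d
        ).copy()
        if self.voxel_weights is not None:
            w *= self.voxel_weights
        return w


def _slice_means(data: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """(Z, N) mean intensity per slice, within the mask when given."""
    if mask is None:
        return data.mean(axis=(0, 1))
    m = mask.astype(bool)
    counts = m.sum(axis=(0, 1)).astype(float)  # per slice
    sums = (data * m[..., None]).sum(axis=(0, 1))
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    return np.where(counts[:, None] > 0, means, 0.0)


def _shell_groups(scheme: GradientScheme):
    """Volume-index groups per b-value shell, b=0 included as a group."""
    groups = [np.flatnonzero(scheme.b0_mask)]
    groups += [
        np.flatnonzero(scheme.shell_mask(b) & ~scheme.b0_mask)
        for b in scheme.shells
    ]
    return [g for g in groups if g.size]


def zscore_slice_weights(series: DWISeries, scheme: GradientScheme | None = None,
                         eta_l: float = DEFAULT_ETA_LOWER,
                         eta_u: float = DEFAULT_ETA_UPPER,
                         mask: np.ndarray | None = None) -> WeightSet:
    """Modified Z-score slice weighting within each shell.

    Per shell: residual of each slice-mean intensity against the shell
    median, standardized by 1.4826 * MAD of those residuals; the weight
    ramps linearly from 1 at ``Z <= eta_l`` to 0 at ``Z >= eta_u``.
    A degenerate shell (MAD = 0) keeps all its weights at 1.
    """
    if not eta_u > eta_l >= 0:
        raise ValueError("need eta_u > eta_l >= 0")
    scheme = scheme if scheme is not None else series.scheme
    data = series.intensities
    means = _slice_means(data, mask)  # (Z, N)
    if mask is not None:
        covered = np.asarray(mask, bool).any(axis=(0, 1))  # (Z,)
    else:
        covered = np.ones(data.shape[2], dtype=bool)
    z = np.zeros_like(means)
    for vols in _shell_groups(scheme):
        sub = means[np.ix_(covered, vols)]
        med = np.median(sub)
        resid = sub - med
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad == 0:
            log.info("degenerate shell (MAD = 0); weights left at 1")
            continue
        z[np.ix_(covered, vols)] = np.abs(resid) / (_MAD_SCALE * mad)
    w = np.clip(1.0 - (z - eta_l) / (eta_u - eta_l), 0.0, 1.0)
    return WeightSet(w, method="zscore")


def _slice_rmse(acquired: np.ndarray, predicted: np.ndarray,
                mask: np.ndarray | None) -> np.ndarray:
    """(Z, N) RMSE between acquired and predicted, per slice and volume."""
    sq = (acquired - predicted) ** 2
    if mask is None:
        return np.sqrt(sq.mean(axis=(0, 1)))
    m = mask.astype(bool)
    counts = m.sum(axis=(0, 1)).astype(float)
    sums = (sq * m[..., None]).sum(axis=(0, 1))
    with np.errstate(invalid="ignore"):
        mse = sums / counts[:, None]
    return np.sqrt(np.where(counts[:, None] > 0, mse, 0.0))


def gmm_slice_weights(series: DWISeries, predicted_series: np.ndarray,
                      seed: int = 0, scheme: GradientScheme | None = None,
                      mask: np.ndarray | None = None) -> WeightSet:
    """Slice weights from a two-component Bayesian Gaussian mixture.

    Per shell, the log-transformed slice RMSE between the acquired and
    predicted series is modeled by a two-component Bayesian GMM; the
    posterior probability of the lower-mean (inlier) component is the
    slice weight.  Shells with fewer than 4 slices, or with a degenerate
    single cluster, fall back to all-ones weights.
    """
    scheme = scheme if scheme is not None else series.scheme
    pred = np.asarray(predicted_series, dtype=float)
    if pred.shape != series.intensities.shape:
        raise ValueError("predicted series shape mismatch")
    rmse = _slice_rmse(series.intensities, pred, mask)  # (Z, N)
    w = np.ones_like(rmse)
    for vols in _shell_groups(scheme):
        eps = rmse[:, vols].ravel()
        valid = eps > 0
        if valid.sum() < 4:
            log.info("shell with < 4 informative slices; weights left at 1")
            continue
        x = np.log(eps[valid])[:, None]
        if np.ptp(x) < 1e-8:
            continue  # single degenerate cluster: all inliers
        gmm = BayesianGaussianMixture(
            n_components=2,
            weight_concentration_prior=1e-2,
            max_iter=200,
            reg_covar=1e-6,
            random_state=seed,
        ).fit(x)
        means = gmm.means_.ravel()
        if np.ptp(means) < 1e-12:
            continue  # components merged: no outlier class
        inlier = int(np.argmin(means))
        post = gmm.predict_proba(x)[:, inlier]
        ws = np.ones_like(eps)
        ws[valid] = post
        w[:, vols] = ws.reshape(rmse[:, vols].shape)
    return WeightSet(np.clip(w, 0.0, 1.0), method="gmm")


def voxel_weights(series: DWISeries, predicted_series: np.ndarray,
                  mask: np.ndarray | None = None) -> WeightSet:
    """Voxel-wise weights w = 1/(z^2 + 1)^2 from standardized residuals.

    z is the residual (acquired - predicted) standardized per volume by
    1.4826 * MAD of the residuals over the brain voxels.  A volume with
    MAD = 0 keeps all voxel weights at 1.
    """
    pred = np.asarray(predicted_series, dtype=float)
    data = series.intensities
    if pred.shape != data.shape:
        raise ValueError("predicted series shape mismatch")
    resid = data - pred
    n_vol = data.shape[3]
    w = np.ones_like(data)
    for v in range(n_vol):
        r = resid[..., v]
        rs = r[mask.astype(bool)] if mask is not None else r.ravel()
        mad = np.median(np.abs(rs - np.median(rs)))
        if mad == 0:
            log.info("volume %d residual MAD = 0; voxel weights left at 1", v)
            continue
        z = r / (_MAD_SCALE * mad)
        w[..., v] = 1.0 / (z * z + 1.0) ** 2
    slice_w = np.ones((data.shape[2], n_vol))
    return WeightSet(slice_w, voxel_weights=w, method="voxel")
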