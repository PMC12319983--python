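"""Quantitative scoring: SSIM, PSNR and motion-trace error summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from .gradients import euler_to_matrix

__all__ = ["ssim", "ssim_slicewise", "psnr", "trace_error", "EvalReport"]


def ssim(image_a: np.ndarray, image_b: np.ndarray,
         data_range: float | None = None) -> float:
    """Structural similarity between two images of the same shape.

    Standard constants (K1 = 0.01, K2 = 0.03) and a 7-voxel window; the
    dynamic range defaults to the joint range of the pair.  Symmetric in
    its arguments; 1 iff the images are identical.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    return float(structural_similarity(
        a, b, data_range=data_range, win_size=7,
        gaussian_weights=False, K1=0.01, K2=0.03,
    ))


def ssim_slicewise(vol_a: np.ndarray, vol_b: np.ndarray,
                   axis: int = 2) -> np.ndarray:
    """Per-slice SSIM along ``axis`` with a shared dynamic range."""
    a = np.asarray(vol_a, dtype=float)
    b = np.asarray(vol_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    rng = hi - lo if hi > lo else 1.0
    a = np.moveaxis(a, axis, 0)
    b = np.moveaxis(b, axis, 0)
    return np.array([ssim(sa, sb, data_range=rng) for sa, sb in zip(a, b)])


def psnr(image_a: np.ndarray, image_b: np.ndarray,
         data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; identical images report inf."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if np.array_equal(a, b):
        return float("inf")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(peak_signal_noise_ratio(a, b, data_range=data_range))


@dataclass
class EvalReport:
    """Per-volume motion-trace errors with summary statistics."""

    translation_error_mm: np.ndarray
    rotation_error_deg: np.ndarray

    @property
    def median_translation(self) -> float:
        return float(np.median(self.translation_error_mm))

    @property
    def median_rotation(self) -> float:
        return float(np.median(self.rotation_error_deg))

    def summary(self) -> dict:
        t, r = self.translation_error_mm, self.rotation_error_deg
        q = lambda x: (float(np.percentile(x, 25)),
                       float(np.percentile(x, 75)))
        return {
            "translation_median_mm": float(np.median(t)),
            "translation_iqr_mm": q(t),
            "rotation_median_deg": float(np.median(r)),
            "rotation_iqr_deg": q(r),
        }


def trace_error(true_trace, estimated_trace) -> EvalReport:
    """Per-volume trace errors.

    Translation error is the Euclidean norm of the translation
    difference (mm); rotation error is the geodesic angle of
    R_true R_est^T (degrees).
    """
    pt = np.asarray(true_trace.params, dtype=float)
    pe = np.asarray(estimated_trace.params, dtype=float)
    if pt.shape != pe.shape:
        raise ValueError(
            f"trace lengths differ: {pt.shape[0]} vs {pe.shape[0]}"
        )
    terr = np.linalg.norm(pt[:, :3] - pe[:, :3], axis=1)
    rerr = np.empty(pt.shape[0])
    for v in range(pt.shape[0]):
        Rt = euler_to_matrix(*pt[v, 3:])
        Re = euler_to_matrix(*pe[v, 3:])
        rerr[v] = np.degrees(
            np.linalg.norm(Rotation.from_matrix(Rt @ Re.T).as_rotvec())
        )
    return EvalReport(terr, rerr)
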