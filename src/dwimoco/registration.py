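"""Rigid volume resampling and registration.

Transforms are parameterized as (tx, ty, tz) in mm and (rx, ry, rz) Euler
angles in degrees, intrinsic z-y-x order, rotating about the image center.
Registration maximizes global normalized cross-correlation over the six
parameters with a coarse-to-fine multiresolution pyramid and a
derivative-free (Powell) local optimizer; it is deterministic for fixed
settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .gradients import euler_to_matrix

__all__ = ["apply_rigid", "rigid_register", "RegistrationSettings"]

_ORDERS = {"nearest": 0, "trilinear": 1, "quadratic-spline": 2,
           "cubic-spline": 3}


def _matrix_offset(mu, shape, voxel_size, inverse=False):
    """Voxel-space matrix/offset for ndimage.affine_transform.

    The forward map moves the object: T(x) = R (x - c) + c + t in mm
    about the image center c.  Resampling needs the inverse map from
    output to input coordinates.
    """
    mu = np.asarray(mu, dtype=float)
    t = mu[:3]
    R = euler_to_matrix(mu[3], mu[4], mu[5])
    S = np.diag(voxel_size)
    Sinv = np.diag(1.0 / np.asarray(voxel_size, dtype=float))
    c = (np.asarray(shape, dtype=float) - 1.0) / 2.0 * voxel_size
    if inverse:
        # sample input at T(x): matrix maps output voxel -> input voxel
        A = Sinv @ R @ S
        b = Sinv @ (c + t - R @ c)
    else:
        A = Sinv @ R.T @ S
        b = Sinv @ (c - R.T @ (c + t))
    return A, b


def apply_rigid(volume: np.ndarray, mu, interpolation: str = "trilinear",
                voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Resample a 3D volume under the rigid map about the image center.

    ``mu`` = (tx, ty, tz, rx, ry, rz) moves the object by t (mm) after
    rotating it by R about the center; out-of-field voxels are 0.
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    vol = np.asarray(volume, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if not mu.any():
        return vol.copy()
    A, b = _matrix_offset(mu, vol.shape, np.asarray(voxel_size, dtype=float))
    return ndimage.affine_transform(
        vol, A, offset=b, order=_ORDERS[interpolation],
        mode="constant", cval=0.0, prefilter=interpolation == "cubic-spline",
    )


@dataclass
class RegistrationSettings:
    """Multiresolution NCC registration settings.

    Powell alone has a limited capture range; when ``global_search`` is
    on, the coarsest level is first scanned over a deterministic grid of
    Euler angles (translation initialized from the intensity centroids)
    and the best candidate — the supplied ``init`` competes — seeds the
    local optimization.
    """

    pyramid_factors: tuple = (4, 2, 1)
    smooth_sigmas: tuple = (2.0, 1.0, 0.0)
    xtol: float = 0.005
    ftol: float = 1e-6
    #: Powell iteration budget; an int applies to every pyramid level,
    #: a tuple sets one budget per level
    maxiter: int | tuple = 12
    #: metric interpolation; a string applies to every level, a tuple
    #: sets one mode per level (cubic gives a smoother cost surface)
    interpolation: str | tuple = ("trilinear", "trilinear",
                                  "cubic-spline")
    #: parameter bounds (mm, degrees); exceeding them flags divergence
    bounds: tuple = (50.0, 60.0)
    init: tuple = (0.0,) * 6
    global_search: bool = True
    #: Euler-angle grid (degrees per axis) for the coarse search
    rot_grid: tuple = (-30.0, -15.0, 0.0, 15.0, 30.0)


def _pyramid(vol, factor, sigma):
    if sigma > 0:
        vol = ndimage.gaussian_filter(vol, sigma)
    if factor > 1:
        sl = tuple(slice(None, None, factor) for _ in range(3))
        vol = vol[sl]
    return vol


def _ncc(a, b):
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b) / (na * nb)


def _support_crop(vol, margin=3):
    """Bounding box of the image support (above 2% of max), with margin."""
    thresh = 0.02 * vol.max()
    nz = np.argwhere(vol > thresh)
    if nz.size == 0:
        return np.zeros(3), vol
    lo = np.maximum(nz.min(axis=0) - margin, 0)
    hi = np.minimum(nz.max(axis=0) + margin + 1, vol.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return lo.astype(float), vol[sl]


def _centroid_mm(vol, voxel_size):
    total = vol.sum()
    if total <= 0:
        return np.zeros(3)
    idx = np.indices(vol.shape, dtype=float)
    return np.array([
        (idx[k] * vol).sum() / total * voxel_size[k] for k in range(3)
    ])


def _coarse_search(moving, fixed, init, settings, voxel_size):
    """Seed the optimizer: centroid translation + Euler-angle grid scan
    at the coarsest pyramid level; the supplied init competes."""
    factor = settings.pyramid_factors[0]
    sigma = settings.smooth_sigmas[0]
    mov = _pyramid(moving, factor, sigma)
    fix = _pyramid(fixed, factor, sigma)
    vs = np.asarray(voxel_size, dtype=float) * factor
    t0 = _centroid_mm(fix, vs) - _centroid_mm(mov, vs)
    candidates = [np.asarray(init, dtype=float)]
    grid = settings.rot_grid
    for rx in grid:
        for ry in grid:
            for rz in grid:
                candidates.append(
                    np.array([t0[0], t0[1], t0[2], rx, ry, rz])
                )
    best, best_cost = candidates[0], np.inf
    for cand in candidates:
        res = apply_rigid(mov, cand, "trilinear", vs)
        cost = -_ncc(res, fix)
        if cost < best_cost:
            best, best_cost = cand, cost
    return best.copy()


def rigid_register(moving: np.ndarray, fixed: np.ndarray,
                   settings: RegistrationSettings | None = None,
                   voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Returns mu such that ``apply_rigid(moving, mu)`` maximizes the global
    normalized cross-correlation with ``fixed``.  Both volumes must share
    grid geometry.
    """
    settings = settings or RegistrationSettings()
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed volumes must share a grid")
    if moving.std() == 0 or fixed.std() == 0:
        raise ValueError("cannot register a flat (zero-variance) image")
    voxel_size = np.asarray(voxel_size, dtype=float)

    mu = np.asarray(settings.init, dtype=float).copy()
    if settings.global_search:
        mu = _coarse_search(moving, fixed, mu, settings, voxel_size)
    n_levels = len(settings.pyramid_factors)
    maxiters = settings.maxiter if isinstance(settings.maxiter, (tuple, list)) \
        else (settings.maxiter,) * n_levels
    interps = settings.interpolation \
        if isinstance(settings.interpolation, (tuple, list)) \
        else (settings.interpolation,) * n_levels
    for factor, sigma, maxiter, interp in zip(
        settings.pyramid_factors, settings.smooth_sigmas, maxiters,
        interps,
    ):
        mov = _pyramid(moving, factor, sigma)
        fix = _pyramid(fixed, factor, sigma)
        order = _ORDERS[interp]
        if order > 1:
            mov = ndimage.spline_filter(mov, order=order)
        vs = voxel_size * factor
        origin, fix_crop = _support_crop(fix, margin=3)

        def cost(p):
            A, b = _matrix_offset(p, mov.shape, vs)
            res = ndimage.affine_transform(
                mov, A, offset=b + A @ origin,
                output_shape=fix_crop.shape, order=order,
                mode="constant", cval=0.0, prefilter=False,
            )
            return -_ncc(res, fix_crop)

        res = optimize.minimize(
            cost, mu, method="Powell",
            options={
                "xtol": settings.xtol,
                "ftol": settings.ftol,
                "maxiter": maxiter,
            },
        )
        mu = res.x
    return mu
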