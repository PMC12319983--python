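"""Synthetic multi-shell diffusion phantom with known ground truth.

The phantom stands in for a fetal brain at desk scale: an ellipsoidal
"brain" containing an isotropic (CSF-like) core, two coherent
single-fiber regions and a crossing-fiber region, each voxel carrying one
or two diffusion tensors with volume fractions.  The simulator then
applies, per volume: the ground-truth rigid motion (signal evaluated on
the motion-rotated encoding direction, volume resampled rigidly), slice
dropouts (multiplicative attenuation from a motion-during-encoding
event), spin-history hyperintense slices (multiplicative gain), Rician
noise (magnitude of a complex Gaussian perturbation), and optionally an
opposed-blip susceptibility distortion pair.

Everything is deterministic for a fixed seed, and the clean motion-free
series is returned alongside so every downstream module can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientScheme, euler_to_matrix
from .io import DWISeries
from .registration import apply_rigid

__all__ = [
    "PhantomSpec",
    "CorruptionSpec",
    "TensorField",
    "make_phantom",
    "simulate_series",
    "simulate_blip_pair",
    "burst_motion_trace",
]

# typical diffusivities, mm^2/s
_LAMBDA_FIBER = (1.7e-3, 0.3e-3, 0.3e-3)
_LAMBDA_ISO = 1.0e-3
_LAMBDA_CSF = 2.8e-3


@dataclass
class PhantomSpec:
    """Geometry and tissue model of the synthetic phantom."""

    shape: tuple = (32, 32, 32)
    voxel_size: tuple = (2.5, 2.5, 2.5)
    s0: float = 100.0
    background: float = 0.0
    with_crossing: bool = True
    seed: int = 0


@dataclass
class TensorField:
    """Per-voxel multi-tensor model: up to two tensors with fractions."""

    tensors: np.ndarray      # (X, Y, Z, 2, 3, 3)
    fractions: np.ndarray    # (X, Y, Z, 2), rows sum to 1
    s0: np.ndarray           # (X, Y, Z)
    mask: np.ndarray         # (X, Y, Z) bool, brain support
    voxel_size: np.ndarray
    regions: np.ndarray      # integer region labels

    def signal(self, b: float, direction: np.ndarray) -> np.ndarray:
        """Multi-tensor forward signal S0 * sum_k f_k exp(-b u^T D_k u)."""
        u = np.asarray(direction, dtype=float)
        if b == 0 or not u.any():
            return self.s0.copy()
        att = np.einsum("...kij,i,j->...k", self.tensors, u, u)
        return self.s0 * np.sum(
            self.fractions * np.exp(-b * att), axis=-1
        )


def _tensor(evals, axis) -> np.ndarray:
    """Diagonalizable tensor with principal eigenvector along ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # complete an orthonormal frame
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(axis, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axis, e2)
    V = np.column_stack([axis, e2, e3])
    return V @ np.diag(evals) @ V.T


def make_phantom(spec: PhantomSpec) -> TensorField:
    """Build the deterministic tensor-field phantom.

    Raises on non-positive eigenvalues (guarded by construction here, but
    enforced for custom diffusivities).
    """
    for lam in (*_LAMBDA_FIBER, _LAMBDA_ISO, _LAMBDA_CSF):
        if lam <= 0:
            raise ValueError("diffusion eigenvalues must be positive")
    nx, ny, nz = spec.shape
    vs = np.asarray(spec.voxel_size, dtype=float)
    idx = np.indices(spec.shape, dtype=float)
    center = (np.asarray(spec.shape, dtype=float) - 1) / 2.0
    # asymmetric ellipsoid so rigid pose is identifiable from any contrast
    semi = (0.30, 0.26, 0.22)
    rel = [(idx[k] - center[k]) / (semi[k] * spec.shape[k])
           for k in range(3)]
    r2 = rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2
    brain = r2 <= 1.0

    def blob(cx, cy, cz, a, b_, c_):
        return ((rel[0] - cx) ** 2 / a ** 2
                + (rel[1] - cy) ** 2 / b_ ** 2
                + (rel[2] - cz) ** 2 / c_ ** 2) <= 1.0

    regions = np.zeros(spec.shape, dtype=int)
    regions[brain] = 1                               # isotropic parenchyma
    # two CSF-filled ventricle-like cavities, deliberately unequal
    core = brain & (blob(-0.18, 0.12, 0.05, 0.22, 0.16, 0.14)
                    | blob(0.24, 0.10, -0.02, 0.14, 0.10, 0.10))
    regions[core] = 2
    fiber_x = brain & (rel[1] > 0.3) & ~core         # coherent along x
    regions[fiber_x] = 3
    fiber_y = brain & (rel[1] < -0.3) & ~core        # coherent along y
    regions[fiber_y] = 4
    if spec.with_crossing:
        crossing = brain & (np.abs(rel[1]) <= 0.3) & (rel[0] > 0.3) & ~core
        regions[crossing] = 5

    iso = np.eye(3) * _LAMBDA_ISO
    csf = np.eye(3) * _LAMBDA_CSF
    dx = _tensor(_LAMBDA_FIBER, [1, 0, 0])
    dy = _tensor(_LAMBDA_FIBER, [0, 1, 0])

    tensors = np.zeros(spec.shape + (2, 3, 3))
    fractions = np.zeros(spec.shape + (2,))
    tensors[..., 0, :, :] = iso
    fractions[..., 0] = 1.0
    for label, (t0, t1, f0) in {
        2: (csf, csf, 1.0),
        3: (dx, dx, 1.0),
        4: (dy, dy, 1.0),
        5: (dx, dy, 0.5),
    }.items():
        sel = regions == label
        tensors[sel, 0] = t0
        tensors[sel, 1] = t1
        fractions[sel, 0] = f0
        fractions[sel, 1] = 1.0 - f0

    rng = np.random.default_rng(spec.seed)
    s0 = np.full(spec.shape, spec.background, dtype=float)
    # region-dependent proton density / T2 weighting plus a smooth
    # texture, so every contrast carries pose information
    texture = rng.standard_normal(spec.shape)
    from scipy.ndimage import gaussian_filter

    texture = gaussian_filter(texture, 1.5)
    texture = 1.0 + 0.12 * texture / max(np.abs(texture).max(), 1e-12)
    level = {1: 1.0, 2: 1.5, 3: 0.8, 4: 0.9, 5: 0.75}
    for label, lv in level.items():
        sel = regions == label
        s0[sel] = spec.s0 * lv * texture[sel]

    return TensorField(tensors, fractions, s0, brain, vs, regions)


@dataclass
class CorruptionSpec:
    """Ground-truth corruption applied to the clean series."""

    #: (N, 6) per-volume rigid parameters (tx,ty,tz mm, rx,ry,rz deg)
    motion: np.ndarray | None = None
    #: list of (volume, slice, attenuation in (0,1))
    dropouts: list = field(default_factory=list)
    #: list of (volume, slice, gain > 1) spin-history hyperintensities
    hyperintense: list = field(default_factory=list)
    sigma: float = 0.0
    #: optional smooth off-resonance field in Hz for blip-pair simulation
    fieldmap: np.ndarray | None = None
    #: displacement per Hz along the phase-encode axis, voxels
    readout_scale: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for _, _, a in self.dropouts:
            if not 0 < a < 1:
                raise ValueError("dropout attenuation must be in (0, 1)")
        for _, _, g in self.hyperintense:
            if g <= 1:
                raise ValueError("spin-history gain must exceed 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def burst_motion_trace(n_volumes: int, n_bursts: int = 3,
                       max_translation: float = 20.0,
                       max_rotation: float = 24.0,
                       seed: int = 0) -> np.ndarray:
    """Piecewise-constant motion: transient bursts over a quiet baseline.

    Emulates a fetus that rests near a baseline pose and repositions
    abruptly for short stretches before settling back — the excursion-
    and-return pattern typical of observed fetal motion traces, which
    also leaves a substantial portion of the data unaffected by motion
    (the working assumption of outlier-weighted reconstruction).
    Translations are bounded by ``max_translation`` (mm) and rotations
    by ``max_rotation`` (degrees) per axis; each burst pose is drawn
    from the upper half of those ranges so bursts exercise them.
    """
    rng = np.random.default_rng(seed)
    trace = np.zeros((n_volumes, 6))
    burst_len = max(3, n_volumes // (4 * n_bursts))
    starts = np.sort(rng.choice(
        np.arange(2, n_volumes - burst_len),
        size=n_bursts, replace=False,
    ))
    for s in starts:
        sign = rng.choice([-1.0, 1.0], size=6)
        t = sign[:3] * rng.uniform(0.4, 1.0, 3) * max_translation
        r = sign[3:] * rng.uniform(0.4, 1.0, 3) * max_rotation
        trace[s:s + burst_len] = np.concatenate([t, r])
    # small residual jitter around every pose
    trace[1:] += rng.normal(0, 0.15, (n_volumes - 1, 6))
    return np.clip(
        trace,
        [-max_translation] * 3 + [-max_rotation] * 3,
        [max_translation] * 3 + [max_rotation] * 3,
    )


def simulate_series(phantom: TensorField, scheme: GradientScheme,
                    corruption: CorruptionSpec | None = None):
    """Forward-simulate an acquisition; returns (series, ground_truth).

    Per volume: the multi-tensor signal is evaluated on the motion-rotated
    encoding direction (the object sees R^T u), the volume is moved
    rigidly by mu_v, slice corruptions are applied, and Rician noise is
    formed as |S + n1 + i n2| with n ~ N(0, sigma).  The ground-truth
    bundle carries the clean motion-free series, the trace, and the
    corrupted-slice bookkeeping.
    """
    corruption = corruption or CorruptionSpec()
    n = len(scheme)
    motion = corruption.motion
    if motion is not None and np.asarray(motion).shape != (n, 6):
        raise ValueError("motion trace must be (n_volumes, 6)")
    rng = np.random.default_rng(corruption.seed)

    clean = np.empty(phantom.s0.shape + (n,))
    moved = np.empty_like(clean)
    for v in range(n):
        b = scheme.b_values[v]
        u = scheme.directions[v]
        clean[..., v] = phantom.signal(b, u)
        if motion is None or not np.asarray(motion[v]).any():
            moved[..., v] = clean[..., v]
        else:
            mu = np.asarray(motion[v], dtype=float)
            R = euler_to_matrix(mu[3], mu[4], mu[5])
            sig = phantom.signal(b, R.T @ u)
            moved[..., v] = apply_rigid(
                sig, mu, "trilinear", phantom.voxel_size
            )

    for v, s, a in corruption.dropouts:
        moved[:, :, s, v] *= a
    for v, s, g in corruption.hyperintense:
        moved[:, :, s, v] *= g

    if corruption.sigma > 0:
        n1 = rng.normal(0, corruption.sigma, moved.shape)
        n2 = rng.normal(0, corruption.sigma, moved.shape)
        moved = np.sqrt((moved + n1) ** 2 + n2 ** 2)

    affine = np.diag(list(phantom.voxel_size) + [1.0])
    series = DWISeries(np.maximum(moved, 0.0), affine, scheme)
    truth = {
        "clean": np.maximum(clean, 0.0),
        "trace": np.zeros((n, 6)) if motion is None else np.asarray(motion),
        "dropouts": list(corruption.dropouts),
        "hyperintense": list(corruption.hyperintense),
        "sigma": corruption.sigma,
        "mask": phantom.mask,
    }
    return series, truth


def simulate_blip_pair(volume: np.ndarray, fieldmap: np.ndarray,
                       pe_axis: int = 1, readout_scale: float = 1.0):
    """Warp a volume into an opposed-blip distortion pair.

    Voxels are displaced along the phase-encode axis by +d and -d with
    d = fieldmap * readout_scale (voxels), using mass-preserving linear
    splatting, so stretching in one blip appears as pile-up in the other.
    """
    vol = np.asarray(volume, dtype=float)
    fmap = np.asarray(fieldmap, dtype=float)
    if fmap.shape != vol.shape:
        raise ValueError("fieldmap must match the volume grid")
    disp = fmap * readout_scale
    half_fov = vol.shape[pe_axis] / 2.0
    if np.max(np.abs(disp)) > half_fov:
        raise ValueError("displacement exceeds half the field of view")

    def warp(sign):
        out = np.zeros_like(vol)
        n = vol.shape[pe_axis]
        moved = np.moveaxis(vol, pe_axis, -1)
        d = np.moveaxis(disp, pe_axis, -1)
        res = np.zeros_like(moved)
        pos = np.arange(n)[None, None, :] + sign * d
        lo = np.floor(pos).astype(int)
        frac = pos - lo
        flat = moved.reshape(-1, n)
        posf = lo.reshape(-1, n)
        fracf = frac.reshape(-1, n)
        resf = res.reshape(-1, n)
        rows = np.arange(flat.shape[0])[:, None].repeat(n, axis=1)
        for shift, wgt in ((0, 1.0 - fracf), (1, fracf)):
            tgt = posf + shift
            ok = (tgt >= 0) & (tgt < n)
            np.add.at(
                resf, (rows[ok], tgt[ok]), flat[ok] * wgt[ok]
            )
        out = np.moveaxis(resf.reshape(moved.shape), -1, pe_axis)
        return out

    return warp(+1), warp(-1)
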