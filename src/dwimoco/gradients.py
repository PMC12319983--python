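"""Gradient tables for multi-shell diffusion acquisitions.

A :class:`GradientScheme` binds the per-volume b-values (s/mm^2), unit
encoding directions, the temporal acquisition order and the phase-encode
axis.  Directions are stored in the image coordinate frame (the FSL bvec
convention); the MRtrix 4-column dialect is converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GradientScheme",
    "B0_THRESHOLD",
    "read_gradients",
    "write_gradients",
    "rotate_gradient_table",
]

#: b-values below this (s/mm^2) count as unweighted; scanners report small
#: nonzero values on nominally b=0 volumes.
B0_THRESHOLD = 50.0

_UNIT_TOL = 1e-3


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume diffusion encoding for a whole acquisition.

    Parameters
    ----------
    b_values : (N,) array
        Diffusion weighting per volume in s/mm^2.
    directions : (N, 3) array
        Unit encoding directions in the image frame; rows may be zero only
        where the b-value is below :data:`B0_THRESHOLD`.
    temporal_order : (N,) array of int, optional
        Permutation mapping acquisition slot -> volume index.  Defaults to
        the identity (volumes stored in acquisition order).
    pe_axis : str
        Phase-encode axis label ("x", "y" or "z").
    """

    b_values: np.ndarray
    directions: np.ndarray
    temporal_order: np.ndarray = field(default=None)  # type: ignore[assignment]
    pe_axis: str = "y"

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float).ravel()
        d = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if b.shape[0] != d.shape[0]:
            raise ValueError(
                f"{b.shape[0]} b-values but {d.shape[0]} directions"
            )
        if np.any(b < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(d, axis=1)
        dw = b >= B0_THRESHOLD
        if np.any(norms[dw] == 0):
            raise ValueError("zero direction on a diffusion-weighted volume")
        if np.any(np.abs(norms[dw] - 1.0) > _UNIT_TOL):
            warnings.warn(
                "non-unit b-vectors on weighted volumes; renormalizing",
                stacklevel=2,
            )
        d = d.copy()
        d[dw] /= norms[dw, None]
        d[~dw] = 0.0
        order = self.temporal_order
        if order is None:
            order = np.arange(b.shape[0])
        order = np.asarray(order, dtype=int).ravel()
        if sorted(order.tolist()) != list(range(b.shape[0])):
            raise ValueError("temporal_order is not a permutation")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "temporal_order", order)

    def __len__(self) -> int:
        return int(self.b_values.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask of unweighted (b=0) volumes."""
        return self.b_values < B0_THRESHOLD

    @property
    def shells(self) -> list[float]:
        """Sorted unique nonzero shell b-values."""
        return sorted(set(np.round(self.b_values[~self.b0_mask], 6)))

    def shell_mask(self, b: float, rtol: float = 0.05) -> np.ndarray:
        """Mask of volumes belonging to the shell at b (within ``rtol``)."""
        return np.abs(self.b_values - b) <= rtol * max(b, 1.0)

    @property
    def q_points(self) -> np.ndarray:
        """(N, 3) q-space sample points under the q = sqrt(b) * u mapping."""
        return np.sqrt(self.b_values)[:, None] * self.directions

    def in_temporal_order(self) -> "GradientScheme":
        """Return the scheme with volumes permuted into acquisition order."""
        o = self.temporal_order
        return GradientScheme(
            self.b_values[o], self.directions[o], None, self.pe_axis
        )


def read_gradients(paths, dialect: str) -> GradientScheme:
    """Read a gradient table.

    ``dialect="fsl"`` expects ``(bval_path, bvec_path)``; ``"mrtrix"``
    expects a single N x 4 ``x y z b`` file (as a 1-tuple or str).
    """
    if dialect == "fsl":
        bval_path, bvec_path = paths
        b = np.loadtxt(bval_path, dtype=float).ravel()
        vec = np.loadtxt(bvec_path, dtype=float)
        if vec.ndim == 1:
            vec = vec.reshape(3, -1)
        if vec.shape[0] != 3:
            vec = vec.T
        return GradientScheme(b, vec.T)
    if dialect == "mrtrix":
        path = paths[0] if isinstance(paths, (tuple, list)) else paths
        grad = np.atleast_2d(np.loadtxt(path, dtype=float, comments="#"))
        if grad.shape[1] != 4:
            raise ValueError("MRtrix grad file must have 4 columns")
        return GradientScheme(grad[:, 3], grad[:, :3])
    raise ValueError(f"unknown gradient dialect {dialect!r}")


def write_gradients(scheme: GradientScheme, paths, dialect: str) -> None:
    """Write ``scheme`` as an FSL bval/bvec pair or an MRtrix grad file."""
    if dialect == "fsl":
        bval_path, bvec_path = paths
        np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6f")
        np.savetxt(bvec_path, scheme.directions.T, fmt="%.10f")
    elif dialect == "mrtrix":
        path = paths[0] if isinstance(paths, (tuple, list)) else paths
        grad = np.column_stack([scheme.directions, scheme.b_values])
        np.savetxt(path, grad, fmt="%.10f")
    else:
        raise ValueError(f"unknown gradient dialect {dialect!r}")


def euler_to_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix for intrinsic z-y-x Euler angles in degrees."""
    return Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()


def rotate_gradient_table(scheme: GradientScheme, trace) -> GradientScheme:
    """Rotate each direction by the rotation component of its volume's
    rigid transform: u_v -> R(mu_v) u_v.

    b-values and temporal order are unchanged.  ``trace`` is a
    :class:`~dwimoco.model.MotionTrace` (or anything with a
    ``rotation_matrices()`` method returning (N, 3, 3)).
    """
    mats = np.asarray(trace.rotation_matrices())
    if mats.shape != (len(scheme), 3, 3):
        raise ValueError(
            f"trace has {mats.shape[0]} transforms for {len(scheme)} volumes"
        )
    dets = np.linalg.det(mats)
    ortho = np.einsum("vij,vkj->vik", mats, mats)
    eye = np.eye(3)
    if np.any(np.abs(dets - 1.0) > 1e-6) or np.any(
        np.abs(ortho - eye) > 1e-6
    ):
        raise ValueError("non-orthonormal rotation matrix in motion trace")
    new_dirs = np.einsum("vij,vj->vi", mats, scheme.directions)
    return replace(scheme, directions=new_dirs)
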