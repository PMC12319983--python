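"""Reading and writing the formats the pipeline touches.

Images are NIfTI-1 (gzipped or plain) via nibabel; gradient tables are
FSL bval/bvec pairs or MRtrix 4-column files; motion traces and slice
weights are TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .gradients import GradientScheme, read_gradients, write_gradients

__all__ = [
    "DWISeries",
    "read_dwi",
    "write_dwi",
    "write_motion_trace",
    "read_motion_trace",
    "write_slice_weights",
    "read_slice_weights",
]


@dataclass
class DWISeries:
    """A 4D diffusion-weighted series bound to its gradient scheme.

    Attributes
    ----------
    intensities : (X, Y, Z, N) array
        Non-negative signal intensities, arbitrary units.
    affine : (4, 4) array
        Voxel-to-world map.
    scheme : GradientScheme
        One entry per volume; ``len(scheme)`` must equal N.
    """

    intensities: np.ndarray
    affine: np.ndarray
    scheme: GradientScheme

    def __post_init__(self):
        data = np.asarray(self.intensities, dtype=float)
        if data.ndim != 4:
            raise ValueError("intensities must be 4D (x, y, z, volume)")
        if data.shape[3] != len(self.scheme):
            raise ValueError(
                f"{data.shape[3]} volumes but scheme has "
                f"{len(self.scheme)} entries"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite intensities")
        if np.any(data < 0):
            raise ValueError("negative intensities")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be strictly positive")
        self.intensities = data
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        aff = np.asarray(self.affine, dtype=float)
        return np.linalg.norm(aff[:3, :3], axis=0)

    @property
    def shape(self):
        return self.intensities.shape

    def volume(self, v: int) -> np.ndarray:
        return self.intensities[..., v]


def read_dwi(image_path, gradient_paths, dialect: str = "fsl") -> DWISeries:
    """Read a 4D NIfTI plus its gradient table into a :class:`DWISeries`.

    Raises a ValueError naming both counts if the number of volumes does
    not match the gradient table length.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got {data.ndim}D")
    scheme = read_gradients(gradient_paths, dialect)
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"image has {data.shape[3]} volumes but gradient table has "
            f"{len(scheme)} entries"
        )
    return DWISeries(data, img.affine, scheme)


def write_dwi(series: DWISeries, image_path, gradient_paths,
              dialect: str = "fsl") -> None:
    """Write a series as NIfTI-1 plus gradient files readable by
    :func:`read_dwi`."""
    if series.intensities.size == 0:
        raise ValueError("refusing to write an empty series")
    img = nib.Nifti1Image(
        np.asarray(series.intensities, dtype=np.float32), series.affine
    )
    nib.save(img, str(image_path))
    write_gradients(series.scheme, gradient_paths, dialect)


def write_motion_trace(trace, path) -> None:
    """Serialize per-volume rigid parameters to TSV.

    Columns: volume, tx, ty, tz (mm), rx, ry, rz (degrees); values
    round-trip losslessly at 6 decimals.
    """
    params = np.asarray(trace.params, dtype=float)
    df = pd.DataFrame(
        params, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
    )
    df.insert(0, "volume", np.arange(params.shape[0]))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_motion_trace(path):
    from .model import MotionTrace

    df = pd.read_csv(path, sep="\t")
    return MotionTrace(df[["tx", "ty", "tz", "rx", "ry", "rz"]].to_numpy())


def write_slice_weights(slice_weights: np.ndarray, path) -> None:
    """Write per-(slice, volume) weights as a TSV table (rows = slices)."""
    w = np.asarray(slice_weights, dtype=float)
    df = pd.DataFrame(
        w, columns=[f"vol{v}" for v in range(w.shape[1])]
    )
    df.insert(0, "slice", np.arange(w.shape[0]))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_slice_weights(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=["slice"]).to_numpy(dtype=float)
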