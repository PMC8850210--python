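"""Core grid-aligned domain containers and NIfTI I/O.

All volumes live in a common "atlas space": a regular 3D grid with voxel
spacing in millimetres and a declared midsagittal mirror plane. The mirror
plane is always the mid-plane of one grid axis (``mirror_axis``), which
requires an even extent along that axis so that left/right reflection is a
bijection on voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "AlignmentError",
    "IntensityVolume",
    "LesionMask",
    "Parcellation",
    "voxel_volume_mL",
    "save_nifti",
    "load_nifti",
]

RELEVANCE_CLASSES = ("high", "moderate", "low", "unclassified")


class GeometryError(ValueError):
    """Raised when a grid violates a geometric requirement (e.g. odd mirror extent)."""


class AlignmentError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def voxel_volume_mL(spacing: Tuple[float, float, float]) -> float:
    """Volume of one voxel in millilitres (spacing is in mm; 1000 mm^3 = 1 mL)."""
    dx, dy, dz = spacing
    return dx * dy * dz / 1000.0


def _check_even_mirror(shape, mirror_axis: int) -> None:
    if shape[mirror_axis] % 2 != 0:
        raise GeometryError(
            f"extent {shape[mirror_axis]} along mirror axis {mirror_axis} is odd; "
            "pad the volume to an even extent so reflection is a voxel bijection"
        )


@dataclass
class IntensityVolume:
    """3D scalar grid standing in for a trace-DWI acquisition.

    Parameters
    ----------
    values : ndarray
        Nonnegative intensities; zero outside ``brain_mask``.
    spacing : tuple of float
        Voxel spacing (dx, dy, dz) in mm.
    brain_mask : ndarray of bool
        Brain (foreground) voxels.
    mirror_axis : int
        Grid axis across whose mid-plane left/right reflection is defined.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float]
    brain_mask: np.ndarray
    mirror_axis: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.values.ndim != 3:
            raise GeometryError("intensity grid must be 3D")
        if self.values.shape != self.brain_mask.shape:
            raise AlignmentError("brain mask and intensity grid shapes differ")
        _check_even_mirror(self.values.shape, self.mirror_axis)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape


@dataclass
class LesionMask:
    """Binary lesion grid; the follow-up infarct volume (FIV) is voxel count x voxel volume."""

    values: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise GeometryError("lesion mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mL(self) -> float:
        return self.n_voxels * voxel_volume_mL(self.spacing)


@dataclass
class Parcellation:
    """Integer label grid plus a region table.

    ``labels`` uses 0 for background/non-brain; each nonzero id names one
    anatomical region. ``regions`` holds one row per region with columns
    ``region_id``, ``name``, ``hemisphere`` and ``relevance``
    (high/moderate/low/unclassified).
    """

    labels: np.ndarray
    spacing: Tuple[float, float, float]
    regions: pd.DataFrame
    mirror_axis: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise GeometryError("parcellation labels must be an integer grid")
        _check_even_mirror(self.labels.shape, self.mirror_axis)
        grid_ids = set(np.unique(self.labels)) - {0}
        table_ids = set(self.regions["region_id"].astype(int))
        if grid_ids - table_ids:
            missing = sorted(grid_ids - table_ids)[:5]
            raise ValueError(f"region ids present in grid but absent from table: {missing}")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["region_id"].to_numpy(dtype=int)

    def relevance_map(self) -> dict:
        """region_id -> relevance class from the region table."""
        return dict(zip(self.regions["region_id"].astype(int), self.regions["relevance"]))


def _affine(spacing: Tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_nifti(path: str | Path, values: np.ndarray, spacing: Tuple[float, float, float]) -> None:
    arr = np.asarray(values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    else:
        arr = arr.astype(np.float32)
    nib.save(nib.Nifti1Image(arr, _affine(spacing)), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, Tuple[float, float, float]]:
    """Load a NIfTI volume; returns (array, voxel spacing in mm)."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj), spacing
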