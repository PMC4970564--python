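"""Discrete analysis space: voxel grids, statistical maps, and NIfTI plumbing.

All coordinate-based meta-analysis here happens on a regular 3-D grid in a
single stereotactic template space.  World coordinates are millimetres at
voxel centers; voxel indices are 0-based; the grid affine is diagonal (no
rotation or shear), which is all a template-space analysis needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "StatMap",
    "GridError",
    "OutOfGridError",
    "make_box_mask",
    "transform_coordinates",
    "read_stat_map",
    "write_stat_map",
]

MapKind = Literal["ma", "ale", "p", "count", "binary"]
MAP_KINDS = ("ma", "ale", "p", "count", "binary")


class GridError(ValueError):
    """Invalid grid geometry or mismatched grids."""


class OutOfGridError(GridError):
    """A voxel index or mm point falls outside the grid."""


@dataclass
class VolumeGrid:
    """A regular 3-D voxel grid with a boolean analysis mask.

    Parameters
    ----------
    shape : tuple of 3 ints
        Grid dimensions (voxels per axis).
    voxel_size : array-like of 3 floats
        Edge length of a voxel along each axis, in mm.
    origin : array-like of 3 floats
        World (mm) coordinate of the *center* of voxel (0, 0, 0).
    mask : ndarray of bool, optional
        Analysis mask; defaults to all-true. Must contain >= 1 true voxel.
    """

    shape: tuple[int, int, int]
    voxel_size: np.ndarray
    origin: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise GridError(f"shape must be 3 positive integers, got {self.shape}")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape == ():
            self.voxel_size = np.repeat(self.voxel_size, 3)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise GridError("voxel_size must be 3 positive mm lengths")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise GridError("origin must be a 3-vector (mm)")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape:
                raise GridError("mask shape does not match grid shape")
        if not self.mask.any():
            raise GridError("mask must contain at least one voxel")

    # -- geometry ---------------------------------------------------------

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_mm(self, idx) -> np.ndarray:
        """Map 0-based voxel indices to mm coordinates of voxel centers."""
        idx = np.asarray(idx)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise OutOfGridError(f"voxel index {idx} outside grid of shape {self.shape}")
        return idx * self.voxel_size + self.origin

    def mm_to_voxel(self, mm) -> tuple[np.ndarray, np.ndarray]:
        """Map mm points to nearest voxel indices.

        Returns ``(indices, inside)`` where ``inside`` flags points whose
        nearest voxel lies within the grid; out-of-grid indices are returned
        unclipped so callers can see where the point fell.
        """
        mm = np.asarray(mm, dtype=float)
        idx = np.rint((mm - self.origin) / self.voxel_size).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)
        return idx, inside

    def mask_indices(self) -> np.ndarray:
        """(n, 3) array of in-mask voxel indices, C-order (lexicographic)."""
        return np.argwhere(self.mask)

    def same_geometry(self, other: "VolumeGrid", rtol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol)
        )

    def check_compatible(self, other: "VolumeGrid") -> None:
        if not (self.same_geometry(other) and np.array_equal(self.mask, other.mask)):
            raise GridError("grids do not match (geometry or mask differ)")


def make_box_mask(shape, voxel_size, origin) -> VolumeGrid:
    """All-true rectangular grid — a desk-scale stand-in for a brain mask."""
    return VolumeGrid(shape=tuple(shape), voxel_size=voxel_size, origin=origin)


def transform_coordinates(grid: VolumeGrid, point, direction: str):
    """Convert a single point between world mm and 0-based voxel indices.

    ``direction="mm_to_voxel"`` returns ``(index, inside)`` with ``inside``
    False when the nearest voxel is outside the grid.  ``"voxel_to_mm"``
    returns the mm center and raises :class:`OutOfGridError` for an
    out-of-bounds index.
    """
    if direction == "mm_to_voxel":
        idx, inside = grid.mm_to_voxel(point)
        return idx, bool(inside)
    if direction == "voxel_to_mm":
        return grid.voxel_to_mm(point)
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class StatMap:
    """A per-voxel scalar field on a :class:`VolumeGrid`.

    ``kind`` declares the semantics: modeled-activation probability (``ma``),
    ALE score (``ale``), p-value (``p``), overlap count (``count``) or binary
    membership (``binary``).  Values outside the mask are always zero.
    """

    grid: VolumeGrid
    values: np.ndarray
    kind: MapKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridError("values shape does not match grid shape")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        self.validate()

    def validate(self) -> None:
        vals = self.values
        if not np.all(np.isfinite(vals)):
            raise ValueError("map contains non-finite values")
        if np.any(vals[~self.grid.mask] != 0):
            raise ValueError("values outside the mask must be 0")
        if self.kind in ("ma", "ale", "p"):
            if vals.min() < 0 or vals.max() > 1:
                raise ValueError(f"{self.kind} values must lie in [0, 1]")
        elif self.kind == "binary":
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary map values must be 0 or 1")
        elif self.kind == "count":
            if vals.min() < 0 or np.any(vals != np.round(vals)):
                raise ValueError("count map values must be nonnegative integers")

    def in_mask(self) -> np.ndarray:
        """Flat array of values at in-mask voxels (C-order)."""
        return self.values[self.grid.mask]

    def new_like(self, values: np.ndarray, kind: MapKind) -> "StatMap":
        return StatMap(grid=self.grid, values=values, kind=kind)


# -- NIfTI I/O ------------------------------------------------------------


def write_stat_map(stat_map: StatMap, path) -> None:
    """Write a map as a NIfTI-1 volume with a diagonal affine."""
    data = np.asarray(stat_map.values, dtype=np.float64)
    img = nib.Nifti1Image(data, stat_map.grid.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_stat_map(path, kind: MapKind, mask: np.ndarray | None = None) -> StatMap:
    """Read a NIfTI-1 volume written by :func:`write_stat_map`.

    The grid is reconstructed from the affine, which must be diagonal.  A
    mask may be supplied; by default the whole volume is in-mask (masks are
    stored as their own binary maps).
    """
    img = nib.load(str(path))
    aff = np.asarray(img.affine, dtype=float)
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise GridError(f"{path}: affine is not diagonal; unsupported orientation")
    voxel_size = np.diag(rot)
    if np.any(voxel_size <= 0):
        raise GridError(f"{path}: non-positive voxel sizes in affine")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise GridError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    grid = VolumeGrid(shape=data.shape, voxel_size=voxel_size, origin=aff[:3, 3], mask=mask)
    if kind == "binary":
        data = (data != 0).astype(np.float64)
    return StatMap(grid=grid, values=data, kind=kind)
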