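"""Volume containers and NIfTI I/O.

All computation happens in voxel space on a masked lattice.  The masked
voxels are linearized in a fixed order — Fortran order over (x, y, z),
x varying fastest — because the topological gradient addresses individual
voxels and must be stable across runs and platforms.  Affine metadata is
carried through for round-trip writing but never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "SubjectScan",
    "ReferenceSet",
    "read_volume",
    "read_scan",
    "write_maps",
    "flatten",
    "unflatten",
]


class GeometryError(ValueError):
    """Shape or mask mismatch between volumes."""


@dataclass
class VolumeGrid:
    """A 3D scalar field on a voxel lattice with a brain mask.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    mask
        3D boolean array, same shape; at least one voxel must be True.
        Non-finite data values are only permitted outside the mask.
    affine
        4x4 voxel-to-world matrix, preserved on write, never interpreted.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise GeometryError(f"expected 3D data, got {self.data.ndim}D")
        if self.mask.shape != self.data.shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} != data shape {self.data.shape}"
            )
        if not self.mask.any():
            raise ValueError("mask has no True voxel")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite data inside the mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        """Number of masked voxels (V)."""
        return int(self.mask.sum())

    def flat_values(self) -> np.ndarray:
        """Masked intensities in the canonical linearization order."""
        return flatten(self.data, self.mask)

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Same geometry, new 3D data."""
        return VolumeGrid(data, self.mask, self.affine)

    def with_flat(self, values: np.ndarray) -> "VolumeGrid":
        """Same geometry, data given as a masked V-vector (zeros outside)."""
        return VolumeGrid(unflatten(values, self.mask), self.mask, self.affine)


@dataclass
class SubjectScan:
    """One subject's scan as a T x V matrix of masked voxel timeseries."""

    Ys: np.ndarray
    grid: VolumeGrid
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.Ys = np.asarray(self.Ys, dtype=np.float64)
        if self.Ys.ndim != 2:
            raise GeometryError("Ys must be T x V")
        if self.Ys.shape[1] != self.grid.n_voxels:
            raise GeometryError(
                f"V={self.Ys.shape[1]} does not match mask ({self.grid.n_voxels} voxels)"
            )
        if self.Ys.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.group not in ("patient", "control", "unknown"):
            raise ValueError(f"unknown group label {self.group!r}")

    @property
    def T(self) -> int:
        return self.Ys.shape[0]

    @property
    def V(self) -> int:
        return self.Ys.shape[1]


@dataclass
class ReferenceSet:
    """K reference network maps on a common grid, rows in masked-vector space."""

    theta_G: np.ndarray
    grid: VolumeGrid
    network_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.theta_G = np.asarray(self.theta_G, dtype=np.float64)
        if self.theta_G.ndim != 2:
            raise GeometryError("theta_G must be K x V")
        if self.theta_G.shape[1] != self.grid.n_voxels:
            raise GeometryError("theta_G columns do not match mask voxel count")
        if self.theta_G.shape[0] < 1:
            raise ValueError("need at least one network")
        norms = np.abs(self.theta_G).sum(axis=1)
        if np.any(norms == 0):
            raise ValueError("all-zero network row in reference set")
        if not self.network_names:
            self.network_names = [f"net{k}" for k in range(self.theta_G.shape[0])]
        if len(self.network_names) != self.theta_G.shape[0]:
            raise ValueError("network_names length does not match K")

    @property
    def K(self) -> int:
        return self.theta_G.shape[0]


# ---------------------------------------------------------------------------
# flatten / unflatten: Fortran order (x fastest) restricted to masked voxels


def flatten(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Masked values of ``data`` in the canonical (x-fastest) order."""
    return data.ravel(order="F")[mask.ravel(order="F")]


def unflatten(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scatter a masked V-vector back to a full 3D array (zeros outside)."""
    values = np.asarray(values, dtype=np.float64)
    flat_mask = mask.ravel(order="F")
    if values.shape != (int(flat_mask.sum()),):
        raise GeometryError(
            f"expected {int(flat_mask.sum())} values, got {values.shape}"
        )
    out = np.zeros(flat_mask.shape, dtype=np.float64)
    out[flat_mask] = values
    return out.reshape(mask.shape, order="F")


def masked_indices(mask: np.ndarray) -> np.ndarray:
    """(V, 3) integer voxel coordinates of masked voxels, canonical order."""
    flat = np.flatnonzero(mask.ravel(order="F"))
    nx, ny, nz = mask.shape
    x = flat % nx
    y = (flat // nx) % ny
    z = flat // (nx * ny)
    return np.stack([x, y, z], axis=1)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> VolumeGrid:
    """Read one 3D volume; the mask marks finite voxels."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim == 4:
        raise GeometryError("4D input: use read_scan for timeseries data")
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D volume, got {data.ndim}D")
    mask = np.isfinite(data)
    if not mask.any():
        raise ValueError("volume contains no finite voxels")
    data = np.where(mask, data, 0.0)
    return VolumeGrid(data, mask, np.asarray(img.affine))


def as_binary_mask(grid: VolumeGrid) -> VolumeGrid:
    """Interpret a loaded volume as a binary mask (nonzero -> True)."""
    m = grid.data > 0
    if not m.any():
        raise ValueError("mask volume has no nonzero voxels")
    return VolumeGrid(m.astype(np.float64), m, grid.affine)


def read_scan(path, mask: VolumeGrid, subject_id: str = "", group: str = "unknown") -> SubjectScan:
    """Read a 4D scan and flatten it to T x V against ``mask``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise GeometryError(f"expected a 4D scan, got {data.ndim}D")
    if data.shape[:3] != mask.shape:
        raise GeometryError(
            f"scan spatial shape {data.shape[:3]} != mask shape {mask.shape}"
        )
    T = data.shape[3]
    Ys = np.stack([flatten(data[..., t], mask.mask) for t in range(T)], axis=0)
    grid = VolumeGrid(np.zeros(mask.shape), mask.mask, np.asarray(img.affine))
    return SubjectScan(Ys, grid, subject_id=subject_id, group=group)


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a 3D volume; out-of-mask voxels are written as zero."""
    data = np.where(grid.mask, grid.data, 0.0)
    nib.save(nib.Nifti1Image(data.astype(np.float32), grid.affine), str(path))


def write_maps(maps: np.ndarray, grid: VolumeGrid, path) -> None:
    """Write K masked-vector maps as one 4D volume (K along the 4th axis)."""
    maps = np.atleast_2d(np.asarray(maps, dtype=np.float64))
    if maps.shape[1] != grid.n_voxels:
        raise GeometryError(
            f"maps have {maps.shape[1]} columns, mask has {grid.n_voxels} voxels"
        )
    vols = np.stack([unflatten(row, grid.mask) for row in maps], axis=3)
    nib.save(nib.Nifti1Image(vols.astype(np.float32), grid.affine), str(path))


def write_scan(scan: SubjectScan, path) -> None:
    """Write a SubjectScan back to a 4D volume."""
    vols = np.stack([unflatten(row, scan.grid.mask) for row in scan.Ys], axis=3)
    nib.save(nib.Nifti1Image(vols.astype(np.float32), scan.grid.affine), str(path))
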