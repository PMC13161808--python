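"""Regular 3-D sampling grids and the containers that live on them.

A :class:`VolumeGrid` is a shape plus a voxel-to-world affine, the minimal
description of a volumetric analysis space (e.g. a 3-mm isotropic MNI-like
grid). :class:`BinaryMask` and :class:`BOLDSeries` wrap boolean membership
volumes and 4-D time series on such a grid and round-trip to NIfTI-1 via
nibabel.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "BinaryMask", "BOLDSeries"]


@dataclasses.dataclass(frozen=True, eq=False)
class VolumeGrid:
    """Shape + voxel-to-world affine of a volumetric sampling grid."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {shape}")
        affine = np.array(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
        affine.setflags(write=False)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    # -- constructors -----------------------------------------------------
    @classmethod
    def isotropic(cls, n: int | tuple[int, int, int], voxel_mm: float = 3.0) -> "VolumeGrid":
        """Centered isotropic grid: ``n`` voxels per axis, ``voxel_mm`` spacing.

        The grid is centered on the world origin so that a cubic grid with
        odd ``n`` has a voxel center exactly at (0, 0, 0), mirroring how a
        resampled MNI bounding box brackets the anterior commissure.
        """
        shape = (n, n, n) if np.isscalar(n) else tuple(n)
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = [-voxel_mm * (s - 1) / 2.0 for s in shape]
        return cls(shape=shape, affine=affine)

    @classmethod
    def from_img(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        return cls(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))

    # -- geometry ---------------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world-space points (mm)."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, C-ordered, shape (V, 3)."""
        ijk = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(ijk)

    def contains_world(self, xyz: np.ndarray) -> np.ndarray:
        """True where a world point falls inside the grid bounding box.

        A point belongs to the box if its continuous voxel coordinate lies in
        [-0.5, s - 0.5) along every axis, i.e. inside some voxel's cell.
        """
        vox = np.atleast_2d(self.world_to_voxel(xyz))
        lo = vox >= -0.5
        hi = vox < np.array(self.shape) - 0.5
        return (lo & hi).all(axis=1)

    # -- identity ---------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def __hash__(self) -> int:  # frozen dataclass with eq=False needs explicit hash
        return hash(self.shape)

    def matches(self, other: "VolumeGrid") -> bool:
        return self == other

    # -- I/O --------------------------------------------------------------
    def to_img(self, data: np.ndarray, dtype=np.float32) -> nib.Nifti1Image:
        arr = np.asarray(data)
        if arr.shape[:3] != self.shape:
            raise ValueError(f"data shape {arr.shape} does not match grid {self.shape}")
        return nib.Nifti1Image(arr.astype(dtype), self.affine)


@dataclasses.dataclass
class BinaryMask:
    """Boolean voxel membership on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data).astype(bool)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match grid {self.grid.shape}"
            )
        self.data = data

    @classmethod
    def empty(cls, grid: VolumeGrid) -> "BinaryMask":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    @classmethod
    def full(cls, grid: VolumeGrid) -> "BinaryMask":
        return cls(grid, np.ones(grid.shape, dtype=bool))

    @classmethod
    def from_img(cls, img: nib.Nifti1Image, threshold: float = 0.5) -> "BinaryMask":
        return cls(VolumeGrid.from_img(img), np.asarray(img.dataobj) > threshold)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.data.ravel())

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask(self.grid, self.data | other.data)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask(self.grid, self.data & other.data)

    def issubset(self, other: "BinaryMask") -> bool:
        self._check(other)
        return bool(np.all(~self.data | other.data))

    def _check(self, other: "BinaryMask") -> None:
        if not self.grid.matches(other.grid):
            raise ValueError("masks live on different grids")

    def to_img(self) -> nib.Nifti1Image:
        return self.grid.to_img(self.data.astype(np.uint8), dtype=np.uint8)

    @staticmethod
    def union(masks: Iterable["BinaryMask"]) -> "BinaryMask":
        masks = list(masks)
        if not masks:
            raise ValueError("cannot take the union of zero masks")
        out = masks[0]
        for m in masks[1:]:
            out = out | m
        return out


@dataclasses.dataclass
class BOLDSeries:
    """One subject's 4-D BOLD time series (x, y, z, t) with repetition time."""

    grid: VolumeGrid
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 4 or data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"BOLD data shape {data.shape} does not match grid {self.grid.shape} + time"
            )
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        self.data = data

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])

    def as_matrix(self) -> np.ndarray:
        """(V, T) view of the series, voxels C-ordered as in voxel_centers."""
        return self.data.reshape(-1, self.n_timepoints)

    def to_img(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.grid.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = self.tr_seconds
        img.header.set_zooms(zooms)
        return img

    @classmethod
    def from_img(cls, img: nib.Nifti1Image, tr_seconds: float | None = None) -> "BOLDSeries":
        if tr_seconds is None:
            zooms = img.header.get_zooms()
            tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr_seconds > 0:
            raise ValueError(
                "repetition time missing: not in NIfTI header and not supplied"
            )
        return cls(VolumeGrid.from_img(img), np.asarray(img.dataobj), tr_seconds)
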