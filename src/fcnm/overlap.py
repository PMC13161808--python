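"""Correspondence between derived networks and canonical parcellations.

Two spatial statistics quantify how a derived network mask relates to
reference anatomy: the overlap proportion |network ∩ C| / |C| against each
canonical network C of an integer-labelled atlas (e.g. the seven cortical
networks of Yeo et al. plus a subcortical network), and the Dice coefficient
2|A ∩ B| / (|A| + |B|) between two network masks.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from nilearn import image as nli_image

from .grid import BinaryMask, VolumeGrid

__all__ = [
    "CanonicalAtlas",
    "OverlapReport",
    "resample_atlas",
    "overlap_proportion",
    "dice_coefficient",
]


@dataclasses.dataclass
class CanonicalAtlas:
    """Integer label volume plus a label -> network-name map (0 = background)."""

    grid: VolumeGrid
    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError("label volume shape does not match grid")
        if labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        names = {int(k): v for k, v in self.names.items()}
        if 0 in names:
            raise ValueError("label 0 is reserved for background")
        if len(set(names.values())) != len(names):
            raise ValueError("canonical network names must be unique")
        self.labels = labels.astype(int)
        self.names = names

    def network_mask(self, label: int) -> BinaryMask:
        return BinaryMask(self.grid, self.labels == label)

    def to_img(self) -> nib.Nifti1Image:
        return self.grid.to_img(self.labels.astype(np.int16), dtype=np.int16)

    @classmethod
    def from_files(cls, label_path: str | Path, names_path: str | Path) -> "CanonicalAtlas":
        img = nib.load(str(label_path))
        with open(names_path) as fh:
            names = {int(k): v for k, v in json.load(fh).items()}
        return cls(VolumeGrid.from_img(img), np.asarray(img.dataobj), names)


@dataclasses.dataclass
class OverlapReport:
    """Overlap-proportion profile of one network mask against an atlas.

    ``proportions`` maps network name -> |mask ∩ C| / |C|, or None when the
    canonical network has no voxels on the analysis grid (undefined, not 0).
    """

    network_name: str
    proportions: dict[str, float | None]
    n_canonical: dict[str, int]
    n_intersection: dict[str, int]
    mask_voxels: int
    grid_shape: tuple[int, int, int]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "network": list(self.proportions),
                "proportion": [self.proportions[k] for k in self.proportions],
                "n_canonical": [self.n_canonical[k] for k in self.proportions],
                "n_intersection": [self.n_intersection[k] for k in self.proportions],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "network_name": self.network_name,
                "mask_voxels": self.mask_voxels,
                "grid_shape": list(self.grid_shape),
                "proportions": self.proportions,
                "n_canonical": self.n_canonical,
                "n_intersection": self.n_intersection,
            },
            indent=2,
        )


def resample_atlas(atlas: CanonicalAtlas, grid: VolumeGrid) -> CanonicalAtlas:
    """Nearest-neighbor resampling of a label atlas onto the analysis grid.

    Labels are never interpolated, so every output label exists in the
    input. Raises when the two fields of view do not overlap (a non-empty
    atlas resamples to an empty volume).
    """
    if atlas.grid.matches(grid):
        return CanonicalAtlas(grid, atlas.labels.copy(), dict(atlas.names))
    res = nli_image.resample_img(
        atlas.to_img(),
        target_affine=grid.affine,
        target_shape=grid.shape,
        interpolation="nearest",
        force_resample=True,
        copy_header=True,
    )
    labels = np.asarray(res.dataobj).astype(int)
    if atlas.labels.any() and not labels.any():
        raise ValueError(
            "atlas and analysis grid fields of view do not overlap: "
            "resampling produced an empty label volume"
        )
    return CanonicalAtlas(grid, labels, dict(atlas.names))


def overlap_proportion(network: BinaryMask, atlas: CanonicalAtlas,
                       network_name: str = "network") -> OverlapReport:
    """Proportion of each canonical network covered by the derived mask."""
    if not network.grid.matches(atlas.grid):
        raise ValueError("network mask and atlas are on different grids")
    proportions: dict[str, float | None] = {}
    n_canonical: dict[str, int] = {}
    n_intersection: dict[str, int] = {}
    for label, name in sorted(atlas.names.items()):
        canon = atlas.labels == label
        size = int(canon.sum())
        inter = int((canon & network.data).sum())
        n_canonical[name] = size
        n_intersection[name] = inter
        proportions[name] = (inter / size) if size > 0 else None
    return OverlapReport(
        network_name=network_name,
        proportions=proportions,
        n_canonical=n_canonical,
        n_intersection=n_intersection,
        mask_voxels=network.n_voxels,
        grid_shape=network.grid.shape,
    )


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A ∩ B| / (|A| + |B|) of two masks on one grid."""
    if not a.grid.matches(b.grid):
        raise ValueError("masks live on different grids")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice coefficient is undefined for two empty masks")
    overlap = int((a.data & b.data).sum())
    return 2.0 * overlap / (na + nb)
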