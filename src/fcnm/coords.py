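"""Study coordinate tables, Talairach-to-MNI conversion, and seed masks.

Activation foci reported by published studies arrive as tab-separated tables
of peak coordinates (one row per focus, grouped into study contrasts). Each
contrast's foci are rendered as small spheres on the analysis grid and merged
into one combined "contrast seed" mask, the seed of the downstream
resting-state functional connectivity analysis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import BinaryMask, VolumeGrid

__all__ = [
    "FocusRecord",
    "SeedSpec",
    "ICBM_SPM2TAL",
    "tal_to_mni",
    "mni_to_tal",
    "parse_coordinate_table",
    "foci_to_mni",
    "build_contrast_seed",
    "group_by_contrast",
]

#: Lancaster pooled affine mapping ICBM/MNI coordinates (SPM convention) to
#: Talairach space ("icbm_spm2tal"). Talairach-reported foci are converted to
#: MNI with the inverse of this matrix.
ICBM_SPM2TAL = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

_SPACE_ALIASES = {
    "mni": "MNI",
    "mni152": "MNI",
    "icbm": "MNI",
    "tal": "Talairach",
    "talairach": "Talairach",
}

_DIRECTION_ALIASES = {
    "hyper": "hyper",
    "hypo": "hypo",
    "increase": "hyper",
    "decrease": "hypo",
}

_COORD_BOUND_MM = 120.0


@dataclasses.dataclass(frozen=True)
class FocusRecord:
    """One reported peak coordinate of a study contrast."""

    study_id: str
    contrast_id: str
    xyz_mm: tuple[float, float, float]
    space: str = "MNI"
    direction: str = "hyper"

    def __post_init__(self) -> None:
        xyz = tuple(float(v) for v in self.xyz_mm)
        if not all(np.isfinite(xyz)):
            raise ValueError(f"non-finite coordinate {xyz} in {self.study_id}/{self.contrast_id}")
        if max(abs(v) for v in xyz) > _COORD_BOUND_MM:
            raise ValueError(
                f"coordinate {xyz} exceeds the {_COORD_BOUND_MM:g} mm sanity bound "
                f"({self.study_id}/{self.contrast_id})"
            )
        if self.space not in ("MNI", "Talairach"):
            raise ValueError(f"unknown reference space {self.space!r}")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "xyz_mm", xyz)


@dataclasses.dataclass(frozen=True)
class SeedSpec:
    """Sphere radius for seed construction; a voxel belongs to a sphere when
    its center lies within ``radius_mm`` (Euclidean, world mm) of the focus."""

    radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.radius_mm <= 20:
            raise ValueError(f"radius_mm must be in (0, 20], got {self.radius_mm}")


def tal_to_mni(xyz_tal: np.ndarray) -> np.ndarray:
    """Map Talairach coordinates (mm) to MNI via the inverse Lancaster affine."""
    xyz = np.asarray(xyz_tal, dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("Talairach coordinates must be finite")
    inv = np.linalg.inv(ICBM_SPM2TAL)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def mni_to_tal(xyz_mni: np.ndarray) -> np.ndarray:
    """Forward Lancaster affine (MNI -> Talairach); inverse of :func:`tal_to_mni`."""
    xyz = np.asarray(xyz_mni, dtype=float)
    return xyz @ ICBM_SPM2TAL[:3, :3].T + ICBM_SPM2TAL[:3, 3]


def parse_coordinate_table(path: str | Path) -> list[FocusRecord]:
    """Read a tab-separated focus table into records.

    Required columns: ``study_id contrast_id x y z space``. An optional
    ``direction`` column ("hyper"/"hypo") defaults to "hyper". Space tokens
    are matched case-insensitively against {MNI, MNI152, ICBM, Tal,
    Talairach}. Rows with non-numeric coordinates raise, naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    required = ["study_id", "contrast_id", "x", "y", "z", "space"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"coordinate table {path} is missing required column {col!r}")

    records: list[FocusRecord] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # 1-based, after the header line
        try:
            xyz = tuple(float(row[c]) for c in ("x", "y", "z"))
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric coordinate in row {line_no} of {path}: "
                f"x={row['x']!r} y={row['y']!r} z={row['z']!r}"
            ) from None
        space_token = str(row["space"]).strip().lower()
        if space_token not in _SPACE_ALIASES:
            raise ValueError(
                f"unknown reference space {row['space']!r} in row {line_no} of {path}"
            )
        direction = "hyper"
        if "direction" in df.columns and isinstance(row.get("direction"), str):
            token = row["direction"].strip().lower()
            if token not in _DIRECTION_ALIASES:
                raise ValueError(
                    f"unknown direction {row['direction']!r} in row {line_no} of {path}"
                )
            direction = _DIRECTION_ALIASES[token]
        records.append(
            FocusRecord(
                study_id=str(row["study_id"]).strip(),
                contrast_id=str(row["contrast_id"]).strip(),
                xyz_mm=xyz,
                space=_SPACE_ALIASES[space_token],
                direction=direction,
            )
        )
    return records


def foci_to_mni(records: Iterable[FocusRecord]) -> list[FocusRecord]:
    """Convert every Talairach-space record to MNI; MNI records pass through."""
    out = []
    for rec in records:
        if rec.space == "Talairach":
            xyz = tal_to_mni(np.asarray(rec.xyz_mm))
            out.append(dataclasses.replace(rec, xyz_mm=tuple(xyz), space="MNI"))
        else:
            out.append(rec)
    return out


def group_by_contrast(
    records: Iterable[FocusRecord],
) -> dict[tuple[str, str, str], list[FocusRecord]]:
    """Group foci by (direction, study_id, contrast_id), preserving file order."""
    groups: dict[tuple[str, str, str], list[FocusRecord]] = {}
    for rec in records:
        groups.setdefault((rec.direction, rec.study_id, rec.contrast_id), []).append(rec)
    return groups


def build_contrast_seed(
    foci: Sequence[FocusRecord],
    spec: SeedSpec,
    grid: VolumeGrid,
) -> BinaryMask:
    """Union of spheres centered at each focus of one contrast.

    Membership is "voxel center within ``radius_mm``" (inclusive). A focus
    whose sphere captures no voxel center — possible for a 1-mm radius on a
    3-mm grid — contributes its single nearest voxel instead, so every focus
    contributes at least one voxel and the merged seed is never empty.
    """
    if len(foci) == 0:
        raise ValueError("a contrast seed needs at least one focus")
    for rec in foci:
        if rec.space != "MNI":
            raise ValueError(
                f"focus {rec.study_id}/{rec.contrast_id} is still in {rec.space}; "
                "convert with foci_to_mni first"
            )

    centers = grid.voxel_centers()  # (V, 3)
    mask = np.zeros(grid.n_voxels, dtype=bool)
    r2 = spec.radius_mm**2
    for rec in foci:
        xyz = np.asarray(rec.xyz_mm)
        if not grid.contains_world(xyz)[0]:
            raise ValueError(
                f"focus {tuple(rec.xyz_mm)} of {rec.study_id}/{rec.contrast_id} "
                "falls outside the analysis grid bounding box"
            )
        d2 = ((centers - xyz) ** 2).sum(axis=1)
        hit = d2 <= r2 + 1e-9
        if not hit.any():
            hit = np.zeros_like(hit)
            hit[np.argmin(d2)] = True  # nearest-voxel fallback
        mask |= hit
    return BinaryMask(grid, mask.reshape(grid.shape))
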