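"""Seed-to-whole-brain functional connectivity maps.

The seed time course of a contrast is the unweighted mean of the BOLD series
over the seed voxels; its Pearson correlation with every in-mask voxel is
Fisher z-transformed (atanh) to stabilize variance before group statistics.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .grid import BinaryMask, BOLDSeries, VolumeGrid

__all__ = ["FCMap", "fisher_z", "seed_fc_map"]

logger = logging.getLogger(__name__)

#: |r| is clipped to this value before atanh so z stays finite at degenerate
#: voxels (a voxel series identical to the seed course).
R_CLIP = 1.0 - 1e-7


@dataclasses.dataclass
class FCMap:
    """Fisher-z seed connectivity of one subject x contrast.

    ``z`` is a full-grid volume, zero outside ``mask``; values are defined
    (and finite) only within the analysis mask.
    """

    grid: VolumeGrid
    z: np.ndarray
    mask: BinaryMask
    subject_id: str
    contrast_id: str
    n_timepoints: int

    def to_img(self):
        return self.mask.grid.to_img(self.z.astype(np.float32))


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped to ``R_CLIP`` so the output is always finite."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP))


def seed_fc_map(
    bold: BOLDSeries,
    seed: BinaryMask,
    brain_mask: BinaryMask | None = None,
    subject_id: str = "",
    contrast_id: str = "",
) -> FCMap:
    """Correlate the mean seed time course with every in-mask voxel.

    Voxels whose series has zero variance get z = 0; their count is logged.
    A zero-variance seed course is fatal (the contrast seed carries no
    signal for this subject).
    """
    if brain_mask is None:
        brain_mask = BinaryMask.full(bold.grid)
    if not bold.grid.matches(seed.grid) or not bold.grid.matches(brain_mask.grid):
        raise ValueError("seed / brain mask grid does not match the BOLD grid")
    if seed.is_empty:
        raise ValueError(f"empty seed mask for {subject_id}/{contrast_id}")
    if not seed.issubset(brain_mask):
        raise ValueError("seed mask must be contained in the brain mask")
    T = bold.n_timepoints
    if T < 30:
        raise ValueError(f"need >= 30 timepoints for a stable FC map, got {T}")

    X = bold.as_matrix().astype(float)  # (V, T)
    course = X[seed.flat_indices()].mean(axis=0)
    course = course - course.mean()
    course_norm = np.linalg.norm(course)
    if course_norm == 0:
        raise ValueError(
            f"zero-variance seed time course (subject={subject_id!r}, "
            f"contrast={contrast_id!r})"
        )

    in_mask = brain_mask.flat_indices()
    Xm = X[in_mask]
    Xm = Xm - Xm.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xm, axis=1)
    flat_vox = norms == 0
    norms[flat_vox] = 1.0
    r = (Xm @ course) / (norms * course_norm)
    r[flat_vox] = 0.0
    n_flat = int(flat_vox.sum())
    if n_flat:
        logger.info(
            "%d zero-variance voxel(s) set to z=0 (subject=%s contrast=%s)",
            n_flat, subject_id, contrast_id,
        )

    z = np.zeros(bold.grid.n_voxels)
    z[in_mask] = fisher_z(r)
    return FCMap(
        grid=bold.grid,
        z=z.reshape(bold.grid.shape),
        mask=brain_mask,
        subject_id=subject_id,
        contrast_id=contrast_id,
        n_timepoints=T,
    )
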