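"""Group statistics: one-sample t, voxel-level FWE, probability networks.

Subject Fisher-z maps for one contrast are combined with a voxel-wise
one-sample t-test; the t map is thresholded at a family-wise-error-corrected
level (Bonferroni by default, or a sign-flip max-t permutation test) and
binarized. Binarized contrast maps are overlaid into a network probability
map — the per-voxel fraction of contrasts whose thresholded map contains the
voxel — and the final network keeps voxels connected to *more than* the
probability threshold (strictly) of the contrast seeds.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .fc import FCMap
from .grid import BinaryMask, VolumeGrid

__all__ = [
    "GroupStatMap",
    "ProbabilityMap",
    "one_sample_t",
    "fwe_threshold_mask",
    "overlay_probability",
    "threshold_probability",
]


@dataclasses.dataclass
class GroupStatMap:
    """Voxel-wise one-sample t statistics for one contrast.

    ``defined`` marks voxels with nonzero across-subject variance inside the
    analysis mask; t is NaN elsewhere and such voxels can never survive
    thresholding.
    """

    grid: VolumeGrid
    t: np.ndarray
    defined: np.ndarray
    df: int
    n_subjects: int
    contrast_id: str = ""

    @property
    def n_undefined(self) -> int:
        return int(self.defined.size - self.defined.sum())

    def to_img(self):
        return self.grid.to_img(np.nan_to_num(self.t).astype(np.float32))


@dataclasses.dataclass
class ProbabilityMap:
    """Per-voxel fraction of thresholded contrast maps containing the voxel."""

    grid: VolumeGrid
    counts: np.ndarray
    n_contrasts: int
    direction: str = "hyper"

    @property
    def fraction(self) -> np.ndarray:
        return self.counts / self.n_contrasts

    def to_img(self):
        return self.grid.to_img(self.fraction.astype(np.float32))


def one_sample_t(z_maps: Sequence[FCMap], contrast_id: str = "") -> GroupStatMap:
    """Voxel-wise one-sample t-test of subject z maps against zero.

    t = mean(z) / (sd(z)/sqrt(n)) with the n-1 sample standard deviation.
    Voxels with zero across-subject variance (or outside the common analysis
    mask) are flagged undefined rather than given an arbitrary value.
    """
    if len(z_maps) < 2:
        raise ValueError("one-sample t-test needs at least 2 subjects")
    grid = z_maps[0].grid
    mask = z_maps[0].mask.data
    for m in z_maps[1:]:
        if not m.grid.matches(grid):
            raise ValueError(f"grid mismatch for subject {m.subject_id!r}")
        if not np.array_equal(m.mask.data, mask):
            raise ValueError(f"analysis mask mismatch for subject {m.subject_id!r}")
    Z = np.stack([m.z for m in z_maps]).astype(float)  # (n, x, y, z)
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    defined = (sd > 0) & mask
    t = np.full(grid.shape, np.nan)
    t[defined] = mean[defined] / (sd[defined] / math.sqrt(n))
    cid = contrast_id or z_maps[0].contrast_id
    return GroupStatMap(grid=grid, t=t, defined=defined, df=n - 1, n_subjects=n,
                        contrast_id=cid)


def _tail_values(t: np.ndarray, tail: str) -> np.ndarray:
    if tail == "positive":
        return t
    if tail == "negative":
        return -t
    raise ValueError(f"tail must be 'positive' or 'negative', got {tail!r}")


def fwe_threshold_mask(
    stat: GroupStatMap,
    alpha: float = 0.05,
    method: str = "bonferroni",
    tail: str = "positive",
    z_maps: Sequence[FCMap] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> BinaryMask:
    """Binary mask of voxels surviving voxel-level FWE at ``alpha``.

    bonferroni
        One-tailed p(t, df) < alpha / V over the V defined voxels.
    permutation
        Sign-flipping max-t null: a voxel survives when its t exceeds the
        (1 - alpha) quantile of the maximum statistic over >= 1000 random
        sign flips of the subject maps (requires ``z_maps``).

    ``alpha = 1`` is accepted as an explicit degenerate, uncorrected case:
    every defined voxel with an effect on the requested tail survives.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    tv = _tail_values(stat.t, tail)
    defined = stat.defined
    V = int(defined.sum())
    if V < 1:
        raise ValueError("no defined voxels to threshold")
    if alpha == 1.0:
        return BinaryMask(stat.grid, defined & (np.nan_to_num(tv) > 0))

    if method == "bonferroni":
        t_crit = stats.t.isf(alpha / V, stat.df)
        survive = defined & (np.nan_to_num(tv, nan=-np.inf) > t_crit)
    elif method == "permutation":
        if z_maps is None:
            raise ValueError("permutation FWE needs the subject z maps")
        if len(z_maps) < 10:
            warnings.warn(
                f"permutation FWE with only {len(z_maps)} subjects: the p-value "
                "grid is coarse (2^n sign patterns)",
                stacklevel=2,
            )
        Z = np.stack([m.z for m in z_maps]).astype(float).reshape(len(z_maps), -1)
        Z = Z[:, defined.ravel()]
        if tail == "negative":
            Z = -Z
        n = Z.shape[0]
        rng = np.random.default_rng(seed)
        max_t = np.empty(n_permutations)
        for p in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=n)[:, None]
            Zp = signs * Z
            mean = Zp.mean(axis=0)
            sd = Zp.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                tp = mean / (sd / math.sqrt(n))
            max_t[p] = np.nanmax(tp)
        t_crit = np.quantile(max_t, 1.0 - alpha, method="higher")
        survive = defined & (np.nan_to_num(tv, nan=-np.inf) > t_crit)
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    return BinaryMask(stat.grid, survive)


def overlay_probability(masks: Sequence[BinaryMask], direction: str = "hyper") -> ProbabilityMap:
    """Overlay binarized contrast maps into a network probability map."""
    if len(masks) == 0:
        raise ValueError("need at least one binarized contrast map")
    grid = masks[0].grid
    for m in masks[1:]:
        if not m.grid.matches(grid):
            raise ValueError("grid mismatch between binarized contrast maps")
    counts = np.sum([m.data for m in masks], axis=0).astype(int)
    return ProbabilityMap(grid=grid, counts=counts, n_contrasts=len(masks),
                          direction=direction)


def threshold_probability(pmap: ProbabilityMap, threshold: float = 0.60) -> BinaryMask:
    """Voxels contained in strictly more than ``threshold`` of the contrasts.

    The inequality is strict: with 25 contrasts at the 60% threshold the
    smallest surviving count is 16 (16/25 > 0.6 while 15/25 = 0.6 fails);
    with 24 contrasts it is 15. Counts are compared as integers so exact
    boundary fractions are handled without floating-point surprises.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"probability threshold must be in (0, 1), got {threshold}")
    # smallest integer k with k / n > threshold
    k_min = math.floor(threshold * pmap.n_contrasts + 1e-9) + 1
    return BinaryMask(pmap.grid, pmap.counts >= k_min)
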