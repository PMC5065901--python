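"""Volume-level tractogram post-processing.

Normalization is log(1 + count) / log(1 + max count) — base-invariant,
maps zero counts to 0 and the busiest voxel to exactly 1. Absolute
thresholding is strict (value > level); rank thresholding keeps voxels at or
above the q-quantile of the *nonzero* values (ties at the cutoff kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import VisitationMap

__all__ = [
    "NormalizedTractogram",
    "OverlapMap",
    "normalize_tractogram",
    "threshold_map",
    "rank_threshold",
    "group_average",
    "overlap_percentage",
    "center_of_gravity",
    "max_intensity_projection",
    "dice_overlap",
]

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


@dataclass
class NormalizedTractogram:
    values: np.ndarray  # in [0, 1]
    source_max_count: int
    affine: np.ndarray
    log_base_note: str = "log1p counts scaled by log1p(max); base-invariant"


@dataclass
class OverlapMap:
    values: np.ndarray  # percentages in [0, 100]
    n_subjects: int
    affine: np.ndarray


def normalize_tractogram(vmap: VisitationMap) -> NormalizedTractogram:
    """value = log(1 + count) / log(1 + max_count)."""
    counts = np.asarray(vmap.counts)
    if np.any(counts < 0):
        raise ValueError("visitation counts must be non-negative")
    max_count = int(counts.max())
    if max_count == 0:
        raise ValueError("cannot normalize an all-zero visitation map")
    values = np.log1p(counts) / np.log1p(max_count)
    return NormalizedTractogram(
        values=values, source_max_count=max_count, affine=vmap.affine.copy()
    )


def threshold_map(norm: NormalizedTractogram, level: float) -> np.ndarray:
    """Binary volume of voxels with value strictly greater than ``level``."""
    if not (0.0 <= level <= 1.0):
        raise ValueError(f"level must be in [0, 1], got {level}")
    return norm.values > level


def rank_threshold(norm: NormalizedTractogram, q: float) -> np.ndarray:
    """Keep voxels >= the q-quantile of the nonzero values (ties kept)."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0, 1), got {q}")
    nz = norm.values[norm.values > 0]
    if nz.size == 0:
        raise ValueError("rank_threshold needs at least one nonzero voxel")
    cutoff = np.quantile(nz, q)  # linear-interpolation quantile
    return norm.values >= cutoff


def group_average(maps: list[NormalizedTractogram]) -> NormalizedTractogram:
    """Voxelwise arithmetic mean of normalized tractograms on one grid."""
    if len(maps) < 2:
        raise ValueError("group_average needs at least 2 maps")
    ref = maps[0]
    for m in maps[1:]:
        if m.values.shape != ref.values.shape or not np.allclose(m.affine, ref.affine):
            raise ValueError("all maps must share grid shape and affine")
    mean = np.mean([m.values for m in maps], axis=0)
    return NormalizedTractogram(
        values=mean,
        source_max_count=max(m.source_max_count for m in maps),
        affine=ref.affine.copy(),
        log_base_note="voxelwise mean of normalized tractograms",
    )


def overlap_percentage(binary_maps: list[np.ndarray], affine=None) -> OverlapMap:
    """Percentage of subjects in which each voxel is kept."""
    if len(binary_maps) < 2:
        raise ValueError("overlap_percentage needs at least 2 binary maps")
    shape = binary_maps[0].shape
    for m in binary_maps[1:]:
        if m.shape != shape:
            raise ValueError("all binary maps must share one grid")
    n = len(binary_maps)
    stack = np.stack([m.astype(bool) for m in binary_maps])
    values = 100.0 * stack.sum(axis=0) / n
    if affine is None:
        affine = np.eye(4)
    return OverlapMap(values=values, n_subjects=n, affine=np.asarray(affine, float))


def center_of_gravity(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Unweighted mean world-mm coordinate of the kept voxel centers."""
    idx = np.argwhere(np.asarray(mask).astype(bool))
    if idx.shape[0] == 0:
        raise ValueError("center_of_gravity of an empty mask")
    hom = np.hstack([idx, np.ones((idx.shape[0], 1))])
    world = hom @ np.asarray(affine, float).T
    return world[:, :3].mean(axis=0)


def max_intensity_projection(norm: NormalizedTractogram, axis) -> np.ndarray:
    """Glass-brain view: per-pixel max over the collapsed axis."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of x, y, z (or 0, 1, 2), got {axis!r}")
    return norm.values.max(axis=_AXES[axis])


def dice_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two binary volumes (0 when both are empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / denom
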