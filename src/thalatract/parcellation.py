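"""Connectivity-based segmentation of the seed region.

Winner-take-all labeling (each seed voxel takes the target with the highest
connection count), fraction-of-maximum thresholding/binarization of
probability maps, and peak-voxel extraction.  All tie-breaks are
deterministic — arg-max ties go to the earlier-listed target, peak ties to
the lexicographically lowest voxel index — and every tie is logged, since
the choice is a convention rather than a result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import VoxelGrid, require_binary
from .tracking import ConnectivityResult

log = logging.getLogger("thalatract.parcellation")


class DegenerateMapError(ValueError):
    """Raised when a map has no positive value to threshold or peak."""


@dataclass
class Parcellation:
    """Integer-label segmentation of the seed mask (0 = unassigned)."""

    labels: VoxelGrid
    target_names: list[str]
    source: ConnectivityResult | None = None
    tie_voxels: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lab = self.labels.data
        if np.any(lab < 0) or np.any(lab > len(self.target_names)):
            raise ValueError("labels must index target_names (or 0)")

    def name_of(self, label: int) -> str:
        if label == 0:
            raise ValueError("label 0 is unassigned")
        return self.target_names[label - 1]

    def legend(self) -> dict[int, str]:
        return {i + 1: n for i, n in enumerate(self.target_names)}


def winner_take_all(result: ConnectivityResult) -> Parcellation:
    """Label each seed voxel with its arg-max target.

    Voxels where every target count is zero stay unassigned (label 0).
    Ties between targets go to the one listed first; tied voxels are
    recorded and logged.
    """
    names = result.target_names
    if not names:
        raise ValueError("ConnectivityResult has no targets")
    seed = result.seed_mask.data.astype(bool)
    stack = np.stack([result.counts[n].data for n in names], axis=0)

    best = np.argmax(stack, axis=0)  # numpy argmax: first max wins = our tie rule
    maxval = np.max(stack, axis=0)
    labels = np.where(seed & (maxval > 0), best + 1, 0).astype(np.int32)

    n_at_max = np.sum(stack == maxval[None], axis=0)
    tie_mask = seed & (maxval > 0) & (n_at_max > 1)
    ties = [tuple(int(c) for c in ijk) for ijk in np.argwhere(tie_mask)]
    if ties:
        log.info("winner-take-all: %d tied voxel(s), first-listed target kept", len(ties))

    return Parcellation(
        labels=VoxelGrid(labels, result.seed_mask.affine),
        target_names=list(names),
        source=result,
        tie_voxels=ties,
    )


def threshold_and_binarise(prob_map: VoxelGrid, fraction: float = 0.10) -> VoxelGrid:
    """Binary mask of voxels at or above ``fraction`` of the map maximum.

    The comparison is inclusive, so the maximum itself always survives.
    With the protocol's 5000 samples per seed voxel this is the familiar
    particle cutoff: fraction 0.10 keeps voxels with >= 500 particles,
    fraction 0.05 keeps >= 250.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    data = prob_map.data
    peak = float(np.max(data))
    if peak <= 0:
        raise DegenerateMapError("map has no positive values to threshold")
    cutoff = particle_cutoff(peak, fraction)
    mask = (data >= cutoff).astype(np.uint8)
    log.info(
        "threshold %.0f%% of max %.6g -> cutoff %.6g, %d voxel(s) retained",
        100 * fraction, peak, cutoff, int(mask.sum()),
    )
    return prob_map.like(mask)


def particle_cutoff(max_count: float, fraction: float) -> float:
    """The display-threshold particle count: fraction x map maximum."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    return fraction * float(max_count)


def peak_voxel(prob_map: VoxelGrid, mask: VoxelGrid) -> np.ndarray:
    """World mm coordinates of the maximal voxel within a mask.

    Ties are broken by the lexicographically lowest voxel index (x, then y,
    then z) and logged.  The returned point is the voxel center.
    """
    m = require_binary(mask, "mask")
    if not prob_map.same_geometry(mask):
        raise ValueError("map and mask geometry differ")
    if not np.any(m):
        raise ValueError("mask is empty")
    vals = np.where(m, prob_map.data, -np.inf)
    peak = np.max(vals)
    if not peak > 0:
        raise DegenerateMapError("map is nonpositive everywhere inside the mask")
    winners = np.argwhere(vals == peak)
    if len(winners) > 1:
        log.info(
            "peak: %d tied maxima, lexicographically lowest index kept", len(winners)
        )
    # argwhere output is already lexicographically sorted
    return prob_map.voxel_to_world(winners[0])
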