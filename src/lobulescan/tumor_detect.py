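"""Coherent tumor mass detection by seeded region growing on stddev-n.

Seeds are the non-lobule segments whose mean texture value lies within
±0.1 of the median over all non-lobule tissue segments. The region then
accretes neighbor segments whose mean texture is within 2 units of the
running area-weighted region mean, provided they share at least 20% of
their border with the region. Post-processing fills enclosed holes and
drops components smaller than one third of the largest.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mrseg import SegmentationLevel

DEFAULT_SEED_TOLERANCE = 0.1
DEFAULT_GROWTH_DELTA = 2.0
DEFAULT_MIN_BORDER_FRACTION = 0.2


@dataclass
class TumorRegion:
    """Binary tumor mask at working resolution."""

    mask: np.ndarray  # (H, W) bool
    pixel_size_um: float

    @property
    def component_areas(self) -> list[int]:
        labels, n = ndimage.label(self.mask)
        if n == 0:
            return []
        return ndimage.sum_labels(
            np.ones_like(labels), labels, index=np.arange(1, n + 1)
        ).astype(int).tolist()

    def border_mask(self) -> np.ndarray:
        """Tumor pixels on the region boundary (8-connected outline)."""
        if not self.mask.any():
            return np.zeros_like(self.mask)
        eroded = ndimage.binary_erosion(self.mask, structure=np.ones((3, 3)), border_value=0)
        return self.mask & ~eroded


def select_seeds(
    level: SegmentationLevel,
    lobule_ids: set[int],
    tolerance: float = DEFAULT_SEED_TOLERANCE,
) -> set[int]:
    """Non-lobule segments whose mean stddev-n is within ``tolerance`` of
    the median mean stddev-n over all non-lobule segments."""
    candidates = {sid: seg.mean_stddevn for sid, seg in level.segments.items() if sid not in lobule_ids}
    if not candidates:
        raise ValueError("no non-lobule segments to seed from")
    med = float(np.median(list(candidates.values())))
    seeds = {sid for sid, m in candidates.items() if abs(m - med) <= tolerance}
    if not seeds:
        raise ValueError(
            f"no segment within ±{tolerance} of the median stddev-n ({med:.3f}); "
            "increase the seed tolerance"
        )
    return seeds


def grow_tumor(
    level: SegmentationLevel,
    seeds: set[int],
    delta: float = DEFAULT_GROWTH_DELTA,
    min_border_fraction: float = DEFAULT_MIN_BORDER_FRACTION,
    excluded: set[int] | None = None,
) -> TumorRegion:
    """Iteratively accrete neighbor segments onto the seed set.

    A neighbor joins when its mean stddev-n differs from the running
    area-weighted region mean by at most ``delta`` AND its border shared
    with the region is at least ``min_border_fraction`` of its total border.
    Candidates are processed from a queue ordered by |mean - region mean|
    (ties by segment id) so the result is deterministic.
    """
    if not seeds:
        raise ValueError("seeds must be nonempty")
    excluded = excluded or set()
    region = set(seeds)
    area = sum(level.segments[s].area_px for s in region)
    weighted = sum(level.segments[s].mean_stddevn * level.segments[s].area_px for s in region)

    total_border = {sid: level.total_border_of(sid) for sid in level.segments}

    def shared_border(sid: int) -> int:
        return sum(l for n, l in level.neighbors_of(sid).items() if n in region)

    frontier: set[int] = set()
    for s in region:
        frontier |= {n for n in level.neighbors_of(s) if n not in region and n not in excluded}

    while True:
        region_mean = weighted / area
        heap = []
        for sid in frontier:
            m = level.segments[sid].mean_stddevn
            heapq.heappush(heap, (abs(m - region_mean), sid))
        added = None
        while heap:
            gap, sid = heapq.heappop(heap)
            if gap > delta:
                break
            if shared_border(sid) >= min_border_fraction * total_border[sid]:
                added = sid
                break
        if added is None:
            break
        region.add(added)
        frontier.discard(added)
        seg = level.segments[added]
        area += seg.area_px
        weighted += seg.mean_stddevn * seg.area_px
        frontier |= {
            n for n in level.neighbors_of(added) if n not in region and n not in excluded
        }

    mask = np.isin(level.label_image, list(region))
    return TumorRegion(mask, level.pixel_size_um)


def postprocess_tumor(region: TumorRegion) -> TumorRegion:
    """Close enclosed holes, then eliminate components smaller than 1/3 of
    the largest component's area."""
    if not region.mask.any():
        raise ValueError("tumor region is empty")
    filled = ndimage.binary_fill_holes(region.mask)
    labels, n = ndimage.label(filled)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= sizes.max() / 3.0) + 1
    return TumorRegion(np.isin(labels, keep), region.pixel_size_um)
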