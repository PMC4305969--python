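"""Lobule candidate classification and hierarchical refinement.

Candidates are selected independently at the four coarsest segmentation
levels from textural (mean stddev-n), geometric (area, roundness) and
relational (difference of means, border contrast) features; all conditions
must hold simultaneously. The refinement pass then walks the hierarchy
coarse to fine, dropping candidates with divergent sub-segments, trimming
failing peripheral sub-segments, and finally merging adjacent segments that
satisfy the reduced criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .mrseg import Segment, SegmentationLevel, SegmentHierarchy, mask_roundness
from .rasters import RasterLayer

_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class LobuleCriteria:
    """Acceptance ranges for lobule classification (working resolution)."""

    stddevn_range: tuple[float, float] = (15.0, 36.0)
    area_range_px: tuple[float, float] = (2000.0, 14000.0)
    roundness_range: tuple[float, float] = (0.0, 1.3)
    min_diff_of_means: float = 5.0
    min_border_contrast: float = 0.4
    #: Max allowed area-weighted standard deviation of sub-segment mean
    #: stddev-n before a candidate is dropped as internally inconsistent.
    #: The source rule set does not publish a value; 10 texture units is an
    #: assumption and stays configurable.
    subdivergence_limit: float = 10.0

    def __post_init__(self) -> None:
        for lo, hi in (self.stddevn_range, self.area_range_px, self.roundness_range):
            if not lo < hi:
                raise ValueError("criteria ranges must be non-degenerate")
        if self.min_diff_of_means < 0 or self.min_border_contrast < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class Lobule:
    """An accepted region of interest at working resolution."""

    id: int
    mask: np.ndarray  # (H, W) bool at working resolution
    centroid: tuple[float, float]
    area_px: int
    area_mm2: float
    review_label: str = "unreviewed"  # unreviewed | TP | FP | FN-added
    #: level whose segment context the acceptance features were computed in
    origin_level_index: int = 0


@dataclass
class RegionFeatures:
    """Feature bundle for a segment or a pixel region; relational features
    are ``None`` when the region has no tissue neighbors."""

    area_px: int
    mean_stddevn: float
    roundness: float
    diff_of_means: float | None
    border_contrast: float | None


# ---------------------------------------------------------------------------
# Feature evaluation


def segment_features(
    level: SegmentationLevel, seg: Segment, texture: RasterLayer, need_roundness: bool = True
) -> RegionFeatures:
    nbrs = level.neighbors_of(seg.id)
    if nbrs:
        lengths = np.array(list(nbrs.values()), dtype=float)
        means = np.array([level.segments[n].mean_stddevn for n in nbrs])
        diff = seg.mean_stddevn - float(np.average(means, weights=lengths))
        contrast = _mean_contrast(
            seg.mean_stddevn, _surroundings_mean(level, set(nbrs), {seg.id})
        )
    else:
        diff = contrast = None
    rnd = seg.roundness if need_roundness else math.nan
    return RegionFeatures(seg.area_px, seg.mean_stddevn, rnd, diff, contrast)


def region_features(
    level: SegmentationLevel, mask: np.ndarray, texture: RasterLayer
) -> RegionFeatures:
    """Features of an arbitrary pixel region, evaluated against the segments
    of ``level`` that border it (overlapping segments are excluded from the
    neighbor set)."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty region")
    labels = level.label_image
    member_ids = set(np.unique(labels[mask]).tolist()) - {-1}
    border_len: dict[int, int] = {}
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nbr_labels = _shift_int(labels, dr, dc, fill=-1)
        nbr_in_mask = _shift_bool(mask, dr, dc)
        sel = mask & ~nbr_in_mask & (nbr_labels >= 0)
        vals, counts = np.unique(nbr_labels[sel], return_counts=True)
        for v, n in zip(vals.tolist(), counts.tolist()):
            if v not in member_ids:
                border_len[v] = border_len.get(v, 0) + n
    mean_sd = float(texture.values[mask].mean())
    if border_len:
        lengths = np.array(list(border_len.values()), dtype=float)
        means = np.array([level.segments[n].mean_stddevn for n in border_len])
        diff = mean_sd - float(np.average(means, weights=lengths))
        contrast = _mean_contrast(
            mean_sd, _surroundings_mean(level, set(border_len), member_ids)
        )
    else:
        diff = contrast = None
    return RegionFeatures(area, mean_sd, mask_roundness(mask), diff, contrast)


def _surroundings_mean(level: SegmentationLevel, ring1: set[int], exclude: set[int]) -> float:
    """Area-weighted mean texture of the surroundings: the adjacent segments
    plus their own neighbors (two hops), excluding the region itself.

    Border-length or single-ring aggregation lets a thin transition sliver
    that happens to enclose the region mask its true surroundings; the
    two-hop area-weighted mean reads "the surroundings" as the nearby tissue.
    """
    ids = set(ring1)
    for n in ring1:
        ids |= set(level.neighbors_of(n))
    ids -= exclude
    areas = np.array([level.segments[n].area_px for n in ids], dtype=float)
    means = np.array([level.segments[n].mean_stddevn for n in ids])
    return float(np.average(means, weights=areas))


def _mean_contrast(m_region: float, m_neighbors: float) -> float:
    """Michelson contrast of a region's mean against the (border-length
    weighted) mean of its neighbor segments.

    The published threshold (0.4) is only reachable on the smoothed texture
    layer when contrast is computed from segment means; 1-pixel border
    strips straddle the smooth transition and saturate far below it.
    """
    if m_region + m_neighbors == 0:
        return 0.0
    return (m_region - m_neighbors) / (m_region + m_neighbors)


def _shift_int(v: np.ndarray, dr: int, dc: int, fill: int) -> np.ndarray:
    h, w = v.shape
    out = np.full_like(v, fill)
    out[max(-dr, 0) : h - max(dr, 0), max(-dc, 0) : w - max(dc, 0)] = v[
        max(dr, 0) : h - max(-dr, 0), max(dc, 0) : w - max(-dc, 0)
    ]
    return out


def _shift_bool(v: np.ndarray, dr: int, dc: int) -> np.ndarray:
    h, w = v.shape
    out = np.zeros_like(v)
    out[max(-dr, 0) : h - max(dr, 0), max(-dc, 0) : w - max(dc, 0)] = v[
        max(dr, 0) : h - max(-dr, 0), max(dc, 0) : w - max(-dc, 0)
    ]
    return out


def passes_full(f: RegionFeatures, c: LobuleCriteria) -> bool:
    """The complete candidate rule: every condition must be met."""
    return (
        c.stddevn_range[0] <= f.mean_stddevn <= c.stddevn_range[1]
        and c.area_range_px[0] <= f.area_px <= c.area_range_px[1]
        and c.roundness_range[0] <= f.roundness <= c.roundness_range[1]
        and f.diff_of_means is not None
        and f.diff_of_means >= c.min_diff_of_means
        and f.border_contrast is not None
        and f.border_contrast >= c.min_border_contrast
    )


def _passes_reduced_seg(
    level: SegmentationLevel,
    seg: Segment,
    texture: RasterLayer,
    c: LobuleCriteria,
    group: set[int] | frozenset[int] | None = None,
) -> bool:
    """Reduced-criteria check for a single segment, cheapest features first
    (border contrast and minimum area are not part of the reduced rule).

    When ``group`` is given, the difference of means is evaluated against
    neighbors outside the group only: a sub-segment buried inside a
    candidate has no surroundings to contrast with and passes the
    relational condition vacuously.
    """
    if not (c.stddevn_range[0] <= seg.mean_stddevn <= c.stddevn_range[1]):
        return False
    if seg.area_px > c.area_range_px[1]:
        return False
    nbrs = level.neighbors_of(seg.id)
    if group is not None:
        nbrs = {n: l for n, l in nbrs.items() if n not in group}
    if nbrs:
        lengths = np.array(list(nbrs.values()), dtype=float)
        means = np.array([level.segments[n].mean_stddevn for n in nbrs])
        diff = seg.mean_stddevn - float(np.average(means, weights=lengths))
        if diff < c.min_diff_of_means:
            return False
    elif group is None:
        return False
    return c.roundness_range[0] <= seg.roundness <= c.roundness_range[1]


def passes_reduced(f: RegionFeatures, c: LobuleCriteria) -> bool:
    """The sub-segment rule: full criteria minus minimum area and border
    contrast (the maximum-area bound and roundness are retained)."""
    return (
        c.stddevn_range[0] <= f.mean_stddevn <= c.stddevn_range[1]
        and f.area_px <= c.area_range_px[1]
        and c.roundness_range[0] <= f.roundness <= c.roundness_range[1]
        and f.diff_of_means is not None
        and f.diff_of_means >= c.min_diff_of_means
    )


# ---------------------------------------------------------------------------
# Initial classification


def initial_classify(
    level: SegmentationLevel, texture: RasterLayer, criteria: LobuleCriteria
) -> set[int]:
    """Ids of segments satisfying the full candidate rule at one level."""
    out: set[int] = set()
    lo_sd, hi_sd = criteria.stddevn_range
    lo_a, hi_a = criteria.area_range_px
    for sid, seg in level.segments.items():
        # cheap screens first; roundness needs a distance transform
        if not (lo_sd <= seg.mean_stddevn <= hi_sd and lo_a <= seg.area_px <= hi_a):
            continue
        f = segment_features(level, seg, texture)
        if passes_full(f, criteria):
            out.add(sid)
    return out


# ---------------------------------------------------------------------------
# Refinement through the hierarchy


def refine(
    hierarchy: SegmentHierarchy,
    initial: dict[int, set[int]],
    criteria: LobuleCriteria,
    texture: RasterLayer,
) -> list[Lobule]:
    """Refine per-level candidates coarse to fine into final lobules.

    Candidates are represented as groups of segment ids of the level under
    consideration. Refining a group against its sub-segments either drops it
    (divergent sub-segments), keeps it whole (all sub-segments pass the
    reduced criteria), or trims failing peripheral sub-segments and keeps
    the remainder iff it passes the full criteria. Surviving groups are
    carried to the next finer level, where not-yet-covered initial
    candidates of that level join them. After the last refinement stage
    every candidate must re-pass the full criteria on its final pixel mask;
    the closing pass merges adjacent non-lobule segments that satisfy the
    reduced criteria and accepts the merge iff it passes the full criteria.
    """
    n_levels = len(hierarchy.levels)
    n_classified = min(4, n_levels - 1)  # levels with initial candidates
    # each candidate is (origin level, segment-id group at the current level)
    carried: list[tuple[int, frozenset[int]]] = []
    for li in range(n_classified):
        covered: set[int] = set()
        for _, g in carried:
            covered |= g
        groups = list(carried)
        for sid in sorted(initial.get(li, set())):
            if sid not in covered:
                groups.append((li, frozenset([sid])))
        carried = []
        for origin, g in sorted(groups, key=lambda t: (t[0], min(t[1]))):
            result = _refine_group(hierarchy, li, g, criteria, texture, origin)
            if result:
                carried.append((origin, result))

    # groups are now expressed in the level below the last classified one;
    # the closing acceptance check replays the full criteria in the context
    # of each candidate's origin level (where it was initially classified)
    group_level = hierarchy.levels[min(n_classified, n_levels - 1)]
    lobules: list[tuple[np.ndarray, int]] = []
    for origin, g in carried:
        mask = _group_mask(group_level, g)
        f = region_features(hierarchy.levels[origin], mask, texture)
        if passes_full(f, criteria):
            lobules.append((mask, origin))

    accepted = np.zeros(group_level.label_image.shape, dtype=bool)
    for m, _ in lobules:
        accepted |= m
    lobules.extend(
        (m, n_classified - 1)
        for m in _merge_reduced_pass(hierarchy.levels[n_classified - 1], accepted, criteria, texture)
    )
    return _finalize(lobules, group_level.pixel_size_um)


def _refine_group(
    hierarchy: SegmentHierarchy,
    level_index: int,
    group: frozenset[int],
    criteria: LobuleCriteria,
    texture: RasterLayer,
    origin_level: int | None = None,
) -> frozenset[int] | None:
    """Apply the sub-segment rules to one candidate group; returns the
    surviving group expressed in the next finer level's segment ids."""
    fine = hierarchy.levels[level_index + 1]
    children: list[int] = []
    for sid in group:
        children.extend(hierarchy.levels[level_index].segments[sid].children)
    if not children:
        return None
    child_segs = [fine.segments[i] for i in children]

    if len(child_segs) > 1:
        sds = np.array([s.mean_stddevn for s in child_segs])
        areas = np.array([s.area_px for s in child_segs], dtype=float)
        wmean = float(np.average(sds, weights=areas))
        wstd = math.sqrt(float(np.average((sds - wmean) ** 2, weights=areas)))
        if wstd > criteria.subdivergence_limit:
            return None  # sub-segments too different from each other

    group_set = frozenset(children)
    reduced_ok = {
        s.id: _passes_reduced_seg(fine, s, texture, criteria, group=group_set) for s in child_segs
    }
    if all(reduced_ok.values()):
        return frozenset(children)

    # trim failing peripheral sub-segments until none remains
    remaining = set(children)
    while True:
        failing = [i for i in sorted(remaining) if not reduced_ok[i]]
        peripheral = [
            i for i in failing if _is_peripheral(fine, i, remaining)
        ]
        if not peripheral:
            break
        remaining.difference_update(peripheral)
        if not remaining:
            return None
    mask = _group_mask(fine, remaining)
    # relational features judged at the candidate's origin level, as in the
    # initial classification: against ever finer neighbors the surroundings
    # degenerate into transition slivers and the contrast of a genuine
    # lobule would erode level by level
    f = region_features(hierarchy.levels[origin_level if origin_level is not None else level_index], mask, texture)
    if passes_full(f, criteria):
        return frozenset(remaining)
    return None


def _is_peripheral(level: SegmentationLevel, sid: int, group: set[int]) -> bool:
    """True when at least half of the sub-segment's border lies on the
    candidate's outline (i.e. not shared with other group members)."""
    nbrs = level.neighbors_of(sid)
    inner = sum(length for n, length in nbrs.items() if n in group)
    total = level.total_border_of(sid)
    return (total - inner) >= 0.5 * total


def _group_mask(level: SegmentationLevel, group: frozenset[int] | set[int]) -> np.ndarray:
    return np.isin(level.label_image, list(group))


def _merge_reduced_pass(
    level: SegmentationLevel,
    accepted: np.ndarray,
    criteria: LobuleCriteria,
    texture: RasterLayer,
) -> list[np.ndarray]:
    """Closing pass: merge adjacent non-lobule segments of the final
    classification level that satisfy the reduced criteria; accept the
    merged region as a lobule iff it passes the full criteria. Merging
    chains through connected groups of qualifying segments."""
    passing = set()
    for sid, seg in level.segments.items():
        r0, c0, r1, c1 = seg.bbox
        if accepted[r0 : r1 + 1, c0 : c1 + 1][
            level.label_image[r0 : r1 + 1, c0 : c1 + 1] == sid
        ].any():
            continue  # already part of an accepted lobule
        if _passes_reduced_seg(level, seg, texture, criteria):
            passing.add(sid)
    # connected components of qualifying segments
    out: list[np.ndarray] = []
    seen: set[int] = set()
    for sid in sorted(passing):
        if sid in seen:
            continue
        comp = {sid}
        stack = [sid]
        while stack:
            cur = stack.pop()
            for nbr in level.neighbors_of(cur):
                if nbr in passing and nbr not in comp:
                    comp.add(nbr)
                    stack.append(nbr)
        seen |= comp
        if len(comp) < 2:
            continue
        mask = _group_mask(level, frozenset(comp))
        f = region_features(level, mask, texture)
        if passes_full(f, criteria):
            out.append(mask)
    return out


def _finalize(masks: list[tuple[np.ndarray, int]], pixel_size_um: float) -> list[Lobule]:
    entries = []
    for mask, origin in masks:
        rr, cc = np.nonzero(mask)
        centroid = (float(rr.mean()), float(cc.mean()))
        entries.append((centroid, mask, origin))
    entries.sort(key=lambda e: e[0])
    lobules = []
    for i, (centroid, mask, origin) in enumerate(entries, start=1):
        area = int(mask.sum())
        lobules.append(
            Lobule(
                id=i,
                mask=mask,
                centroid=centroid,
                area_px=area,
                area_mm2=area * (pixel_size_um / 1000.0) ** 2,
                review_label="unreviewed",
                origin_level_index=origin,
            )
        )
    return lobules


# ---------------------------------------------------------------------------
# Pathologist review


def apply_review(
    lobules: list[Lobule],
    labels: pd.DataFrame | None = None,
    fn_outlines: np.ndarray | None = None,
    pixel_size_um: float | None = None,
) -> list[Lobule]:
    """Apply a review table (columns ``lobule_id``, ``label`` with values
    TP/FP) and optional false-negative outlines (a label image whose positive
    values are missed lobules). FP lobules are excluded from downstream
    evaluation; FN outlines are added with label ``FN-added``."""
    if labels is None or len(labels) == 0:
        out = [replace(lb, mask=lb.mask) for lb in lobules]
    else:
        known = {lb.id for lb in lobules}
        bad = labels[~labels["lobule_id"].isin(list(known))]
        if len(bad):
            raise ValueError(f"review rows reference unknown lobule ids: {bad.to_dict('records')}")
        label_of = dict(zip(labels["lobule_id"], labels["label"]))
        out = []
        for lb in lobules:
            lab = str(label_of.get(lb.id, "unreviewed"))
            if lab not in ("TP", "FP", "unreviewed"):
                raise ValueError(f"unknown review label {lab!r} for lobule {lb.id}")
            if lab == "FP":
                continue
            out.append(replace(lb, review_label=lab))
    if fn_outlines is not None:
        if pixel_size_um is None:
            pixel_size_um = 1.0
        next_id = max((lb.id for lb in out), default=0) + 1
        for val in np.unique(fn_outlines):
            if val <= 0:
                continue
            mask = fn_outlines == val
            rr, cc = np.nonzero(mask)
            area = int(mask.sum())
            out.append(
                Lobule(
                    id=next_id,
                    mask=mask,
                    centroid=(float(rr.mean()), float(cc.mean())),
                    area_px=area,
                    area_mm2=area * (pixel_size_um / 1000.0) ** 2,
                    review_label="FN-added",
                )
            )
            next_id += 1
    return out
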