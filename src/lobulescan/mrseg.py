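"""Multiresolution region-merging segmentation with a strict hierarchy.

Segments are grown bottom-up from single tissue pixels by greedy pairwise
merging. The cost of merging regions ``a`` and ``b`` is the increase in
weighted heterogeneity

    cost = H(a ∪ b) - H(a) - H(b),   H(r) = sum_c w_c * n_r * sigma_{r,c}

summed over the input channels (R, G, B, texture by default, with the
texture channel weighted twice). Merges are executed in ascending cost
order from a global queue (ties broken by lowest region-id pair), and the
single merge tree is cut at cost threshold ``scale**2`` for each requested
scale, which guarantees that the resulting levels are strictly nested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import heappush, heappop
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .rasters import RasterLayer, TissueMask

DEFAULT_SCALES = (100, 80, 60, 40, 20)
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 2.0)


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Segment:
    """A connected region of tissue pixels at one segmentation level."""

    id: int
    level_index: int
    area_px: int
    means: tuple[float, ...]  # per input channel (R, G, B, texture)
    bbox: tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax) inclusive
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    _level: "SegmentationLevel | None" = field(default=None, repr=False)
    _roundness: float | None = field(default=None, repr=False)

    @property
    def mean_stddevn(self) -> float:
        """Mean of the texture (stddev-to-neighbors) channel over the segment."""
        return self.means[-1]

    @property
    def roundness(self) -> float:
        if self._roundness is None:
            self._roundness = mask_roundness(self.mask())
        return self._roundness

    def mask(self) -> np.ndarray:
        """Full-grid boolean membership mask."""
        return self._level.label_image == self.id


@dataclass
class SegmentationLevel:
    """An exact partition of the tissue mask at one scale."""

    level_index: int
    scale_parameter: float
    segments: dict[int, Segment]
    adjacency: dict[tuple[int, int], int]  # (a, b) with a < b -> shared border length (pixel edges)
    label_image: np.ndarray  # (H, W) int, -1 outside tissue
    pixel_size_um: float

    _neighbor_map: dict[int, dict[int, int]] | None = field(default=None, repr=False)

    def neighbors_of(self, seg_id: int) -> dict[int, int]:
        """Neighbor segment id -> shared border length."""
        if self._neighbor_map is None:
            nm: dict[int, dict[int, int]] = {sid: {} for sid in self.segments}
            for (a, b), length in self.adjacency.items():
                nm[a][b] = length
                nm[b][a] = length
            self._neighbor_map = nm
        return self._neighbor_map[seg_id]

    def total_border_of(self, seg_id: int) -> int:
        """Total border length (pixel edges) of a segment, including edges to
        non-tissue and the image boundary."""
        seg = self.segments[seg_id]
        crop, _ = _crop_mask(self.label_image, seg.bbox, seg.id)
        perim = 0
        padded = np.pad(crop, 1, constant_values=False)
        for axis in (0, 1):
            perim += int(np.sum(np.diff(padded.astype(np.int8), axis=axis) != 0))
        return perim


@dataclass
class SegmentHierarchy:
    """Strictly nested segmentation levels, ordered coarse to fine."""

    levels: list[SegmentationLevel]
    tissue: TissueMask
    channels: list[RasterLayer]
    merge_log: list[tuple[float, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._link()

    def _link(self) -> None:
        for fine, coarse in zip(self.levels[1:], self.levels[:-1]):
            coarse_labels = coarse.label_image
            for seg in fine.segments.values():
                r, c = _first_pixel(fine.label_image, seg.bbox, seg.id)
                parent_id = int(coarse_labels[r, c])
                seg.parent = parent_id
                coarse.segments[parent_id].children.append(seg.id)

    def level_by_scale(self, scale: float) -> SegmentationLevel:
        for lvl in self.levels:
            if lvl.scale_parameter == scale:
                return lvl
        raise KeyError(f"no level with scale {scale}")

    def children_of(self, level_index: int, seg_id: int) -> list[Segment]:
        if level_index + 1 >= len(self.levels):
            return []
        fine = self.levels[level_index + 1]
        return [fine.segments[i] for i in self.levels[level_index].segments[seg_id].children]


# ---------------------------------------------------------------------------
# Merge engine


class _MergeEngine:
    """Greedy global-queue region merging over the 4-adjacency graph."""

    def __init__(self, channels: np.ndarray, weights: Sequence[float], mask: np.ndarray):
        # channels: (C, H, W) float; mask: (H, W) bool
        self.h, self.w = mask.shape
        self.mask = mask
        self.nchan = channels.shape[0]
        self.weights = [float(x) for x in weights]
        flat = [ch.ravel() for ch in channels]
        size = self.h * self.w
        # per-region stats: [n, s_0..s_{C-1}, q_0..q_{C-1}, H]
        self.stats: list[list[float] | None] = [None] * size
        self.neighbors: list[dict[int, int] | None] = [None] * size
        self.version = [0] * size
        self.uf_parent = list(range(size))
        self.heap: list[tuple[float, int, int, int, int]] = []
        self.merge_log: list[tuple[float, int, int]] = []

        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise ValueError("tissue mask is empty")
        for i in idx:
            vals = [float(f[i]) for f in flat]
            self.stats[i] = [1.0, *vals, *[v * v for v in vals], 0.0]
            self.neighbors[i] = {}
        m = mask
        # horizontal and vertical pixel adjacencies within tissue
        rr, cc = np.nonzero(m[:, :-1] & m[:, 1:])
        pairs = [(rr * self.w + cc, rr * self.w + cc + 1)]
        rr, cc = np.nonzero(m[:-1, :] & m[1:, :])
        pairs.append((rr * self.w + cc, (rr + 1) * self.w + cc))
        for ia, ib in pairs:
            for a, b in zip(ia.tolist(), ib.tolist()):
                self.neighbors[a][b] = 1
                self.neighbors[b][a] = 1
                self._push(a, b)

    # -- cost -------------------------------------------------------------
    def _cost(self, a: int, b: int) -> float:
        sa, sb = self.stats[a], self.stats[b]
        n = sa[0] + sb[0]
        c = self.nchan
        h = 0.0
        for k in range(c):
            s = sa[1 + k] + sb[1 + k]
            q = sa[1 + c + k] + sb[1 + c + k]
            var = q / n - (s / n) ** 2
            if var > 0.0:
                h += self.weights[k] * n * math.sqrt(var)
        return h - sa[1 + 2 * c] - sb[1 + 2 * c]

    def _push(self, a: int, b: int) -> None:
        if a > b:
            a, b = b, a
        heappush(self.heap, (self._cost(a, b), a, b, self.version[a], self.version[b]))

    # -- merging ----------------------------------------------------------
    def merge_until(self, threshold: float) -> None:
        """Execute all merges with cost <= threshold, in ascending cost order."""
        heap = self.heap
        version = self.version
        while heap:
            item = heappop(heap)
            cost, a, b, va, vb = item
            if version[a] != va or version[b] != vb:
                continue
            if cost > threshold:
                heappush(heap, item)
                return
            self._merge(a, b, cost)

    def _merge(self, a: int, b: int, cost: float) -> None:
        # survivor is a (a < b by construction)
        self.merge_log.append((cost, a, b))
        sa, sb = self.stats[a], self.stats[b]
        c = self.nchan
        n = sa[0] + sb[0]
        sa[0] = n
        h = 0.0
        for k in range(c):
            s = sa[1 + k] + sb[1 + k]
            q = sa[1 + c + k] + sb[1 + c + k]
            sa[1 + k] = s
            sa[1 + c + k] = q
            var = q / n - (s / n) ** 2
            if var > 0.0:
                h += self.weights[k] * n * math.sqrt(var)
        sa[1 + 2 * c] = h
        self.stats[b] = None
        self.uf_parent[b] = a

        na, nb = self.neighbors[a], self.neighbors[b]
        na.pop(b, None)
        for nbr, length in nb.items():
            if nbr == a:
                continue
            na[nbr] = na.get(nbr, 0) + length
            d = self.neighbors[nbr]
            d.pop(b, None)
            d[a] = na[nbr]
        self.neighbors[b] = None
        self.version[a] += 1
        self.version[b] = -1
        for nbr in na:
            self._push(a, nbr)

    # -- snapshots ---------------------------------------------------------
    def find_root(self, i: int) -> int:
        p = self.uf_parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def labels(self) -> np.ndarray:
        out = np.full(self.h * self.w, -1, dtype=np.int64)
        find = self.find_root
        for i in np.flatnonzero(self.mask.ravel()).tolist():
            out[i] = find(i)
        return out.reshape(self.h, self.w)


def multires_hierarchy(
    channels: Sequence[RasterLayer],
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    scales: Sequence[float] = DEFAULT_SCALES,
    mask: TissueMask | None = None,
) -> SegmentHierarchy:
    """Segment the tissue at every scale in ``scales`` (given coarse to fine).

    Returns a hierarchy whose levels partition the tissue mask exactly and
    are strictly nested: each finer segment lies inside exactly one coarser
    segment.
    """
    if mask is None:
        mask = TissueMask(np.ones(channels[0].shape, dtype=bool), channels[0].pixel_size_um)
    scales = list(scales)
    if any(s2 >= s1 for s1, s2 in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly descending")
    if len(channels) != len(weights):
        raise ValueError("one weight per channel required")
    if not any(w > 0 for w in weights):
        raise ValueError("weights must not all be zero")
    for ch in channels:
        if ch.shape != mask.shape:
            raise ValueError("all channels must share the tissue grid")

    stack = np.stack([ch.values for ch in channels])
    engine = _MergeEngine(stack, weights, mask.mask)
    levels: list[SegmentationLevel] = []
    for level_index, scale in reversed(list(enumerate(scales))):  # fine -> coarse
        engine.merge_until(float(scale) ** 2)
        labels = engine.labels()
        levels.append(_build_level(level_index, float(scale), labels, engine, mask.pixel_size_um))
    levels.reverse()
    return SegmentHierarchy(levels, mask, list(channels), merge_log=engine.merge_log)


def _build_level(
    level_index: int,
    scale: float,
    labels: np.ndarray,
    engine: _MergeEngine,
    pixel_size_um: float,
) -> SegmentationLevel:
    segments: dict[int, Segment] = {}
    ids = np.unique(labels)
    ids = ids[ids >= 0]
    objects = _bboxes(labels, ids)
    c = engine.nchan
    for sid in ids.tolist():
        st = engine.stats[sid]
        n = int(st[0])
        means = tuple(st[1 + k] / n for k in range(c))
        segments[sid] = Segment(
            id=sid, level_index=level_index, area_px=n, means=means, bbox=objects[sid]
        )
    adjacency: dict[tuple[int, int], int] = {}
    for sid in ids.tolist():
        for nbr, length in engine.neighbors[sid].items():
            key = (sid, nbr) if sid < nbr else (nbr, sid)
            adjacency[key] = length
    level = SegmentationLevel(level_index, scale, segments, adjacency, labels, pixel_size_um)
    for seg in segments.values():
        seg._level = level
    return level


def _bboxes(labels: np.ndarray, ids: np.ndarray) -> dict[int, tuple[int, int, int, int]]:
    out: dict[int, tuple[int, int, int, int]] = {}
    if ids.size == 0:
        return out
    # relabel compactly for ndimage.find_objects (ids is sorted by np.unique)
    compact = np.zeros_like(labels, dtype=np.int32)
    m = labels >= 0
    compact[m] = np.searchsorted(ids, labels[m]) + 1
    slices = ndimage.find_objects(compact)
    for i, v in enumerate(ids.tolist()):
        sl = slices[i]
        out[v] = (sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1)
    return out


def _first_pixel(labels: np.ndarray, bbox: tuple[int, int, int, int], sid: int) -> tuple[int, int]:
    r0, c0, r1, c1 = bbox
    sub = labels[r0 : r1 + 1, c0 : c1 + 1]
    rr, cc = np.nonzero(sub == sid)
    return r0 + int(rr[0]), c0 + int(cc[0])


def _crop_mask(labels: np.ndarray, bbox: tuple[int, int, int, int], sid: int):
    r0, c0, r1, c1 = bbox
    return labels[r0 : r1 + 1, c0 : c1 + 1] == sid, (r0, c0)


# ---------------------------------------------------------------------------
# Geometric and relational features


def roundness_from_radii(r_enclosing: float, r_inscribed: float, area: float) -> float:
    """Roundness = (enclosing radius - inscribed radius) / equivalent radius.

    Zero for a perfect disk (all three radii coincide); grows with
    elongation and boundary irregularity.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    r_equiv = math.sqrt(area / math.pi)
    return max(0.0, (r_enclosing - r_inscribed)) / r_equiv


def mask_roundness(mask: np.ndarray) -> float:
    """Roundness of a rasterized region.

    The enclosing radius is that of the minimum bounding circle over the
    pixel corner points; the inscribed radius comes from the Euclidean
    distance transform (distance to the region boundary).
    """
    from scipy.spatial import ConvexHull
    from shapely import MultiPoint, minimum_bounding_radius

    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    rr, cc = np.nonzero(mask)
    r0, r1 = rr.min(), rr.max()
    c0, c1 = cc.min(), cc.max()
    crop = mask[r0 : r1 + 1, c0 : c1 + 1]
    # inscribed radius: distance from the deepest pixel center to the nearest
    # outside pixel center, less half a pixel to reach the region boundary
    padded = np.pad(crop, 1, constant_values=False)
    edt = ndimage.distance_transform_edt(padded)
    r_ins = float(edt.max()) - 0.5
    # enclosing radius over pixel corners of the boundary pixels
    boundary = crop & ~ndimage.binary_erosion(crop)
    br, bc = np.nonzero(boundary)
    pts = np.concatenate(
        [np.stack([br + dr, bc + dc], axis=1) for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)]
    ).astype(float)
    if len(pts) > 8:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:
            pass  # degenerate (collinear) point sets fall through to shapely
    r_enc = float(minimum_bounding_radius(MultiPoint(pts)))
    return roundness_from_radii(r_enc, max(r_ins, 0.0), area)


def roundness(segment: Segment) -> float:
    """Roundness feature of a segment (0 for a perfect disk)."""
    return segment.roundness


def _border_strips(level: SegmentationLevel, a: Segment, b: Segment):
    r0 = min(a.bbox[0], b.bbox[0])
    c0 = min(a.bbox[1], b.bbox[1])
    r1 = max(a.bbox[2], b.bbox[2])
    c1 = max(a.bbox[3], b.bbox[3])
    sub = level.label_image[r0 : r1 + 1, c0 : c1 + 1]
    ma = sub == a.id
    mb = sub == b.id
    cross = ndimage.generate_binary_structure(2, 1)
    strip_a = ma & ndimage.binary_dilation(mb, structure=cross)
    strip_b = mb & ndimage.binary_dilation(ma, structure=cross)
    return strip_a, strip_b, (r0, c0, r1, c1)


def border_contrast(a: Segment, b: Segment, layer: RasterLayer) -> float:
    """Michelson contrast between the 1-pixel-deep strips of two adjacent
    segments along their shared border; positive when ``a`` is brighter."""
    level = a._level
    if level is not b._level:
        raise ValueError("segments must come from the same level")
    strip_a, strip_b, (r0, c0, r1, c1) = _border_strips(level, a, b)
    if not strip_a.any() or not strip_b.any():
        raise ValueError(f"segments {a.id} and {b.id} are not adjacent")
    sub = layer.values[r0 : r1 + 1, c0 : c1 + 1]
    m_a = float(sub[strip_a].mean())
    m_b = float(sub[strip_b].mean())
    if m_a + m_b == 0:
        return 0.0
    return (m_a - m_b) / (m_a + m_b)


def diff_of_means(a: Segment, neighbors: Sequence[Segment], layer: RasterLayer) -> float:
    """Mean of ``layer`` over ``a`` minus the border-length-weighted mean of
    the neighbor segments' means."""
    if not neighbors:
        raise ValueError("neighbors must be nonempty")
    level = a._level
    a_mean = _layer_mean(level, a, layer)
    weights = []
    means = []
    nbr_lengths = level.neighbors_of(a.id)
    for nb in neighbors:
        weights.append(nbr_lengths.get(nb.id, 1))
        means.append(_layer_mean(level, nb, layer))
    w = np.asarray(weights, dtype=float)
    return a_mean - float(np.average(means, weights=w))


def _layer_mean(level: SegmentationLevel, seg: Segment, layer: RasterLayer) -> float:
    crop, (r0, c0) = _crop_mask(level.label_image, seg.bbox, seg.id)
    sub = layer.values[r0 : r0 + crop.shape[0], c0 : c0 + crop.shape[1]]
    return float(sub[crop].mean())
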