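"""Full-resolution stain separation and nuclei detection inside lobules.

RGB pixels are mapped to optical densities (Beer-Lambert), then to the
hue-saturation-density plane: total density D is the channel-average OD and
the chromatic point is the OD vector normalized by D. Per-stain densities
follow by decomposing the chromatic point onto the hematoxylin and DAB
reference directions and scaling by D. Nuclear regions are thresholded per
stain, split by watershed, cut at significant concave dents, smoothed, and
area-filtered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import find_contours
from skimage.draw import polygon2mask
from skimage.segmentation import watershed

from .rasters import RGBRaster, RasterLayer

DEFAULT_STAIN_THRESHOLD = 0.2
DEFAULT_MIN_NUCLEUS_AREA_PX = 30  # ~9.4 um^2 at 0.56 um/pixel
DEFAULT_DENT_ANGLE_DEG = 30.0

#: Standard hematoxylin / DAB optical-density directions (R, G, B).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DAB_OD = (0.268, 0.570, 0.776)


def _chroma(od: np.ndarray) -> np.ndarray:
    """Chromatic (c_x, c_y) coordinates of OD vectors with positive mean."""
    od = np.asarray(od, dtype=float)
    d = od.mean(axis=-1, keepdims=True)
    cx = od[..., 0:1] / d - 1.0
    cy = (od[..., 1:2] - od[..., 2:3]) / (math.sqrt(3.0) * d)
    return np.concatenate([cx, cy], axis=-1)


@dataclass
class StainReference:
    """Background intensity and stain chromatic references for deconvolution."""

    background_intensity: tuple[float, float, float] = (255.0, 255.0, 255.0)
    hematoxylin_od: tuple[float, float, float] = HEMATOXYLIN_OD
    dab_od: tuple[float, float, float] = DAB_OD

    def __post_init__(self) -> None:
        if any(i0 <= 0 for i0 in self.background_intensity):
            raise ValueError("background intensity must be positive per channel")
        ch = _chroma(np.asarray(self.hematoxylin_od))
        cd = _chroma(np.asarray(self.dab_od))
        if abs(ch[0] * cd[1] - ch[1] * cd[0]) < 1e-9 and np.allclose(ch, cd):
            raise ValueError("stain chromatic references are collinear")
        self.hema_chroma = tuple(ch.tolist())
        self.dab_chroma = tuple(cd.tolist())


@dataclass
class DensityLayers:
    """Per-stain density images (DAB and hematoxylin), clamped to >= 0."""

    dab: RasterLayer
    hema: RasterLayer
    n_clamped_pixels: int = 0


@dataclass
class Nucleus:
    """A connected full-resolution nuclear object.

    The mask is a tight crop; ``offset`` locates its (0, 0) corner on the
    tile grid and ``centroid`` is in tile coordinates.
    """

    mask: np.ndarray  # (h, w) bool crop
    area_px: int
    centroid: tuple[float, float]
    stain_class: str  # "positive" (DAB) | "negative" (hematoxylin)
    offset: tuple[int, int] = (0, 0)


def hsd_deconvolve(tile: RGBRaster, ref: StainReference | None = None) -> DensityLayers:
    """Separate DAB and hematoxylin densities with the HSD model.

    Optical density per channel is -ln(I/I0); the chromatic point of each
    pixel is decomposed onto the two stain reference directions and the
    coefficients are scaled by the total density. Negative projections are
    clamped to zero. Zero-intensity pixels are clamped to 1 intensity unit
    before the log and counted.
    """
    if ref is None:
        ref = StainReference()
    i0 = np.asarray(ref.background_intensity, dtype=float)
    pixels = tile.pixels.astype(np.float64)
    n_clamped = int(np.sum(pixels <= 0))
    pixels = np.maximum(pixels, 1.0)
    od = -np.log(pixels / i0)
    od = np.maximum(od, 0.0)
    d = od.mean(axis=2)

    # decompose chroma onto the stain directions: chroma = p_h*c_h + p_d*c_d
    m = np.array([[ref.hema_chroma[0], ref.dab_chroma[0]],
                  [ref.hema_chroma[1], ref.dab_chroma[1]]])
    minv = np.linalg.inv(m)
    safe_d = np.where(d > 1e-12, d, 1.0)
    cx = od[:, :, 0] / safe_d - 1.0
    cy = (od[:, :, 1] - od[:, :, 2]) / (math.sqrt(3.0) * safe_d)
    p_h = minv[0, 0] * cx + minv[0, 1] * cy
    p_d = minv[1, 0] * cx + minv[1, 1] * cy
    hema = np.clip(p_h, 0.0, None) * d
    dab = np.clip(p_d, 0.0, None) * d
    zero = d <= 1e-12
    hema[zero] = 0.0
    dab[zero] = 0.0
    return DensityLayers(
        dab=RasterLayer(dab, tile.pixel_size_um),
        hema=RasterLayer(hema, tile.pixel_size_um),
        n_clamped_pixels=n_clamped,
    )


def nuclear_regions(
    layers: DensityLayers, threshold: float = DEFAULT_STAIN_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Preliminary nuclear masks: density above threshold and dominant over
    the other stain. The two masks are disjoint by construction."""
    dab = layers.dab.values
    hema = layers.hema.values
    mask_dab = (dab > threshold) & (dab > hema)
    mask_hema = (hema > threshold) & (hema > dab)
    return mask_dab, mask_hema


def split_nuclei(
    mask: np.ndarray,
    density: RasterLayer,
    min_area_px: int = DEFAULT_MIN_NUCLEUS_AREA_PX,
    stain_class: str = "positive",
    peak_min_distance: int = 11,
    smooth_window: int = 9,
) -> list[Nucleus]:
    """Separate touching nuclei by watershed on the stain density.

    Basins are seeded at local maxima of the Gaussian-smoothed density
    (minimum peak separation ``peak_min_distance``); objects below
    ``min_area_px`` are discarded and holes are filled.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    sigma = (smooth_window - 1) / 6.0
    smooth = ndimage.gaussian_filter(density.values, sigma=sigma, radius=(smooth_window - 1) // 2)
    peaks = peak_local_max(smooth, min_distance=peak_min_distance, labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(mask)
    else:
        labels = watershed(-smooth, markers=markers, mask=mask)
        # pixels of the mask not reached from any marker: keep as own objects
        orphan = mask & (labels == 0)
        if orphan.any():
            extra, n = ndimage.label(orphan)
            labels = labels + np.where(orphan, extra + labels.max(), 0)
    return _objects_from_labels(labels, min_area_px, stain_class)


def _objects_from_labels(labels: np.ndarray, min_area_px: int, stain_class: str) -> list[Nucleus]:
    out = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, labels.max() + 1)):
        if sl is None:
            continue
        local = labels[sl] == lab
        # a watershed basin can be disconnected in rare cases; keep pieces separate
        comp, n = ndimage.label(local)
        for k in range(1, n + 1):
            piece = ndimage.binary_fill_holes(comp == k)
            area = int(piece.sum())
            if area >= min_area_px:
                out.append(_make_nucleus(piece, (sl[0].start, sl[1].start), stain_class))
    return out


def _make_nucleus(crop: np.ndarray, offset: tuple[int, int], stain_class: str) -> Nucleus:
    """Build a Nucleus from a crop-local mask, re-tightening the bbox."""
    rr, cc = np.nonzero(crop)
    r0, r1 = int(rr.min()), int(rr.max()) + 1
    c0, c1 = int(cc.min()), int(cc.max()) + 1
    tight = crop[r0:r1, c0:c1]
    off = (offset[0] + r0, offset[1] + c0)
    return Nucleus(
        tight,
        int(tight.sum()),
        (off[0] + float(rr.mean()) - r0, off[1] + float(cc.mean()) - c0),
        stain_class,
        off,
    )


# ---------------------------------------------------------------------------
# Dent cutting


def dent_cut(
    nucleus: Nucleus,
    max_tangent_angle_deg: float = DEFAULT_DENT_ANGLE_DEG,
    min_area_px: int = DEFAULT_MIN_NUCLEUS_AREA_PX,
    simplify_tolerance: float = 1.0,
) -> list[Nucleus]:
    """Cut a nucleus at significant concave dents.

    The contour is simplified (Douglas-Peucker) to a polygon; vertices whose
    concave turning exceeds the angle threshold are significant dents. With
    at least two dents the object is cut along the shortest interior chord
    joining two dents, recursively; fragments below the minimum area are
    discarded. Convex objects are returned unchanged.
    """
    from shapely.geometry import LineString, Polygon

    masks = _dent_cut_mask(
        nucleus.mask, max_tangent_angle_deg, min_area_px, simplify_tolerance
    )
    if len(masks) == 1:
        return [nucleus]
    return [_make_nucleus(m, nucleus.offset, nucleus.stain_class) for m in masks]


def _dent_cut_mask(
    mask: np.ndarray, max_angle: float, min_area: int, tol: float
) -> list[np.ndarray]:
    from shapely.geometry import LineString, Polygon

    poly = _mask_polygon(mask, tol)
    if poly is None:
        return [mask]
    dents = _significant_dents(poly, max_angle)
    if len(dents) < 2:
        return [mask]
    # shortest interior chord between two dents
    best = None
    for i in range(len(dents)):
        for j in range(i + 1, len(dents)):
            a, b = dents[i], dents[j]
            chord = LineString([a, b])
            if chord.length < 1e-9:
                continue
            if not chord.covered_by(poly):
                continue
            if best is None or chord.length < best.length:
                best = chord
    if best is None:
        return [mask]
    (ar, ac), (br, bc) = list(best.coords)
    # rasterize the cut: remove pixels within half a pixel of the chord
    halves = _split_by_chord(mask, (ar, ac), (br, bc))
    if halves is None:
        return [mask]
    out: list[np.ndarray] = []
    for piece in halves:
        if int(piece.sum()) < min_area:
            continue
        out.extend(_dent_cut_mask(piece, max_angle, min_area, tol))
    return out if out else [mask]


def _mask_polygon(mask: np.ndarray, tol: float):
    from shapely.geometry import Polygon

    contours = find_contours(np.pad(mask.astype(float), 1), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len) - 1.0  # undo padding offset
    if len(contour) < 4:
        return None
    poly = Polygon(contour)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.is_empty or poly.geom_type != "Polygon":
            return None
    poly = poly.simplify(tol, preserve_topology=True)
    if poly.is_empty or poly.geom_type != "Polygon":
        return None
    return poly


def _significant_dents(poly, max_angle: float) -> list[tuple[float, float]]:
    """Vertices of the polygon whose inward (concave) turning exceeds the
    angle threshold."""
    coords = np.asarray(poly.exterior.coords[:-1])
    n = len(coords)
    if n < 4:
        return []
    # signed area > 0 means counterclockwise in (row, col) convention
    x, y = coords[:, 0], coords[:, 1]
    signed = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    ccw = signed > 0
    dents = []
    for i in range(n):
        p0 = coords[(i - 1) % n]
        p1 = coords[i]
        p2 = coords[(i + 1) % n]
        v1 = p1 - p0
        v2 = p2 - p1
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        dot = float(np.dot(v1, v2))
        turn = math.degrees(math.atan2(abs(cross), dot))
        concave = (cross < 0) if ccw else (cross > 0)
        if concave and turn > max_angle:
            dents.append((float(p1[0]), float(p1[1])))
    return dents


def _split_by_chord(mask: np.ndarray, a: tuple[float, float], b: tuple[float, float]):
    """Split the mask into the connected pieces on either side of the chord."""
    h, w = mask.shape
    rr, cc = np.nonzero(mask)
    # distance from each pixel center to the segment a-b
    pa = np.stack([rr - a[0], cc - a[1]], axis=1).astype(float)
    ab = np.array([b[0] - a[0], b[1] - a[1]])
    t = np.clip((pa @ ab) / (ab @ ab), 0.0, 1.0)
    proj = np.stack([a[0] + t * ab[0], a[1] + t * ab[1]], axis=1)
    dist = np.hypot(rr - proj[:, 0], cc - proj[:, 1])
    cut = dist <= 0.7
    kept = mask.copy()
    kept[rr[cut], cc[cut]] = False
    labels, n = ndimage.label(kept)
    if n < 2:
        return None
    pieces = []
    for k in range(1, n + 1):
        piece = labels == k
        # reassign cut-line pixels to the nearest piece so no area is lost
        pieces.append(piece)
    # give each removed pixel to the nearest piece (by erosion distance)
    removed_r, removed_c = rr[cut], cc[cut]
    if removed_r.size:
        dist_maps = [ndimage.distance_transform_edt(~p) for p in pieces]
        stack = np.stack([dm[removed_r, removed_c] for dm in dist_maps])
        owner = np.argmin(stack, axis=0)
        for k, piece in enumerate(pieces):
            sel = owner == k
            piece[removed_r[sel], removed_c[sel]] = True
    return pieces


# ---------------------------------------------------------------------------
# Post-processing and per-lobule positivity


def postprocess_nuclei(
    nuclei: list[Nucleus],
    min_area_px: int = DEFAULT_MIN_NUCLEUS_AREA_PX,
    tile_shape: tuple[int, int] | None = None,
) -> list[Nucleus]:
    """Smooth borders with a 3x3 morphological open-close, re-apply the
    minimum-area filter, and keep masks disjoint (earlier nuclei win any
    overlap created by closing)."""
    se = np.ones((3, 3), dtype=bool)
    if tile_shape is None and nuclei:
        tile_shape = (
            max(n.offset[0] + n.mask.shape[0] for n in nuclei) + 2,
            max(n.offset[1] + n.mask.shape[1] for n in nuclei) + 2,
        )
    claimed = np.zeros(tile_shape, dtype=bool) if tile_shape else None
    out = []
    for nuc in nuclei:
        padded = np.pad(nuc.mask, 2, constant_values=False)
        m = ndimage.binary_opening(padded, structure=se)
        m = ndimage.binary_closing(m, structure=se)
        m = ndimage.binary_fill_holes(m)
        rr, cc = np.nonzero(m)
        if rr.size == 0:
            continue
        off = (nuc.offset[0] - 2, nuc.offset[1] - 2)
        # clip against already-claimed tile pixels and the tile bounds
        h, w = claimed.shape
        sel_r = np.clip(rr + off[0], 0, h - 1)
        sel_c = np.clip(cc + off[1], 0, w - 1)
        valid = (rr + off[0] >= 0) & (rr + off[0] < h) & (cc + off[1] >= 0) & (cc + off[1] < w)
        free = valid.copy()
        free[valid] = ~claimed[sel_r[valid], sel_c[valid]]
        m[rr[~free], cc[~free]] = False
        area = int(m.sum())
        if area < min_area_px:
            continue
        claimed[sel_r[free], sel_c[free]] = True
        out.append(_make_nucleus(m, off, nuc.stain_class))
    return out


@dataclass
class NucleiConfig:
    stain_threshold: float = DEFAULT_STAIN_THRESHOLD
    min_nucleus_area_px: int = DEFAULT_MIN_NUCLEUS_AREA_PX
    dent_angle_deg: float = DEFAULT_DENT_ANGLE_DEG
    peak_min_distance: int = 11
    smooth_window: int = 9


def detect_nuclei_in_tile(
    tile: RGBRaster,
    roi_mask: np.ndarray | None = None,
    ref: StainReference | None = None,
    config: NucleiConfig | None = None,
) -> list[Nucleus]:
    """Full nuclei pipeline on one tile: deconvolve, threshold, watershed,
    dent-cut, smooth, filter. ``roi_mask`` restricts detection to the lobule."""
    config = config or NucleiConfig()
    layers = hsd_deconvolve(tile, ref)
    mask_dab, mask_hema = nuclear_regions(layers, config.stain_threshold)
    if roi_mask is not None:
        mask_dab &= roi_mask
        mask_hema &= roi_mask
    nuclei: list[Nucleus] = []
    for mask, density, cls in (
        (mask_dab, layers.dab, "positive"),
        (mask_hema, layers.hema, "negative"),
    ):
        raw = split_nuclei(
            mask,
            density,
            config.min_nucleus_area_px,
            cls,
            peak_min_distance=config.peak_min_distance,
            smooth_window=config.smooth_window,
        )
        cut: list[Nucleus] = []
        for nuc in raw:
            cut.extend(dent_cut(nuc, config.dent_angle_deg, config.min_nucleus_area_px))
        nuclei.extend(postprocess_nuclei(cut, config.min_nucleus_area_px, tile.shape))
    return nuclei


def lobule_positivity(
    lobule_mask_working: np.ndarray,
    full_res_image: RGBRaster,
    working_pixel_size_um: float,
    ref: StainReference | None = None,
    config: NucleiConfig | None = None,
) -> tuple[int, int, float | None, list[Nucleus], tuple[int, int]]:
    """Counts of positive (DAB) and negative (hematoxylin) nuclei inside one
    lobule, processed at full resolution.

    The working-resolution lobule mask is upsampled (nearest neighbor) onto
    the full-resolution grid and used as region of interest. Returns
    ``(n_pos, n_neg, ratio, nuclei, tile_offset)``; the ratio is ``None``
    when no nuclei are detected.
    """
    factor = working_pixel_size_um / full_res_image.pixel_size_um
    rr, cc = np.nonzero(lobule_mask_working)
    h, w = full_res_image.shape
    r0 = max(int(rr.min() * factor), 0)
    r1 = min(int((rr.max() + 1) * factor) + 1, h)
    c0 = max(int(cc.min() * factor), 0)
    c1 = min(int((cc.max() + 1) * factor) + 1, w)
    tile = RGBRaster(full_res_image.pixels[r0:r1, c0:c1], full_res_image.pixel_size_um)
    # nearest-neighbor upsample of the mask onto the tile grid
    tr = np.clip(((np.arange(r0, r1) + 0.5) / factor - 0.5).round().astype(int), 0,
                 lobule_mask_working.shape[0] - 1)
    tc = np.clip(((np.arange(c0, c1) + 0.5) / factor - 0.5).round().astype(int), 0,
                 lobule_mask_working.shape[1] - 1)
    roi = lobule_mask_working[np.ix_(tr, tc)]
    nuclei = detect_nuclei_in_tile(tile, roi, ref, config)
    n_pos = sum(1 for n in nuclei if n.stain_class == "positive")
    n_neg = sum(1 for n in nuclei if n.stain_class == "negative")
    total = n_pos + n_neg
    ratio = n_pos / total if total else None
    return n_pos, n_neg, ratio, nuclei, (r0, c0)
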