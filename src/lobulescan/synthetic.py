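"""Synthetic brightfield slides with exact ground truth.

A slide is rendered at full resolution through a Beer-Lambert optical
density model: a white background, faintly textured eosin stroma, a
coherent irregular tumor blob (dense sheet of hematoxylin nuclei of
intermediate working-resolution texture), and round lobules built from
tubules — rings of nuclei around lumens — whose nuclei are hematoxylin
(negative) or DAB (positive) absorbers with a configurable positive
fraction per distance band. Because rendering composes optical densities
additively and exponentiates, the HSD deconvolution has an exact inverse
on noise-free pixels.

All randomness flows from one seed through deterministic substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .rasters import RGBRaster
from .stain_nuclei import HEMATOXYLIN_OD, DAB_OD

EOSIN_OD = (0.07, 0.99, 0.11)


@dataclass
class BandSpec:
    """Placement band for lobules at a given distance range from tumor."""

    name: str
    distance_range_mm: tuple[float, float]
    n_lobules: int
    positive_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in [0, 1]")


DEFAULT_BANDS = (
    BandSpec("adjacent", (0.22, 0.46), 4, 0.05),
    BandSpec("intermediate", (0.9, 1.7), 4, 0.10),
    BandSpec("distant", (2.1, 2.45), 4, 0.15),
)


@dataclass
class SyntheticConfig:
    shape_full: tuple[int, int] = (4600, 7000)
    pixel_size_um: float = 0.56
    working_scale: float = 0.1
    seed: int = 0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    margin_px: int = 260
    #: width (full-res px) over which stroma absorption fades to background
    #: at the tissue boundary; a hard edge would ring in the texture layer
    tissue_edge_feather_px: float = 90.0

    # lobule / tubule geometry (microns)
    lobule_radius_um: float = 200.0
    tubules_per_lobule: int = 15
    tubule_radius_um: float = 20.0
    nuclei_per_ring: int = 16
    interstitial_nuclei_per_lobule: int = 900
    nucleus_radius_um: float = 3.6
    #: epithelial cytoplasm absorption over the whole lobule disk; fills the
    #: space between tubules so the lobule is spectrally coherent instead of
    #: stroma-colored gaps between dark rings
    lobule_base_eosin_od: float = 0.0
    lobule_base_hema_od: float = 0.18
    #: depth (full-res px) of the azimuthal scalloping of the nucleus extent
    lobule_scallop_px: float = 50.0
    #: width (full-res px) of the linear ramp feathering the cytoplasm edge;
    #: a hard step would itself read as texture at the working resolution
    lobule_edge_feather_px: float = 15.0
    #: nucleus-free margin inside the lobule edge (full-res px): keeps the
    #: texture transition inside the stained disk so the rim merges with the
    #: lobule rather than forming a separate halo ring
    lobule_quiet_rim_px: float = 0.0

    # tumor geometry
    tumor: bool = True
    tumor_center_col_mm: float = 0.35  # from tissue left edge
    tumor_half_width_mm: float = 0.55
    tumor_irregularity: float = 0.18
    tumor_nucleus_coverage: float = 0.62
    #: low-frequency modulation of the tumor nucleus coverage; gives the
    #: tumor mesoscale heterogeneity so it splits into many mid-sized
    #: segments (as real tumor does) instead of one uniform region
    tumor_coverage_amplitude: float = 0.0
    tumor_patch_px: int = 200

    # stain strengths (Beer-Lambert concentrations on unit OD vectors)
    hema_conc_lobule: float = 0.6
    dab_conc_lobule: float = 0.8
    hema_conc_tumor: float = 0.18
    stroma_od: float = 0.55
    stroma_noise_od: float = 0.03
    #: sparse fibroblast nuclei in the stroma; they give the stroma its own
    #: mild texture variance so segmentation does not treat every faint
    #: transition zone as a foreign object against razor-flat background
    fibro_coverage: float = 0.055
    fibro_radius_um: float = 2.8
    fibro_conc: float = 0.45
    fibro_min_sep_factor: float = 2.8
    noise_od: float = 0.015
    background_od: float = 0.008

    # failure-mode emulation: dense small extra nuclei inside lobules
    lobulitis: bool = False
    lobulitis_nuclei_per_lobule: int = 1100
    lobulitis_nucleus_radius_um: float = 2.6

    max_placement_retries: int = 2000

    @property
    def working_pixel_size_um(self) -> float:
        return self.pixel_size_um / self.working_scale


@dataclass
class GTLobule:
    id: int
    band: str
    centroid_full: tuple[float, float]
    radius_px_full: float
    n_nuclei: int
    n_positive: int
    distance_mm: float

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_nuclei


@dataclass
class GroundTruth:
    lobules: list[GTLobule]
    lobule_label_full: np.ndarray  # uint16, 0 = none
    tumor_mask_full: np.ndarray  # bool
    tissue_mask_full: np.ndarray  # bool
    config: SyntheticConfig

    def lobule_label_working(self) -> np.ndarray:
        return _downsample_nearest(self.lobule_label_full, self.config.working_scale)

    def tumor_mask_working(self) -> np.ndarray:
        return _downsample_nearest(self.tumor_mask_full, self.config.working_scale)

    def tissue_mask_working(self) -> np.ndarray:
        return _downsample_nearest(self.tissue_mask_full, self.config.working_scale)


def _downsample_nearest(arr: np.ndarray, scale: float) -> np.ndarray:
    h, w = arr.shape[:2]
    oh, ow = int(h * scale), int(w * scale)
    rows = np.clip(np.round((np.arange(oh) + 0.5) / scale - 0.5).astype(int), 0, h - 1)
    cols = np.clip(np.round((np.arange(ow) + 0.5) / scale - 0.5).astype(int), 0, w - 1)
    return arr[np.ix_(rows, cols)]


def _draw_disks(field: np.ndarray, centers: np.ndarray, radius: float, value: float) -> None:
    """Add ``value`` inside a disk of ``radius`` around each center."""
    if len(centers) == 0:
        return
    r_int = int(math.ceil(radius))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disk = (yy**2 + xx**2) <= radius**2
    h, w = field.shape
    size = 2 * r_int + 1
    for r, c in np.asarray(centers, dtype=int):
        r0, c0 = r - r_int, c - r_int
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r0 + size, h), min(c0 + size, w)
        if rs >= re or cs >= ce:
            continue
        field[rs:re, cs:ce][disk[rs - r0 : re - r0, cs - c0 : ce - c0]] += value


def generate_slide(config: SyntheticConfig | None = None) -> tuple[RGBRaster, GroundTruth]:
    """Render a synthetic slide and its exact ground truth."""
    cfg = config or SyntheticConfig()
    h, w = cfg.shape_full
    px = cfg.pixel_size_um
    mm = 1000.0 / px  # full-res pixels per mm
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_tumor = np.random.default_rng(seeds[0])
    rng_place = np.random.default_rng(seeds[1])
    rng_nuclei = np.random.default_rng(seeds[2])
    rng_noise = np.random.default_rng(seeds[3])

    m = cfg.margin_px
    tissue = np.zeros((h, w), dtype=bool)
    tissue[m : h - m, m : w - m] = True

    tumor = np.zeros((h, w), dtype=bool)
    if cfg.tumor:
        tumor = _tumor_blob(cfg, tissue, rng_tumor)

    # distance map (mm) to the tumor border, at working resolution for speed
    tumor_w = _downsample_nearest(tumor, cfg.working_scale)
    if tumor_w.any():
        dist_w = ndimage.distance_transform_edt(~tumor_w) * cfg.working_pixel_size_um / 1000.0
    else:
        dist_w = np.full(tumor_w.shape, np.inf)

    lobule_radius = cfg.lobule_radius_um / px
    placements = _place_lobules(cfg, tissue, dist_w, lobule_radius, rng_place)

    # concentration fields
    c_h = np.zeros((h, w), dtype=np.float32)
    c_d = np.zeros((h, w), dtype=np.float32)
    c_e = np.zeros((h, w), dtype=np.float32)
    edge = np.minimum.outer(
        np.minimum(np.arange(h) - m, h - 1 - m - np.arange(h)),
        np.minimum(np.arange(w) - m, w - 1 - m - np.arange(w)),
    ).astype(np.float32)
    tissue_ramp = np.clip((edge + 1.0) / max(cfg.tissue_edge_feather_px, 1e-6), 0.0, 1.0)
    tissue_ramp[~tissue] = 0.0
    c_e += cfg.stroma_od * tissue_ramp
    lowfreq = ndimage.gaussian_filter(
        rng_noise.standard_normal((h // 8 + 1, w // 8 + 1), dtype=np.float32), 6.0
    )
    lowfreq = np.kron(lowfreq, np.ones((8, 8), dtype=np.float32))[:h, :w]
    c_e += (tissue_ramp * (cfg.stroma_noise_od / max(lowfreq.std(), 1e-6)) * lowfreq).astype(
        np.float32
    )

    if tumor.any():
        _render_tumor_nuclei(cfg, tumor, c_h, rng_nuclei)
    _render_stroma_fibroblasts(cfg, tissue, tumor, placements, lobule_radius, c_h, rng_nuclei)

    lobule_label = np.zeros((h, w), dtype=np.uint16)
    gt_lobules: list[GTLobule] = []
    for i, (band, (r, c)) in enumerate(placements, start=1):
        n_total, n_pos = _render_lobule(cfg, (r, c), lobule_radius, band, c_h, c_d, c_e, rng_nuclei)
        _draw_label_disk(lobule_label, (r, c), lobule_radius, i)
        d_mm = float(dist_w[int(r * cfg.working_scale), int(c * cfg.working_scale)])
        gt_lobules.append(
            GTLobule(i, band.name, (float(r), float(c)), lobule_radius, n_total, n_pos, d_mm)
        )

    pixels = _expose(cfg, tissue, c_h, c_d, c_e, rng_noise)
    image = RGBRaster(pixels, px)
    truth = GroundTruth(gt_lobules, lobule_label, tumor, tissue, cfg)
    return image, truth


def _tumor_blob(cfg: SyntheticConfig, tissue: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.shape_full
    mm = 1000.0 / cfg.pixel_size_um
    cr = h / 2.0
    cc = cfg.margin_px + cfg.tumor_center_col_mm * mm
    ar = h / 2.0 - 1.6 * cfg.margin_px
    ac = cfg.tumor_half_width_mm * mm
    rr = (np.arange(h, dtype=np.float32)[:, None] - cr) / ar
    ccol = (np.arange(w, dtype=np.float32)[None, :] - cc) / ac
    radial = np.sqrt(rr**2 + ccol**2)
    rough = ndimage.gaussian_filter(
        rng.standard_normal((h // 16 + 1, w // 16 + 1), dtype=np.float32), 8.0
    )
    rough = np.kron(rough, np.ones((16, 16), dtype=np.float32))[:h, :w]
    rough = rough / max(rough.std(), 1e-6)
    blob = (radial <= 1.0 + cfg.tumor_irregularity * rough) & tissue
    labels, n = ndimage.label(blob)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        blob = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(blob)


def _place_lobules(
    cfg: SyntheticConfig,
    tissue: np.ndarray,
    dist_w: np.ndarray,
    radius: float,
    rng: np.random.Generator,
) -> list[tuple[BandSpec, tuple[float, float]]]:
    h, w = cfg.shape_full
    m = cfg.margin_px
    placed: list[tuple[BandSpec, tuple[float, float]]] = []
    gap = 0.12 * radius
    for band in cfg.bands:
        lo, hi = band.distance_range_mm
        for k in range(band.n_lobules):
            ok = False
            for _ in range(cfg.max_placement_retries):
                r = rng.uniform(m + radius + gap, h - m - radius - gap)
                c = rng.uniform(m + radius + gap, w - m - radius - gap)
                d = dist_w[int(r * cfg.working_scale), int(c * cfg.working_scale)]
                if not (lo <= d <= hi):
                    continue
                if any(
                    math.hypot(r - pr, c - pc) < 2 * radius + gap for _, (pr, pc) in placed
                ):
                    continue
                placed.append((band, (r, c)))
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place lobule {k + 1} of band {band.name!r} after "
                    f"{cfg.max_placement_retries} retries; enlarge the image or relax the bands"
                )
    return placed


def _render_tumor_nuclei(
    cfg: SyntheticConfig, tumor: np.ndarray, c_h: np.ndarray, rng: np.random.Generator
) -> None:
    px = cfg.pixel_size_um
    h, w = tumor.shape
    nucleus_r = cfg.nucleus_radius_um / px
    area = float(tumor.sum())
    # patchy coverage field: base +/- low-frequency modulation
    step = cfg.tumor_patch_px
    grid = rng.standard_normal((h // step + 2, w // step + 2), dtype=np.float32)
    grid = ndimage.gaussian_filter(grid, 1.0)
    grid /= max(grid.std(), 1e-6)
    coverage = np.clip(
        cfg.tumor_nucleus_coverage + cfg.tumor_coverage_amplitude * grid, 0.12, 0.95
    )
    n_max = int(coverage.max() * area / (math.pi * nucleus_r**2))
    rr, cc = np.nonzero(tumor)
    idx = rng.integers(0, len(rr), size=n_max)
    keep_p = coverage[rr[idx] // step, cc[idx] // step] / coverage.max()
    sel = rng.uniform(size=n_max) < keep_p
    centers = np.stack([rr[idx][sel], cc[idx][sel]], axis=1)
    _draw_disks(c_h, centers, nucleus_r, cfg.hema_conc_tumor)


def _render_stroma_fibroblasts(
    cfg: SyntheticConfig,
    tissue: np.ndarray,
    tumor: np.ndarray,
    placements,
    lobule_radius: float,
    c_h: np.ndarray,
    rng: np.random.Generator,
) -> None:
    if cfg.fibro_coverage <= 0:
        return
    px = cfg.pixel_size_um
    r_n = cfg.fibro_radius_um / px
    stroma = tissue & ~tumor
    area = float(stroma.sum())
    n = int(cfg.fibro_coverage * area / (math.pi * r_n**2))
    rr, cc = np.nonzero(stroma)
    # Poisson-disk-like thinning: sample generously, then enforce a minimum
    # separation on a coarse grid so the stroma texture is even — local
    # fibroblast clumps would read as texture hotspots next to lobules
    idx = rng.integers(0, len(rr), size=3 * n)
    pts = np.stack([rr[idx], cc[idx]], axis=1).astype(float)
    keep = np.ones(len(pts), dtype=bool)
    for _, (lr, lc) in placements:
        keep &= np.hypot(pts[:, 0] - lr, pts[:, 1] - lc) > lobule_radius + 30.0
    pts = pts[keep]
    min_sep = cfg.fibro_min_sep_factor * r_n
    cell = min_sep / math.sqrt(2.0)
    grid: set[tuple[int, int]] = set()
    chosen = []
    for r, c in pts:
        gr, gc = int(r / cell), int(c / cell)
        if any(
            (gr + dr, gc + dc) in grid for dr in (-2, -1, 0, 1, 2) for dc in (-2, -1, 0, 1, 2)
        ):
            continue
        grid.add((gr, gc))
        chosen.append((r, c))
        if len(chosen) >= n:
            break
    _draw_disks(c_h, np.asarray(chosen), r_n, cfg.fibro_conc)


def _render_lobule(
    cfg: SyntheticConfig,
    center: tuple[float, float],
    radius: float,
    band: BandSpec,
    c_h: np.ndarray,
    c_d: np.ndarray,
    c_e: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Render one lobule as a cluster of tubules in epithelial cytoplasm,
    with interstitial nuclei between tubules; returns (n_nuclei, n_pos)."""
    px = cfg.pixel_size_um
    tub_r = cfg.tubule_radius_um / px
    nuc_r = cfg.nucleus_radius_um / px
    footprint = tub_r + nuc_r
    inner = radius - footprint - cfg.lobule_quiet_rim_px - 2.0
    # cytoplasm base over the whole disk, feathered at the edge
    _draw_feathered_disk(c_e, center, radius, cfg.lobule_base_eosin_od, cfg.lobule_edge_feather_px)
    _draw_feathered_disk(c_h, center, radius, cfg.lobule_base_hema_od, cfg.lobule_edge_feather_px)
    # scalloped nucleus extent: alternating textured and quiet boundary arcs
    # keep the smoothed-texture transition from coalescing into a coherent
    # ring object around the lobule
    k1, k2 = rng.integers(5, 8), rng.integers(9, 13)
    ph1, ph2 = rng.uniform(0, 2 * math.pi, size=2)
    amp = cfg.lobule_scallop_px

    def _extent(theta: float) -> float:
        mod = 0.5 + 0.35 * math.sin(k1 * theta + ph1) + 0.15 * math.sin(k2 * theta + ph2)
        return radius - 10.0 - amp * mod
    tubules: list[tuple[float, float]] = []
    attempts = 0
    while len(tubules) < cfg.tubules_per_lobule:
        attempts += 1
        if attempts > cfg.max_placement_retries * 5:
            raise RuntimeError("could not place tubules inside lobule; geometry too tight")
        rho = inner * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * math.pi)
        r = center[0] + rho * math.cos(theta)
        c = center[1] + rho * math.sin(theta)
        if any(math.hypot(r - tr, c - tc) < 2 * footprint + 2.0 for tr, tc in tubules):
            continue
        tubules.append((r, c))

    nuclei: list[tuple[float, float]] = []
    for tr, tc in tubules:
        phase = rng.uniform(0, 2 * math.pi)
        for j in range(cfg.nuclei_per_ring):
            ang = phase + 2 * math.pi * j / cfg.nuclei_per_ring
            jitter = rng.uniform(-0.08, 0.08)
            rad = tub_r * (1 + jitter)
            nr, nc = tr + rad * math.cos(ang), tc + rad * math.sin(ang)
            rho_n = math.hypot(nr - center[0], nc - center[1])
            if rho_n <= _extent(math.atan2(nc - center[1], nr - center[0])):
                nuclei.append((nr, nc))
    # interstitial epithelial nuclei: pack the space between tubule rings
    # to saturation under a minimum-separation constraint, so the lobule
    # interior is a statistically uniform nucleus carpet (internal density
    # gaps would segment as separate low-texture objects)
    min_sep = 2.4 * nuc_r
    cell = min_sep / math.sqrt(2.0)
    grid: dict[tuple[int, int], tuple[float, float]] = {}
    for r, c in nuclei:
        grid[(int(r / cell), int(c / cell))] = (r, c)

    def _free(r: float, c: float) -> bool:
        gr, gc = int(r / cell), int(c / cell)
        for dr in (-2, -1, 0, 1, 2):
            for dc in (-2, -1, 0, 1, 2):
                p = grid.get((gr + dr, gc + dc))
                if p is not None and math.hypot(p[0] - r, p[1] - c) < min_sep:
                    return False
        return True

    tries = 0
    n_interstitial = 0
    max_tries = cfg.max_placement_retries * 25
    while n_interstitial < cfg.interstitial_nuclei_per_lobule and tries < max_tries:
        tries += 1
        rho = (radius - nuc_r - 1.0) * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * math.pi)
        if rho > _extent(theta):
            continue
        r = center[0] + rho * math.cos(theta)
        c = center[1] + rho * math.sin(theta)
        if any(math.hypot(r - tr, c - tc) < tub_r - nuc_r for tr, tc in tubules):
            continue  # inside a lumen
        if not _free(r, c):
            continue
        grid[(int(r / cell), int(c / cell))] = (r, c)
        nuclei.append((r, c))
        n_interstitial += 1
    # trim to a multiple of 20 so the configured positive fractions
    # (multiples of 5%) are exactly representable
    while len(nuclei) % 20:
        nuclei.pop()
    n_total = len(nuclei)
    n_pos = int(round(band.positive_fraction * n_total))
    # spatially stratified positive assignment: order nuclei by angle around
    # the lobule center and stride through them, so positives never clump
    # into one sector (a clump of strong DAB absorbers would split the
    # lobule's texture statistics in two)
    arr = np.asarray(nuclei)
    order = np.argsort(np.arctan2(arr[:, 0] - center[0], arr[:, 1] - center[1]))
    phase = rng.uniform()
    picks = (np.floor(phase * n_total / max(n_pos, 1) + np.arange(n_pos) * n_total / max(n_pos, 1)).astype(int)) % n_total
    pos_idx = set(int(order[k]) for k in picks)
    pos_centers = np.array([nuclei[i] for i in sorted(pos_idx)]) if n_pos else np.empty((0, 2))
    neg_centers = np.array([nuclei[i] for i in range(n_total) if i not in pos_idx])
    _draw_disks(c_d, pos_centers, nuc_r, cfg.dab_conc_lobule)
    _draw_disks(c_h, neg_centers, nuc_r, cfg.hema_conc_lobule)

    if cfg.lobulitis:
        extra = []
        small_r = cfg.lobulitis_nucleus_radius_um / px
        for _ in range(cfg.lobulitis_nuclei_per_lobule):
            rho = (radius - small_r) * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            extra.append((center[0] + rho * math.cos(theta), center[1] + rho * math.sin(theta)))
        _draw_disks(c_h, np.array(extra), small_r, cfg.hema_conc_lobule * 1.6)
    return n_total, n_pos


def _draw_feathered_disk(
    field: np.ndarray, center: tuple[float, float], radius: float, value: float, feather: float
) -> None:
    """Add ``value`` inside the disk, ramping linearly to zero over the last
    ``feather`` pixels of the radius."""
    h, w = field.shape
    r_int = int(math.ceil(radius)) + 1
    r0 = max(int(center[0]) - r_int, 0)
    r1 = min(int(center[0]) + r_int + 1, h)
    c0 = max(int(center[1]) - r_int, 0)
    c1 = min(int(center[1]) + r_int + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.sqrt((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
    ramp = np.clip((radius - d) / max(feather, 1e-6), 0.0, 1.0).astype(field.dtype)
    field[r0:r1, c0:c1] += value * ramp


def _draw_label_disk(label: np.ndarray, center: tuple[float, float], radius: float, value: int) -> None:
    h, w = label.shape
    r_int = int(math.ceil(radius))
    r0 = max(int(center[0]) - r_int, 0)
    r1 = min(int(center[0]) + r_int + 1, h)
    c0 = max(int(center[1]) - r_int, 0)
    c1 = min(int(center[1]) + r_int + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    label[r0:r1, c0:c1][disk] = value


def _expose(
    cfg: SyntheticConfig,
    tissue: np.ndarray,
    c_h: np.ndarray,
    c_d: np.ndarray,
    c_e: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = cfg.shape_full
    hv = np.asarray(HEMATOXYLIN_OD, dtype=np.float32) / np.linalg.norm(HEMATOXYLIN_OD)
    dv = np.asarray(DAB_OD, dtype=np.float32) / np.linalg.norm(DAB_OD)
    ev = np.asarray(EOSIN_OD, dtype=np.float32) / np.linalg.norm(EOSIN_OD)
    out = np.empty((h, w, 3), dtype=np.uint8)
    for ch in range(3):
        od = c_h * hv[ch] + c_d * dv[ch] + c_e * ev[ch] + np.float32(cfg.background_od)
        if cfg.noise_od > 0:
            od = od + rng.standard_normal((h, w), dtype=np.float32) * np.float32(cfg.noise_od)
        np.maximum(od, 0.0, out=od)
        intensity = 255.0 * np.exp(-od)
        out[:, :, ch] = np.clip(intensity, 1, 255).astype(np.uint8)
    return out


def render_working_view(
    slide: RGBRaster, truth: GroundTruth
) -> tuple[RGBRaster, dict[str, np.ndarray]]:
    """Nearest-neighbor working-resolution view of the slide and its masks."""
    from .preprocess import downsample

    cfg = truth.config
    image_w = downsample(slide, cfg.working_scale)
    masks = {
        "lobule_label": truth.lobule_label_working(),
        "tumor": truth.tumor_mask_working(),
        "tissue": truth.tissue_mask_working(),
    }
    return image_w, masks
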