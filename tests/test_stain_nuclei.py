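import math

import numpy as np
import pytest

from lobulescan.rasters import RGBRaster, RasterLayer
from lobulescan.stain_nuclei import (
    DAB_OD,
    HEMATOXYLIN_OD,
    Nucleus,
    StainReference,
    dent_cut,
    hsd_deconvolve,
    lobule_positivity,
    nuclear_regions,
    postprocess_nuclei,
    split_nuclei,
)

from conftest import disk_mask


def beer_lambert(c_hema, c_dab, shape=(1, 1), i0=255.0, unit=True):
    """Forward Beer-Lambert rendering with unit-normalized stain vectors."""
    hv = np.asarray(HEMATOXYLIN_OD) / np.linalg.norm(HEMATOXYLIN_OD)
    dv = np.asarray(DAB_OD) / np.linalg.norm(DAB_OD)
    od = c_hema * hv + c_dab * dv
    pixels = np.clip(i0 * np.exp(-od), 1, 255)
    tile = np.broadcast_to(pixels, (*shape, 3)).astype(np.float64)
    return RGBRaster(tile.copy(), 0.56)


class TestHSD:
    def test_background_zero_density(self):
        tile = RGBRaster(np.full((4, 4, 3), 255, dtype=np.uint8), 0.56)
        layers = hsd_deconvolve(tile)
        assert np.allclose(layers.dab.values, 0.0)
        assert np.allclose(layers.hema.values, 0.0)

    def test_dab_linearity(self):
        hv_mean = np.mean(np.asarray(DAB_OD) / np.linalg.norm(DAB_OD))
        densities = []
        for c in (0.2, 0.4, 0.8):
            layers = hsd_deconvolve(beer_lambert(0.0, c))
            assert np.allclose(layers.hema.values, 0.0, atol=1e-6)
            densities.append(layers.dab.values[0, 0])
        # dab density proportional to concentration (ratio matches within 1e-6)
        assert densities[1] / densities[0] == pytest.approx(2.0, abs=1e-6)
        assert densities[2] / densities[0] == pytest.approx(4.0, abs=1e-6)
        assert densities[0] == pytest.approx(0.2 * hv_mean, abs=1e-6)

    def test_mixed_pixel_roundtrip(self):
        hv = np.asarray(HEMATOXYLIN_OD) / np.linalg.norm(HEMATOXYLIN_OD)
        dv = np.asarray(DAB_OD) / np.linalg.norm(DAB_OD)
        layers = hsd_deconvolve(beer_lambert(0.5, 0.5))
        assert layers.dab.values[0, 0] > 0
        assert layers.hema.values[0, 0] > 0
        ratio = layers.dab.values[0, 0] / layers.hema.values[0, 0]
        assert ratio == pytest.approx(float(dv.mean() / hv.mean()), abs=1e-6)

    def test_exact_inversion_oracle(self):
        # forward-simulate a grid of mixtures and invert: relative error <=1e-6
        hv = np.asarray(HEMATOXYLIN_OD) / np.linalg.norm(HEMATOXYLIN_OD)
        dv = np.asarray(DAB_OD) / np.linalg.norm(DAB_OD)
        rng = np.random.default_rng(0)
        ch = rng.uniform(0.1, 1.5, size=(16, 16))
        cd = rng.uniform(0.1, 1.5, size=(16, 16))
        od = ch[..., None] * hv + cd[..., None] * dv
        tile = RGBRaster(255.0 * np.exp(-od), 0.56)
        layers = hsd_deconvolve(tile)
        assert np.allclose(layers.hema.values, ch * hv.mean(), rtol=1e-6)
        assert np.allclose(layers.dab.values, cd * dv.mean(), rtol=1e-6)

    def test_zero_pixels_clamped_with_counter(self):
        pixels = np.zeros((2, 2, 3), dtype=np.uint8)
        layers = hsd_deconvolve(RGBRaster(pixels, 0.56))
        assert layers.n_clamped_pixels == 12
        assert np.all(np.isfinite(layers.dab.values))


class TestNuclearRegions:
    def _layers(self, dab, hema):
        return type("L", (), {
            "dab": RasterLayer(np.full((2, 2), dab), 0.56),
            "hema": RasterLayer(np.full((2, 2), hema), 0.56),
        })()

    def test_dab_dominant(self):
        md, mh = nuclear_regions(self._layers(0.3, 0.1))
        assert md.all() and not mh.any()

    def test_below_threshold_neither(self):
        md, mh = nuclear_regions(self._layers(0.15, 0.15))
        assert not md.any() and not mh.any()

    def test_hema_dominant(self):
        md, mh = nuclear_regions(self._layers(0.25, 0.30))
        assert mh.all() and not md.any()

    def test_masks_always_disjoint(self):
        rng = np.random.default_rng(1)
        layers = type("L", (), {
            "dab": RasterLayer(rng.uniform(0, 1, (30, 30)), 0.56),
            "hema": RasterLayer(rng.uniform(0, 1, (30, 30)), 0.56),
        })()
        md, mh = nuclear_regions(layers)
        assert not (md & mh).any()


def gaussian_blob(shape, center, sigma, amp=1.0):
    yy, xx = np.indices(shape)
    return amp * np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)))


class TestSplitNuclei:
    def test_single_disk_one_nucleus(self):
        mask = disk_mask((40, 40), (20, 20), 8)
        density = RasterLayer(gaussian_blob((40, 40), (20, 20), 6), 0.56)
        nuclei = split_nuclei(mask, density, min_area_px=10)
        assert len(nuclei) == 1
        assert nuclei[0].area_px == int(mask.sum())

    def test_two_blobs_split_on_ridge(self):
        shape = (40, 60)
        d = gaussian_blob(shape, (20, 22), 5) + gaussian_blob(shape, (20, 38), 5)
        mask = d > 0.15
        nuclei = split_nuclei(mask, RasterLayer(d, 0.56), min_area_px=10, peak_min_distance=8)
        assert len(nuclei) == 2
        cols = sorted(n.centroid[1] for n in nuclei)
        assert cols[0] < 30 < cols[1]
        # brute-force hill-climb oracle: each mask pixel ascends the smoothed
        # density to one of the two peaks; the watershed split must agree on
        # the overwhelming majority of pixels
        owner = _hill_climb_owner(d, mask)
        full = [np.zeros(shape, bool) for _ in nuclei]
        for i, n in enumerate(nuclei):
            full[i][n.offset[0] : n.offset[0] + n.mask.shape[0],
                    n.offset[1] : n.offset[1] + n.mask.shape[1]] |= n.mask
        if full[0][20, 22]:
            left, right = full
        else:
            right, left = full
        agree = ((owner == 1) & left) | ((owner == 2) & right)
        assert agree.sum() / mask.sum() > 0.95

    def test_small_speckle_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:7, 5:7] = True  # 4 px < min area
        nuclei = split_nuclei(mask, RasterLayer(np.ones((20, 20)), 0.56), min_area_px=10)
        assert nuclei == []


def _hill_climb_owner(density, mask):
    from scipy import ndimage

    smooth = ndimage.gaussian_filter(density, sigma=8 / 6)
    h, w = density.shape
    owner = np.zeros((h, w), dtype=int)
    peaks = []
    for r, c in np.argwhere(mask):
        rr, cc = r, c
        for _ in range(500):
            best = (smooth[rr, cc], rr, cc)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    r2, c2 = rr + dr, cc + dc
                    if 0 <= r2 < h and 0 <= c2 < w and smooth[r2, c2] > best[0]:
                        best = (smooth[r2, c2], r2, c2)
            if (best[1], best[2]) == (rr, cc):
                break
            rr, cc = best[1], best[2]
        peak = (rr, cc)
        if peak not in peaks:
            peaks.append(peak)
        owner[r, c] = peaks.index(peak) + 1
    return owner


def _nucleus_from_mask(mask, cls="negative"):
    rr, cc = np.nonzero(mask)
    return Nucleus(mask, int(mask.sum()), (float(rr.mean()), float(cc.mean())), cls)


class TestDentCut:
    def test_convex_uncut(self):
        nuc = _nucleus_from_mask(disk_mask((40, 40), (20, 20), 10))
        assert len(dent_cut(nuc)) == 1

    def test_figure_eight_cut(self):
        mask = disk_mask((40, 70), (20, 22), 11) | disk_mask((40, 70), (20, 40), 11)
        pieces = dent_cut(_nucleus_from_mask(mask), min_area_px=30)
        assert len(pieces) == 2
        cols = sorted(p.centroid[1] for p in pieces)
        assert cols[0] < 31 < cols[1]
        assert sum(p.area_px for p in pieces) == pytest.approx(int(mask.sum()), rel=0.05)

    def test_shallow_dent_uncut(self):
        # a 160-degree interior notch: tangents turn by ~20 degrees, below 30
        mask = disk_mask((60, 60), (30, 30), 20)
        yy, xx = np.indices((60, 60))
        ang = np.arctan2(yy - 30.0, xx - 30.0)
        wedge = (np.abs(ang) < math.radians(10)) & (xx > 30 + 12)
        pieces = dent_cut(_nucleus_from_mask(mask & ~wedge), min_area_px=30)
        assert len(pieces) == 1


class TestPostprocess:
    def test_smooth_disk_roughly_unchanged(self):
        mask = disk_mask((30, 30), (15, 15), 9)
        out = postprocess_nuclei([_nucleus_from_mask(mask)], min_area_px=10, tile_shape=(30, 30))
        assert len(out) == 1
        assert abs(out[0].area_px - int(mask.sum())) <= 0.1 * mask.sum()

    def test_spur_removed(self):
        mask = disk_mask((40, 40), (20, 15), 8)
        mask[20, 24:33] = True  # 1-px spur
        out = postprocess_nuclei([_nucleus_from_mask(mask)], min_area_px=10, tile_shape=(40, 40))
        assert len(out) == 1
        assert out[0].area_px < mask.sum() - 5

    def test_shrunk_below_min_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:11, 5] = True  # 1-px-wide line: opening erases it
        out = postprocess_nuclei([_nucleus_from_mask(mask)], min_area_px=5, tile_shape=(20, 20))
        assert out == []

    def test_disjointness_preserved(self):
        a = disk_mask((30, 50), (15, 15), 8)
        b = disk_mask((30, 50), (15, 33), 8)
        out = postprocess_nuclei(
            [_nucleus_from_mask(a), _nucleus_from_mask(b)], min_area_px=10, tile_shape=(30, 50)
        )
        full = np.zeros((30, 50), dtype=int)
        for n in out:
            full[n.offset[0] : n.offset[0] + n.mask.shape[0],
                 n.offset[1] : n.offset[1] + n.mask.shape[1]] += n.mask
        assert full.max() <= 1


class TestLobulePositivity:
    def test_synthetic_lobule_ratio(self, small_slide):
        image, truth = small_slide
        lobw = truth.lobule_label_working()
        for gt in truth.lobules:
            n_pos, n_neg, ratio, nuclei, offset = lobule_positivity(
                lobw == gt.id, image, truth.config.working_pixel_size_um
            )
            assert ratio is not None
            assert abs(ratio - gt.positive_fraction) <= 0.05

    def test_all_blue_ratio_zero(self):
        rng = np.random.default_rng(0)
        hv = np.asarray(HEMATOXYLIN_OD) / np.linalg.norm(HEMATOXYLIN_OD)
        od = np.zeros((120, 120, 3))
        for r, c in rng.integers(20, 100, size=(15, 2)):
            od[disk_mask((120, 120), (r, c), 5)] += 1.0
        tile = RGBRaster(np.clip(255 * np.exp(-od * hv), 1, 255), 0.56)
        mask = np.ones((12, 12), dtype=bool)
        n_pos, n_neg, ratio, *_ = lobule_positivity(mask, tile, 5.6)
        assert n_neg > 0
        assert ratio == 0.0

    def test_zero_nuclei_missing(self):
        tile = RGBRaster(np.full((60, 60, 3), 255, dtype=np.uint8), 0.56)
        mask = np.ones((6, 6), dtype=bool)
        n_pos, n_neg, ratio, *_ = lobule_positivity(mask, tile, 5.6)
        assert (n_pos, n_neg, ratio) == (0, 0, None)

    def test_area_bounded_by_region_mask(self):
        rng = np.random.default_rng(3)
        d = gaussian_blob((50, 50), (25, 25), 8)
        mask = d > 0.2
        nuclei = split_nuclei(mask, RasterLayer(d, 0.56), min_area_px=10)
        assert sum(n.area_px for n in nuclei) <= mask.sum()
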