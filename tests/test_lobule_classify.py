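import numpy as np
import pandas as pd
import pytest

from lobulescan.lobule_classify import (
    Lobule,
    LobuleCriteria,
    RegionFeatures,
    apply_review,
    initial_classify,
    passes_full,
    passes_reduced,
    refine,
    region_features,
    segment_features,
)
from lobulescan.mrseg import multires_hierarchy
from lobulescan.rasters import RasterLayer, TissueMask

from conftest import disk_mask


def feats(sd=25.0, area=5000, rnd=0.5, dom=10.0, bc=0.6):
    return RegionFeatures(area, sd, rnd, dom, bc)


class TestCriteria:
    def test_all_conditions_met(self):
        assert passes_full(feats(), LobuleCriteria())

    @pytest.mark.parametrize(
        "kw",
        [
            {"sd": 10.0},  # below stddev-n range 15-36
            {"sd": 40.0},
            {"area": 1000},  # below 2000 px^2 minimum
            {"area": 15000},
            {"rnd": 1.4},  # above roundness 1.3
            {"dom": 4.9},  # below difference-of-means 5
            {"bc": 0.39},  # below border contrast 0.4
            {"dom": None},
            {"bc": None},
        ],
    )
    def test_single_violation_rejects(self, kw):
        assert not passes_full(feats(**kw), LobuleCriteria())

    def test_reduced_drops_min_area_and_contrast(self):
        crit = LobuleCriteria()
        assert passes_reduced(feats(area=100, bc=None), crit)
        assert not passes_reduced(feats(area=100, bc=None, sd=10.0), crit)
        assert not passes_reduced(feats(area=20000, bc=None), crit)
        assert not passes_reduced(feats(area=100, bc=None, dom=1.0), crit)

    def test_degenerate_ranges_rejected(self):
        with pytest.raises(ValueError):
            LobuleCriteria(stddevn_range=(20.0, 20.0))


def lobule_scene(
    lobule_sd=25.0,
    stroma_sd=5.0,
    radius=28,
    shape=(120, 120),
    center=(60, 60),
):
    """A texture layer with a high-stddev disk on low-stddev stroma,
    segmented into exactly disk + stroma segments."""
    values = np.full(shape, stroma_sd)
    disk = disk_mask(shape, center, radius)
    values[disk] = lobule_sd
    lay = RasterLayer(values, 5.6)
    h = multires_hierarchy([lay], [1.0], (100, 80, 60, 40, 20),
                           TissueMask(np.ones(shape, bool), 5.6))
    return h, lay, disk


class TestInitialClassify:
    def test_disk_is_candidate(self):
        h, lay, disk = lobule_scene()
        lvl = h.levels[0]
        cands = initial_classify(lvl, lay, LobuleCriteria())
        assert len(cands) == 1
        seg = lvl.segments[next(iter(cands))]
        assert seg.area_px == int(disk.sum())

    def test_out_of_range_texture_rejected(self):
        h, lay, disk = lobule_scene(lobule_sd=10.0)  # below 15
        assert initial_classify(h.levels[0], lay, LobuleCriteria()) == set()

    def test_too_small_rejected(self):
        h, lay, disk = lobule_scene(radius=20)  # area ~1257 < 2000
        assert initial_classify(h.levels[0], lay, LobuleCriteria()) == set()

    def test_weak_contrast_rejected(self):
        # stroma at 15: dom = 10 >= 5 but contrast (25-15)/40 = 0.25 < 0.4
        h, lay, disk = lobule_scene(stroma_sd=15.0)
        assert initial_classify(h.levels[0], lay, LobuleCriteria()) == set()


class TestRefine:
    def test_clean_candidate_survives(self):
        h, lay, disk = lobule_scene()
        initial = {li: initial_classify(h.levels[li], lay, LobuleCriteria()) for li in range(4)}
        lobules = refine(h, initial, LobuleCriteria(), lay)
        assert len(lobules) == 1
        assert lobules[0].area_px == pytest.approx(int(disk.sum()), rel=0.05)
        assert lobules[0].area_mm2 == pytest.approx(
            lobules[0].area_px * (5.6 / 1000) ** 2
        )

    def test_peripheral_failing_subsegment_trimmed(self):
        # disk plus a low-texture tail: the tail fails the reduced criteria,
        # sits on the candidate outline, and is removed; the remaining disk
        # passes the full criteria
        shape = (120, 160)
        values = np.full(shape, 5.0)
        disk = disk_mask(shape, (60, 60), 28)
        values[disk] = 25.0
        tail = np.zeros(shape, bool)
        tail[52:68, 88:130] = True
        values[tail] = 13.0  # in-range for nothing: below stddev-n minimum
        lay = RasterLayer(values, 5.6)
        h = multires_hierarchy([lay], [1.0], (100, 80, 60, 40, 20),
                               TissueMask(np.ones(shape, bool), 5.6))
        initial = {li: initial_classify(h.levels[li], lay, LobuleCriteria()) for li in range(4)}
        lobules = refine(h, initial, LobuleCriteria(), lay)
        assert len(lobules) == 1
        assert not (lobules[0].mask & tail).any()

    def test_no_candidates_no_lobules(self):
        h, lay, disk = lobule_scene(lobule_sd=50.0)  # out of range everywhere
        initial = {li: set() for li in range(4)}
        assert refine(h, initial, LobuleCriteria(), lay) == []

    def test_deterministic(self, small_hierarchy, small_working):
        _, texture, _, _ = small_working
        crit = LobuleCriteria()
        initial = {
            li: initial_classify(small_hierarchy.levels[li], texture, crit) for li in range(4)
        }
        a = refine(small_hierarchy, initial, crit, texture)
        b = refine(small_hierarchy, initial, crit, texture)
        assert [lb.centroid for lb in a] == [lb.centroid for lb in b]
        for x, y in zip(a, b):
            assert np.array_equal(x.mask, y.mask)


class TestRegionFeatures:
    def test_mask_features_match_segment_features(self):
        h, lay, disk = lobule_scene()
        lvl = h.levels[0]
        sid = int(lvl.label_image[60, 60])
        seg = lvl.segments[sid]
        f_seg = segment_features(lvl, seg, lay)
        f_mask = region_features(lvl, lvl.label_image == sid, lay)
        assert f_mask.area_px == f_seg.area_px
        assert f_mask.mean_stddevn == pytest.approx(f_seg.mean_stddevn)
        assert f_mask.diff_of_means == pytest.approx(f_seg.diff_of_means)
        assert f_mask.border_contrast == pytest.approx(f_seg.border_contrast)

    def test_empty_region_rejected(self):
        h, lay, _ = lobule_scene()
        with pytest.raises(ValueError):
            region_features(h.levels[0], np.zeros((120, 120), bool), lay)


def _lobules(n=3):
    out = []
    for i in range(1, n + 1):
        mask = np.zeros((50, 50), bool)
        mask[i * 10 : i * 10 + 5, 10:15] = True
        out.append(Lobule(i, mask, (i * 10 + 2.0, 12.0), 25, 25 * (5.6 / 1000) ** 2))
    return out


class TestApplyReview:
    def test_all_tp_unchanged(self):
        labels = pd.DataFrame({"lobule_id": [1, 2, 3], "label": ["TP"] * 3})
        out = apply_review(_lobules(), labels)
        assert [lb.id for lb in out] == [1, 2, 3]
        assert all(lb.review_label == "TP" for lb in out)

    def test_fp_excluded_fn_added(self):
        labels = pd.DataFrame({"lobule_id": [1, 2, 3], "label": ["TP", "FP", "TP"]})
        fn = np.zeros((50, 50), dtype=np.int32)
        fn[40:45, 40:45] = 1
        out = apply_review(_lobules(), labels, fn_outlines=fn, pixel_size_um=5.6)
        assert [lb.id for lb in out] == [1, 3, 4]
        assert out[-1].review_label == "FN-added"
        assert out[-1].area_px == 25

    def test_empty_table_retains_unreviewed(self):
        out = apply_review(_lobules(), None)
        assert [lb.review_label for lb in out] == ["unreviewed"] * 3

    def test_unknown_id_errors(self):
        labels = pd.DataFrame({"lobule_id": [9], "label": ["TP"]})
        with pytest.raises(ValueError, match="unknown lobule ids"):
            apply_review(_lobules(), labels)

    def test_unknown_label_errors(self):
        labels = pd.DataFrame({"lobule_id": [1], "label": ["maybe"]})
        with pytest.raises(ValueError, match="unknown review label"):
            apply_review(_lobules(), labels)
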