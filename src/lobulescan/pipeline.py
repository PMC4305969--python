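"""End-to-end orchestration: preprocess, segment, classify, grow tumor,
count nuclei per lobule, and relate positivity to tumor distance."""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, mrseg, lobule_classify, tumor_detect, stain_nuclei, spatial_analysis
from .config import PipelineConfig
from .lobule_classify import Lobule
from .rasters import RGBRaster, RasterLayer, write_label_tiff, write_layer_tiff, TissueMask


@dataclass
class RunReport:
    status: str = "ok"
    stage_seconds: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    summary: dict | None = None
    regression: dict | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)


@dataclass
class PipelineResult:
    report: RunReport
    working: RGBRaster | None = None
    texture: RasterLayer | None = None
    tissue: TissueMask | None = None
    hierarchy: "mrseg.SegmentHierarchy | None" = None
    lobules: list[Lobule] = field(default_factory=list)
    tumor: "tumor_detect.TumorRegion | None" = None
    measurements: list = field(default_factory=list)


def run_pipeline(
    image: RGBRaster | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    review_labels: pd.DataFrame | None = None,
    fn_outlines: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full workflow on one slide image.

    ``image`` may be a raster or a path to a TIFF/PNG; outputs (label TIFFs,
    CSVs, JSON report, QC plots) are written to ``outdir`` when given.
    Deterministic for a fixed image and configuration.
    """
    cfg = config or PipelineConfig()
    report = RunReport()
    result = PipelineResult(report)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if not isinstance(image, RGBRaster):
        from .rasters import read_image

        image = read_image(image, cfg.pixel_size_um)

    # -- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    working = preprocess.downsample(image, cfg.downsample_fraction)
    texture = preprocess.build_texture_layer(working)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        tissue = preprocess.tissue_mask(working, cfg.small_area_limit_px)
    report.warnings.extend(str(w.message) for w in caught)
    report.stage_seconds["preprocess"] = time.perf_counter() - t0
    report.counts["tissue_px"] = int(tissue.mask.sum())
    result.working, result.texture, result.tissue = working, texture, tissue
    if out is not None:
        write_layer_tiff(out / "texture.tif", texture)
        write_layer_tiff(out / "tissue_mask.tif", tissue)
    if not tissue.mask.any():
        report.status = "no tissue"
        _write_report(out, report)
        return result

    # -- segmentation -----------------------------------------------------
    t0 = time.perf_counter()
    channels = [working.channel(0), working.channel(1), working.channel(2), texture]
    hierarchy = mrseg.multires_hierarchy(channels, cfg.channel_weights, cfg.scales, tissue)
    report.stage_seconds["mrseg"] = time.perf_counter() - t0
    for lvl in hierarchy.levels:
        report.counts[f"segments_scale_{lvl.scale_parameter:g}"] = len(lvl.segments)
    result.hierarchy = hierarchy
    if out is not None:
        _export_hierarchy(out, hierarchy)

    # -- lobule classification --------------------------------------------
    t0 = time.perf_counter()
    n_cls = min(4, len(hierarchy.levels) - 1)
    initial = {
        li: lobule_classify.initial_classify(hierarchy.levels[li], texture, cfg.criteria)
        for li in range(n_cls)
    }
    report.counts["initial_candidates"] = sum(len(s) for s in initial.values())
    lobules = lobule_classify.refine(hierarchy, initial, cfg.criteria, texture)
    report.stage_seconds["lobule_classify"] = time.perf_counter() - t0
    report.counts["lobules_detected"] = len(lobules)

    if review_labels is not None or fn_outlines is not None:
        lobules = lobule_classify.apply_review(
            lobules, review_labels, fn_outlines, working.pixel_size_um
        )
        report.counts["lobules_after_review"] = len(lobules)
    result.lobules = lobules

    # -- tumor detection --------------------------------------------------
    t0 = time.perf_counter()
    growth_level = hierarchy.levels[min(3, len(hierarchy.levels) - 1)]
    lobule_union = np.zeros(tissue.shape, dtype=bool)
    for lb in lobules:
        lobule_union |= lb.mask
    lobule_seg_ids = set(np.unique(growth_level.label_image[lobule_union]).tolist()) - {-1}
    tumor = None
    tolerance = cfg.seed_tolerance
    min_area = 0.02 * int(tissue.mask.sum())  # coherent-mass plausibility floor
    while True:
        try:
            seeds = tumor_detect.select_seeds(growth_level, lobule_seg_ids, tolerance)
            grown = tumor_detect.grow_tumor(
                growth_level, seeds, cfg.growth_delta, cfg.min_border_fraction,
                excluded=lobule_seg_ids,
            )
            grown = tumor_detect.postprocess_tumor(grown)
        except ValueError as exc:
            grown = None
            last_error = str(exc)
        if grown is not None and grown.mask.sum() >= min_area:
            tumor = grown
            break
        if tolerance >= 8 * cfg.seed_tolerance:
            tumor = grown
            break
        tolerance *= 2
        report.warnings.append(
            f"tumor growth degenerate; retrying with seed tolerance {tolerance:g}"
        )
    if tumor is None:
        report.status = f"tumor detection failed: {last_error}"
        report.warnings.append(last_error)
        _write_report(out, report)
        return result
    report.stage_seconds["tumor_detect"] = time.perf_counter() - t0
    report.counts["tumor_components"] = len(tumor.component_areas)
    report.counts["tumor_px"] = int(tumor.mask.sum())
    result.tumor = tumor
    if out is not None:
        write_layer_tiff(out / "tumor_mask.tif", TissueMask(tumor.mask, tumor.pixel_size_um))
        _export_tumor_border(out, tumor)

    # -- per-lobule nuclei at full resolution ------------------------------
    t0 = time.perf_counter()
    positivity: dict[int, tuple[int, int, float | None]] = {}
    nucleus_rows = []
    for lb in lobules:
        n_pos, n_neg, ratio, nuclei, offset = stain_nuclei.lobule_positivity(
            lb.mask, image, working.pixel_size_um, config=cfg.nuclei
        )
        positivity[lb.id] = (n_pos, n_neg, ratio)
        if out is not None:
            _write_qc_snapshot(out, lb.id, image, nuclei, offset, lb.mask, working.pixel_size_um)
        for j, nuc in enumerate(nuclei, start=1):
            nucleus_rows.append(
                {
                    "lobule_id": lb.id,
                    "nucleus_id": j,
                    "class": nuc.stain_class,
                    "area_px": nuc.area_px,
                    "centroid_row": nuc.centroid[0] + offset[0],
                    "centroid_col": nuc.centroid[1] + offset[1],
                }
            )
    report.stage_seconds["stain_nuclei"] = time.perf_counter() - t0
    report.counts["nuclei_total"] = len(nucleus_rows)
    if out is not None:
        pd.DataFrame(
            nucleus_rows,
            columns=["lobule_id", "nucleus_id", "class", "area_px", "centroid_row", "centroid_col"],
        ).to_csv(out / "nuclei.csv", index=False)

    # -- spatial analysis --------------------------------------------------
    t0 = time.perf_counter()
    measurements = spatial_analysis.measure_lobules(
        lobules, tumor, positivity, working.pixel_size_um, cfg.bin_edges_mm
    )
    summary = spatial_analysis.summarize_case(measurements)
    report.summary = {
        "mean_positivity_pct": summary.mean_positivity_pct,
        "lobule_count": summary.lobule_count,
    }
    try:
        fit = spatial_analysis.fit_regression(measurements)
        report.regression = {"slope_pct_per_mm": fit.slope_pct_per_mm, "intercept_pct": fit.intercept_pct}
    except ValueError as exc:
        report.warnings.append(f"regression skipped: {exc}")
    report.stage_seconds["spatial_analysis"] = time.perf_counter() - t0
    result.measurements = measurements

    if out is not None:
        _export_lobules(out, lobules, measurements, tissue.shape, working.pixel_size_um)
        summary.to_frame().to_csv(out / "case_summary.csv", index=False)
        if report.regression is not None:
            (out / "regression.json").write_text(json.dumps(report.regression, indent=2))
        _plot_scatter(out / "positivity_vs_distance.png", measurements)
    _write_report(out, report)
    return result


def detection_quality(review_labels: pd.DataFrame) -> dict[str, float]:
    """TP/FP/FN counts and TP fraction from a review table with a ``label``
    column holding TP / FP / FN entries."""
    if review_labels is None or len(review_labels) == 0:
        raise ValueError("no reviewed lobules")
    labels = review_labels["label"].astype(str)
    n_tp = int((labels == "TP").sum())
    n_fp = int((labels == "FP").sum())
    n_fn = int(labels.isin(["FN", "FN-added"]).sum())
    if n_tp + n_fp == 0:
        raise ValueError("no reviewed detections (TP or FP) present")
    return {"n_TP": n_tp, "n_FP": n_fp, "n_FN": n_fn, "tp_fraction": n_tp / (n_tp + n_fp)}


# ---------------------------------------------------------------------------
# Artifact export helpers


def _export_hierarchy(out: Path, hierarchy) -> None:
    rows = []
    for lvl in hierarchy.levels:
        write_label_tiff(out / f"segments_scale_{lvl.scale_parameter:g}.tif", lvl.label_image, lvl.pixel_size_um)
        for seg in lvl.segments.values():
            rows.append(
                {
                    "level": lvl.level_index,
                    "scale": lvl.scale_parameter,
                    "id": seg.id,
                    "area_px": seg.area_px,
                    "mean_r": seg.means[0],
                    "mean_g": seg.means[1],
                    "mean_b": seg.means[2],
                    "mean_stddevn": seg.mean_stddevn,
                    "parent": seg.parent if seg.parent is not None else -1,
                }
            )
    pd.DataFrame(rows).to_csv(out / "segments.csv", index=False)


def _export_tumor_border(out: Path, tumor) -> None:
    rr, cc = np.nonzero(tumor.border_mask())
    pd.DataFrame({"row": rr, "col": cc}).to_csv(out / "tumor_border.csv", index=False)


def _export_lobules(out: Path, lobules, measurements, shape, pixel_size_um: float = 1.0) -> None:
    label = np.zeros(shape, dtype=np.int32)
    rows = []
    meas = {m.lobule_id: m for m in measurements}
    for lb in lobules:
        label[lb.mask] = lb.id
        m = meas.get(lb.id)
        rows.append(
            {
                "lobule_id": lb.id,
                "centroid_row": lb.centroid[0],
                "centroid_col": lb.centroid[1],
                "area_px": lb.area_px,
                "area_mm2": lb.area_mm2,
                "review_label": lb.review_label,
                "distance_mm": m.distance_mm if m else np.nan,
                "category": m.category if m else "",
                "n_pos": m.n_pos if m else 0,
                "n_neg": m.n_neg if m else 0,
                "ratio": (np.nan if (m is None or m.positivity is None) else m.positivity),
            }
        )
    if lobules:
        write_label_tiff(out / "lobules.tif", label, pixel_size_um)
    pd.DataFrame(rows).to_csv(out / "lobules.csv", index=False)


def _write_qc_snapshot(out: Path, lobule_id, image, nuclei, offset, mask_working, working_px_um) -> None:
    """Per-lobule QC image: the full-resolution tile with nucleus outlines
    (DAB-positive red, hematoxylin-negative green)."""
    import imageio.v3 as iio
    from scipy import ndimage as ndi

    factor = working_px_um / image.pixel_size_um
    rr, cc = np.nonzero(mask_working)
    r0 = max(int(rr.min() * factor), 0)
    r1 = min(int((rr.max() + 1) * factor) + 1, image.shape[0])
    c0 = max(int(cc.min() * factor), 0)
    c1 = min(int((cc.max() + 1) * factor) + 1, image.shape[1])
    tile = image.pixels[r0:r1, c0:c1].copy()
    for nuc in nuclei:
        outline = nuc.mask & ~ndi.binary_erosion(nuc.mask, border_value=0)
        orr, occ = np.nonzero(outline)
        orr = orr + nuc.offset[0]
        occ = occ + nuc.offset[1]
        keep = (orr < tile.shape[0]) & (occ < tile.shape[1])
        color = (220, 30, 30) if nuc.stain_class == "positive" else (30, 160, 30)
        tile[orr[keep], occ[keep]] = color
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    iio.imwrite(qc_dir / f"lobule_{lobule_id:03d}.png", tile)


def _plot_scatter(path: Path, measurements) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [m.distance_mm for m in measurements if m.positivity is not None]
    ys = [100 * m.positivity for m in measurements if m.positivity is not None]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(xs, ys, s=18)
    if len({round(x, 9) for x in xs}) >= 2:
        slope, intercept = np.polyfit(xs, ys, 1)
        grid = np.linspace(min(xs), max(xs), 20)
        ax.plot(grid, slope * grid + intercept, color="tab:blue")
    ax.set_xlabel("distance to tumor (mm)")
    ax.set_ylabel("positive nuclei (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_report(out: Path | None, report: RunReport) -> None:
    if out is not None:
        (out / "run_report.json").write_text(report.to_json())
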