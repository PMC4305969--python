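"""Distance-to-tumor binning and per-case positivity summaries.

Lobules are grouped into three categories by the distance from their center
to the nearest tumor border pixel: adjacent (< 0.5 mm), intermediate
(0.5-2 mm, both bounds included) and distant (> 2 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lobule_classify import Lobule
from .tumor_detect import TumorRegion

CATEGORIES = ("adjacent", "intermediate", "distant")
DEFAULT_BIN_EDGES_MM = (0.5, 2.0)


@dataclass
class LobuleMeasurement:
    lobule_id: int
    distance_mm: float
    category: str
    n_pos: int
    n_neg: int
    positivity: float | None  # ratio in [0, 1], None when no nuclei
    inside_tumor: bool = False


@dataclass
class CaseSummary:
    """Six-column per-case row: mean positivity (%) and count per category."""

    mean_positivity_pct: dict[str, float | None]
    lobule_count: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        row = {}
        for cat in CATEGORIES:
            mean = self.mean_positivity_pct[cat]
            row[f"avg_positive_{cat}"] = "-" if mean is None else round(mean, 1)
            row[f"n_{cat}"] = self.lobule_count[cat]
        return pd.DataFrame([row])


@dataclass
class RegressionFit:
    slope_pct_per_mm: float
    intercept_pct: float


def lobule_distance(lobule: Lobule, tumor: TumorRegion, pixel_size_um: float) -> float:
    """Euclidean distance (mm) from the lobule centroid to the nearest tumor
    border pixel."""
    border = tumor.border_mask()
    if not border.any():
        raise ValueError("tumor region is empty; distance undefined")
    rr, cc = np.nonzero(border)
    r0, c0 = lobule.centroid
    d_px = float(np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2).min())
    return d_px * pixel_size_um / 1000.0


def categorize(distance_mm: float, bin_edges_mm: tuple[float, float] = DEFAULT_BIN_EDGES_MM) -> str:
    """Bin a distance into adjacent [0, lo), intermediate [lo, hi], distant (hi, inf)."""
    if distance_mm < 0:
        raise ValueError(f"distance must be >= 0, got {distance_mm}")
    lo, hi = bin_edges_mm
    if distance_mm < lo:
        return "adjacent"
    if distance_mm <= hi:
        return "intermediate"
    return "distant"


def area_px_to_mm2(area_px: float, pixel_size_um: float) -> float:
    """Convert a pixel-count area to mm^2 at the given pixel size."""
    if area_px < 0:
        raise ValueError("area_px must be >= 0")
    return area_px * (pixel_size_um / 1000.0) ** 2


def measure_lobules(
    lobules: list[Lobule],
    tumor: TumorRegion,
    positivity: dict[int, tuple[int, int, float | None]],
    pixel_size_um: float,
    bin_edges_mm: tuple[float, float] = DEFAULT_BIN_EDGES_MM,
) -> list[LobuleMeasurement]:
    """Assemble per-lobule measurements from detection and nuclei counts.

    ``positivity`` maps lobule id to (n_pos, n_neg, ratio). Lobules whose
    centroid falls inside the tumor mask are retained but flagged.
    """
    out = []
    for lb in lobules:
        d = lobule_distance(lb, tumor, pixel_size_um)
        n_pos, n_neg, ratio = positivity.get(lb.id, (0, 0, None))
        r, c = int(round(lb.centroid[0])), int(round(lb.centroid[1]))
        inside = bool(tumor.mask[r, c]) if (0 <= r < tumor.mask.shape[0] and 0 <= c < tumor.mask.shape[1]) else False
        out.append(
            LobuleMeasurement(lb.id, d, categorize(d, bin_edges_mm), n_pos, n_neg, ratio, inside)
        )
    return out


def summarize_case(measurements: list[LobuleMeasurement]) -> CaseSummary:
    """Per-category arithmetic mean of per-lobule positivity (as %) over
    lobules with a defined ratio, plus lobule counts."""
    means: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    for cat in CATEGORIES:
        in_cat = [m for m in measurements if m.category == cat]
        counts[cat] = len(in_cat)
        ratios = [m.positivity for m in in_cat if m.positivity is not None]
        means[cat] = 100.0 * float(np.mean(ratios)) if ratios else None
    return CaseSummary(means, counts)


def fit_regression(measurements: list[LobuleMeasurement]) -> RegressionFit:
    """Ordinary least squares of positivity (%) on distance to tumor (mm)."""
    pts = [(m.distance_mm, 100.0 * m.positivity) for m in measurements if m.positivity is not None]
    if len({round(d, 12) for d, _ in pts}) < 2:
        raise ValueError("regression requires >= 2 distinct distances with defined ratios")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(x, y, 1)
    return RegressionFit(float(slope), float(intercept))


def measurements_frame(measurements: list[LobuleMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lobule_id": m.lobule_id,
                "distance_mm": m.distance_mm,
                "category": m.category,
                "n_pos": m.n_pos,
                "n_neg": m.n_neg,
                "ratio": np.nan if m.positivity is None else m.positivity,
                "inside_tumor": m.inside_tumor,
            }
            for m in measurements
        ]
    )
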