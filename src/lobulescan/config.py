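"""Pipeline configuration: every threshold of the rule set in one place.

Defaults reproduce the published rule set (10% downsampling, scales 100 to
20 in steps of 20, texture weighted twice, lobule criteria, seed tolerance
0.1, growth delta 2, 20% border fraction, stain threshold 0.2, 30 degree
dents, 0.5/2 mm distance bins). Configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lobule_classify import LobuleCriteria
from .stain_nuclei import NucleiConfig


@dataclass
class PipelineConfig:
    pixel_size_um: float | None = None  # None: read from TIFF tags
    downsample_fraction: float = 0.1
    scales: tuple[float, ...] = (100.0, 80.0, 60.0, 40.0, 20.0)
    channel_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 2.0)
    small_area_limit_px: int = 2500
    criteria: LobuleCriteria = field(default_factory=LobuleCriteria)
    seed_tolerance: float = 0.1
    growth_delta: float = 2.0
    min_border_fraction: float = 0.2
    nuclei: NucleiConfig = field(default_factory=NucleiConfig)
    bin_edges_mm: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if not 0 < self.downsample_fraction <= 1:
            raise ValueError("downsample_fraction must be in (0, 1]")
        if len(self.channel_weights) != 4:
            raise ValueError("need one weight per channel (R, G, B, texture)")
        if list(self.scales) != sorted(self.scales, reverse=True):
            raise ValueError("scales must be strictly descending")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("scales", "channel_weights", "bin_edges_mm"):
            d[key] = list(d[key])
        for key in ("stddevn_range", "area_range_px", "roundness_range"):
            d["criteria"][key] = list(d["criteria"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "criteria" in d:
            crit = {k: tuple(v) if isinstance(v, list) else v for k, v in d["criteria"].items()}
            d["criteria"] = LobuleCriteria(**crit)
        if "nuclei" in d:
            d["nuclei"] = NucleiConfig(**d["nuclei"])
        for key in ("scales", "channel_weights", "bin_edges_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
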