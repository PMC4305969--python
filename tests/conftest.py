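import numpy as np
import pytest

from lobulescan.rasters import RGBRaster, RasterLayer
from lobulescan.synthetic import BandSpec, SyntheticConfig, generate_slide


def make_rgb(shape=(20, 20), value=200, pixel_size_um=5.6):
    return RGBRaster(np.full((*shape, 3), value, dtype=np.uint8), pixel_size_um)


def disk_mask(shape, center, radius):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def small_slide():
    """A reduced slide: one lobule per distance band, ~20 Mpx full res."""
    bands = (
        BandSpec("adjacent", (0.22, 0.46), 1, 0.05),
        BandSpec("intermediate", (0.9, 1.5), 1, 0.10),
        BandSpec("distant", (2.1, 2.35), 1, 0.15),
    )
    cfg = SyntheticConfig(seed=2, shape_full=(3000, 6600), bands=bands)
    image, truth = generate_slide(cfg)
    return image, truth


@pytest.fixture(scope="session")
def small_working(small_slide):
    """Working-resolution channels, texture and tissue mask of the small slide."""
    from lobulescan import preprocess

    image, truth = small_slide
    working = preprocess.downsample(image, truth.config.working_scale)
    texture = preprocess.build_texture_layer(working)
    tissue = preprocess.tissue_mask(working)
    return working, texture, tissue, truth


@pytest.fixture(scope="session")
def small_hierarchy(small_working):
    from lobulescan import mrseg

    working, texture, tissue, truth = small_working
    channels = [working.channel(0), working.channel(1), working.channel(2), texture]
    return mrseg.multires_hierarchy(channels, (1, 1, 1, 2), (100, 80, 60, 40, 20), tissue)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default synthetic slide (shared across tests)."""
    from lobulescan.config import PipelineConfig
    from lobulescan.pipeline import run_pipeline

    cfg = SyntheticConfig(seed=0)
    image, truth = generate_slide(cfg)
    result = run_pipeline(image, PipelineConfig(pixel_size_um=cfg.pixel_size_um))
    return image, truth, result
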