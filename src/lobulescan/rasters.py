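"""Calibrated raster containers and image I/O.

All grids use row/col indexing, 0-based, with coordinates referring to pixel
centers. ``pixel_size_um`` is isotropic (microns per pixel edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio


@dataclass
class RGBRaster:
    """A 3-channel brightfield image with physical pixel calibration."""

    pixels: np.ndarray  # (H, W, 3), values 0-255
    pixel_size_um: float
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got {self.pixels.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < 0 or hi > 255:
            raise ValueError(f"channel values outside [0, 255]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, index: int) -> "RasterLayer":
        return RasterLayer(self.pixels[:, :, index].astype(np.float64), self.pixel_size_um)


@dataclass
class RasterLayer:
    """A single-channel scalar grid with physical pixel calibration."""

    values: np.ndarray  # (H, W) float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"expected 2-D array, got shape {self.values.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("layer contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class TissueMask:
    """Boolean tissue/background partition of the working grid."""

    mask: np.ndarray  # (H, W) bool, True = tissue
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"expected 2-D mask, got shape {self.mask.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def read_image(path: str | Path, pixel_size_um: float | None = None) -> RGBRaster:
    """Read a TIFF or PNG image as an :class:`RGBRaster`.

    For TIFF, the pixel size is taken from the resolution tags when present
    and not supplied explicitly. Grayscale input is broadcast to 3 channels;
    an alpha channel is dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            if pixel_size_um is None:
                pixel_size_um = _pixel_size_from_tags(page)
    else:
        arr = iio.imread(path)
    if pixel_size_um is None:
        raise ValueError(f"pixel size not supplied and not recoverable from {path}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] > 3:
        arr = arr[:, :, :3]
    return RGBRaster(arr, pixel_size_um)


def _pixel_size_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags.get("ResolutionUnit")
    per_unit = num / den
    # pixels per cm -> um per pixel; per inch -> um per pixel
    if unit is not None and getattr(unit.value, "name", str(unit.value)) in ("INCH", "2"):
        return 25400.0 / per_unit
    return 10000.0 / per_unit


def write_layer_tiff(path: str | Path, layer: RasterLayer | TissueMask) -> None:
    """Export a scalar layer or mask as a single-channel TIFF with resolution tags."""
    if isinstance(layer, TissueMask):
        data = layer.mask.astype(np.uint8) * 255
    else:
        data = layer.values.astype(np.float32)
    px_cm = 10000.0 / layer.pixel_size_um
    tifffile.imwrite(str(path), data, resolution=(px_cm, px_cm), resolutionunit="CENTIMETER")


def write_rgb_tiff(path: str | Path, image: RGBRaster) -> None:
    px_cm = 10000.0 / image.pixel_size_um
    tifffile.imwrite(
        str(path),
        image.pixels.astype(np.uint8),
        photometric="rgb",
        resolution=(px_cm, px_cm),
        resolutionunit="CENTIMETER",
    )


def write_label_tiff(path: str | Path, labels: np.ndarray, pixel_size_um: float) -> None:
    px_cm = 10000.0 / pixel_size_um
    tifffile.imwrite(str(path), labels.astype(np.int32), resolution=(px_cm, px_cm), resolutionunit="CENTIMETER")
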