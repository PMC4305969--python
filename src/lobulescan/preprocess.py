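"""Working-resolution preparation: downsampling, texture layer, tissue mask.

The workflow operates on a heavily downsampled "working" image (default 10%
of original resolution). A texture layer — the per-pixel standard deviation
to the 8-neighborhood, median- and Gaussian-filtered — is the key channel
for everything downstream: it is bright over lobules (regular tubular
structure) and dark over stroma.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .rasters import RGBRaster, RasterLayer, TissueMask

#: Background components smaller than this (working pixels) that are fully
#: enclosed by tissue get reclassified as tissue, and vice versa. Kept well
#: above nothing but below the minimum lobule area (2000 px^2) so that
#: reclassification can never destroy a candidate lobule.
SMALL_AREA_LIMIT_PX = 2500


def gaussian_kernel_sigma(window: int) -> float:
    """Sigma convention for an odd ``window``-sized truncated Gaussian."""
    return (window - 1) / 6.0


def _gaussian_filter(values: np.ndarray, window: int) -> np.ndarray:
    sigma = gaussian_kernel_sigma(window)
    radius = (window - 1) // 2
    return ndimage.gaussian_filter(values, sigma=sigma, radius=radius, mode="nearest")


def downsample(image: RGBRaster, scale_fraction: float) -> RGBRaster:
    """Nearest-neighbor downsample by ``scale_fraction`` in (0, 1].

    Output dimensions are ``floor(dim * scale_fraction)`` and the pixel size
    grows by ``1 / scale_fraction``. Each output pixel copies the nearest
    input pixel; no interpolation is performed.
    """
    if not 0 < scale_fraction <= 1:
        raise ValueError(f"scale_fraction must be in (0, 1], got {scale_fraction}")
    h, w = image.shape
    oh, ow = int(h * scale_fraction), int(w * scale_fraction)
    if oh < 1 or ow < 1:
        raise ValueError(f"downsampling {h}x{w} by {scale_fraction} yields an empty image")
    # Nearest source pixel for output pixel center i: center maps to
    # (i + 0.5) / scale - 0.5 in input coordinates.
    rows = np.clip(np.round((np.arange(oh) + 0.5) / scale_fraction - 0.5).astype(int), 0, h - 1)
    cols = np.clip(np.round((np.arange(ow) + 0.5) / scale_fraction - 0.5).astype(int), 0, w - 1)
    out = image.pixels[np.ix_(rows, cols)]
    return RGBRaster(out, image.pixel_size_um / scale_fraction)


def stddev_to_neighbors(layer: RasterLayer) -> RasterLayer:
    """Per-pixel RMS difference to the 8-connected neighborhood.

    For pixel value v with neighbors n_1..n_k (k < 8 at edges), returns
    sqrt(mean((n_i - v)^2)). Zero exactly where the layer is locally
    constant.
    """
    v = layer.values
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise ValueError("layer must be at least 3x3")
    sq_sum = np.zeros_like(v)
    count = np.zeros_like(v)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = _shift(v, dr, dc)
            valid = _shift_valid(v.shape, dr, dc)
            sq_sum += np.where(valid, (shifted - v) ** 2, 0.0)
            count += valid
    return RasterLayer(np.sqrt(sq_sum / count), layer.pixel_size_um)


def _shift(v: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Value of pixel p + (dr, dc) at each pixel p, zero where out of bounds."""
    h, w = v.shape
    out = np.zeros_like(v)
    out[max(-dr, 0) : h - max(dr, 0), max(-dc, 0) : w - max(dc, 0)] = v[
        max(dr, 0) : h - max(-dr, 0), max(dc, 0) : w - max(-dc, 0)
    ]
    return out


def _shift_valid(shape: tuple[int, int], dr: int, dc: int) -> np.ndarray:
    h, w = shape
    valid = np.zeros(shape, dtype=float)
    valid[max(-dr, 0) : h - max(dr, 0), max(-dc, 0) : w - max(dc, 0)] = 1.0
    return valid


def build_texture_layer(image: RGBRaster) -> RasterLayer:
    """Texture layer: stddev-to-neighbors of the blue channel, median filtered
    with a 3x3 window, then smoothed with an 11x11 Gaussian kernel."""
    sd = stddev_to_neighbors(image.channel(2))
    med = ndimage.median_filter(sd.values, size=3, mode="nearest")
    smooth = _gaussian_filter(med, 11)
    return RasterLayer(np.maximum(smooth, 0.0), image.pixel_size_um)


def tissue_mask(
    image: RGBRaster,
    small_area_limit_px: int = SMALL_AREA_LIMIT_PX,
    variance_tolerance: float = 1e-3,
) -> TissueMask:
    """Separate tissue from (bright) background.

    Mean-RGB brightness is smoothed with a 15x15 Gaussian, thresholded with
    Otsu's method (pixels above the threshold are background), and small
    fully-enclosed islands of either class below ``small_area_limit_px`` are
    flipped to the enclosing class.
    """
    brightness = image.pixels.astype(np.float64).mean(axis=2)
    smooth = _gaussian_filter(brightness, 15)
    if smooth.var() < variance_tolerance:
        warnings.warn("near-constant image: classifying everything as background")
        return TissueMask(np.zeros(image.shape, dtype=bool), image.pixel_size_um)
    thr = otsu_threshold(smooth)
    tissue = smooth <= thr
    tissue = _flip_small_enclosed(tissue, small_area_limit_px)
    return TissueMask(tissue, image.pixel_size_um)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold maximizing between-class variance of a histogram."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values, nbins=nbins))


def _flip_small_enclosed(tissue: np.ndarray, limit: int) -> np.ndarray:
    out = tissue.copy()
    for target in (False, True):  # first close background holes, then tissue specks
        labels, n = ndimage.label(out == target)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        border_labels = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        for lab in range(1, n + 1):
            if sizes[lab - 1] < limit and lab not in border_labels:
                out[labels == lab] = not target
    return out
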