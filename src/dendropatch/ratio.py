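"""Ratiometric image processing.

Turns raw two-channel fluorescence images (protein of interest + freely
diffusing cytosolic reference) into background-corrected POI/cytosol ratio
images: Gaussian low-pass denoising, local background subtraction with a
fixed physical radius, pixelwise ratio with a validity mask, and maximum
projection of z-stacks.

All grids are 0-indexed, row-major, (row, col) = (y, x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

__all__ = [
    "ChannelImage",
    "CellMask",
    "RatioImage",
    "gaussian_lowpass",
    "subtract_local_background",
    "compute_ratio",
    "max_project",
]

# direct convolution below this op count; FFT above (counts are re-rounded
# to integers so only the intensity sums carry FFT rounding, ~1e-12 relative)
_DIRECT_CONV_MAX_OPS = 1e8


@dataclass
class ChannelImage:
    """A single 2-D fluorescence channel with physical pixel calibration."""

    values: np.ndarray
    pixel_size: float  # µm per pixel
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("channel image must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("channel image contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")


# a cell mask is a boolean grid; True = cell (foreground) pixels
CellMask = np.ndarray


@dataclass
class RatioImage:
    """POI/cytosol ratio grid plus the mask of pixels where it is defined."""

    values: np.ndarray
    valid_mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("ratio values and valid_mask shapes differ")


def gaussian_lowpass(img: ChannelImage, sigma_px: float) -> ChannelImage:
    """Gaussian low-pass filter with reflective boundary handling.

    sigma 0 returns the input unchanged; the reflective boundary preserves the
    image mean.
    """
    if sigma_px < 0:
        raise ValueError(f"sigma_px must be >= 0, got {sigma_px}")
    if sigma_px == 0:
        return ChannelImage(img.values.copy(), img.pixel_size, img.name)
    out = ndimage.gaussian_filter(img.values, sigma=sigma_px, mode="reflect")
    return ChannelImage(out, img.pixel_size, img.name)


def _disk_kernel(radius_px: float) -> np.ndarray:
    """Boolean disk: integer offsets with Euclidean norm <= radius (inclusive)."""
    r_int = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    return (yy * yy + xx * xx) <= radius_px * radius_px


def _windowed_sum(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Sum of ``arr`` over the kernel footprint around each pixel.

    Out-of-image area contributes zero (background outside the frame does not
    exist, so it simply is not averaged).
    """
    if arr.size * kernel.size <= _DIRECT_CONV_MAX_OPS:
        return ndimage.convolve(arr, kernel.astype(float), mode="constant", cval=0.0)
    return fftconvolve(arr, kernel.astype(float), mode="same")


def subtract_local_background(
    img: ChannelImage, mask: CellMask, radius_um: float = 40.0
) -> tuple[ChannelImage, np.ndarray]:
    """Subtract, at each pixel, the mean background intensity within a radius.

    Background pixels are those outside the cell mask. The radius is physical
    (default 40 µm), converted to pixels via the image calibration with no
    rounding; distances are Euclidean, center-to-center, radius inclusive.

    Pixels with no background pixel inside the radius get the global
    background mean subtracted instead and are flagged in the returned
    fallback mask.

    Returns (corrected image, fallback mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.values.shape:
        raise ValueError("mask shape must match image shape")
    bg = ~mask
    if not bg.any():
        raise ValueError("mask covers the whole image; no background pixels")
    radius_px = radius_um / img.pixel_size
    kernel = _disk_kernel(radius_px)
    counts = np.rint(_windowed_sum(bg.astype(float), kernel))
    sums = _windowed_sum(np.where(bg, img.values, 0.0), kernel)
    global_mean = img.values[bg].mean()
    fallback = counts < 1
    local_mean = np.where(fallback, global_mean, sums / np.maximum(counts, 1))
    out = img.values - local_mean
    return ChannelImage(out, img.pixel_size, img.name), fallback


def compute_ratio(
    poi: ChannelImage, cyto: ChannelImage, min_cyto: float
) -> RatioImage:
    """Pixelwise POI/cytosol ratio.

    Pixels where the cytosolic reference falls below ``min_cyto`` carry no
    volume information and are marked invalid rather than raising.
    """
    if poi.values.shape != cyto.values.shape:
        raise ValueError(
            f"channel shapes differ: {poi.values.shape} vs {cyto.values.shape}"
        )
    if not min_cyto > 0:
        raise ValueError("min_cyto must be > 0")
    valid = cyto.values >= min_cyto
    values = np.full(poi.values.shape, np.nan)
    np.divide(poi.values, cyto.values, out=values, where=valid)
    return RatioImage(values=values, valid_mask=valid, pixel_size=poi.pixel_size)


def estimate_min_cyto(cyto: ChannelImage, mask: CellMask, n_sd: float = 5.0) -> float:
    """Default ratio validity cutoff: n_sd × the background standard deviation."""
    bg = ~np.asarray(mask, dtype=bool)
    if not bg.any():
        raise ValueError("no background pixels to estimate noise from")
    sd = float(cyto.values[bg].std())
    return max(n_sd * sd, np.finfo(float).tiny)


def max_project(stack: list[ChannelImage]) -> ChannelImage:
    """Per-pixel maximum intensity projection of a z-stack."""
    if len(stack) == 0:
        raise ValueError("cannot project an empty stack")
    shapes = {im.values.shape for im in stack}
    if len(shapes) > 1:
        raise ValueError(f"stack planes have differing shapes: {shapes}")
    out = np.max(np.stack([im.values for im in stack]), axis=0)
    return ChannelImage(out, stack[0].pixel_size, stack[0].name)
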