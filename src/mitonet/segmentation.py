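"""Segmentation of grayscale mitochondrial images into binary masks.

Confocal images are segmented with the pipeline used throughout this
package: median smoothing, contrast enhancement, the intersection of a
local (median) and a global threshold, and a conservative neighbour-count
erosion.  Synthetic images carry no background structure and are segmented
with a single global threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure
from skimage.filters import threshold_triangle
from skimage.morphology import disk

DEFAULT_PIXEL_SIZE_UM = 1.0 / 15.0  # 15 px per micron


@dataclass
class GrayImage:
    """Single-channel grayscale image with a physical pixel size (um/px)."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("image must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("image intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryImage:
    """Binary mitochondrial mask; foreground is mitochondrial signal."""

    mask: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SegmentationParams:
    """Parameters of the confocal segmentation pipeline.

    median_radius_px
        Radius of the initial median smoothing (disk footprint).
    saturation_fraction
        Total fraction of pixels saturated during contrast enhancement
        (split evenly between the two intensity tails).
    local_radius_px
        Radius of the local median threshold window; chosen on the order
        of a mitochondrion's apparent width.
    global_threshold
        Manual global threshold on the enhanced image (in [0, 1]); when
        None the triangle method is applied automatically.
    erode_iterations, erode_count
        Neighbour-count erosion: a foreground pixel is removed when at
        least ``erode_count`` of its 8 neighbours are background; applied
        ``erode_iterations`` times.
    """

    median_radius_px: int = 2
    saturation_fraction: float = 0.004
    local_radius_px: int = 10
    global_threshold: float | None = None
    erode_iterations: int = 1
    erode_count: int = 4

    def validate(self) -> None:
        if self.median_radius_px < 1 or self.local_radius_px < 1:
            raise ValueError("radii must be >= 1")
        if not (0 <= self.saturation_fraction < 1):
            raise ValueError("saturation_fraction must lie in [0, 1)")
        if self.erode_iterations < 0:
            raise ValueError("erode_iterations must be >= 0")
        if not (1 <= self.erode_count <= 8):
            raise ValueError("erode_count must lie in [1, 8]")


def enhance_contrast(pixels: np.ndarray, saturation_fraction: float = 0.004) -> np.ndarray:
    """Clip the intensity tails, rescale to [0, 1] and equalize the histogram."""
    tail = 100.0 * saturation_fraction / 2.0
    lo, hi = np.percentile(pixels, [tail, 100.0 - tail])
    if hi <= lo:  # constant image
        return np.zeros_like(pixels, dtype=float)
    clipped = np.clip(pixels, lo, hi)
    rescaled = (clipped - lo) / (hi - lo)
    return exposure.equalize_hist(rescaled)


def _count_erode(mask: np.ndarray, count: int, iterations: int) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    out = mask.copy()
    for _ in range(iterations):
        bg_neighbours = ndimage.convolve((~out).astype(int), kernel, mode="constant", cval=1)
        out = out & (bg_neighbours < count)
    return out


def segment_confocal(image: GrayImage, params: SegmentationParams | None = None) -> BinaryImage:
    """Segment a confocal image into a binary mitochondrial mask.

    Stages: median smoothing, contrast enhancement, local median
    threshold AND global threshold, then neighbour-count erosion.
    Deterministic for fixed input and parameters.
    """
    params = params or SegmentationParams()
    params.validate()
    pixels = image.pixels
    if not np.any(pixels > 0):
        warnings.warn("all-zero image: returning empty mask", stacklevel=2)
        return BinaryImage(np.zeros(image.shape, dtype=bool), image.pixel_size_um)

    smoothed = ndimage.median_filter(
        pixels, footprint=disk(params.median_radius_px), mode="reflect"
    )
    enhanced = enhance_contrast(smoothed, params.saturation_fraction)

    size = 2 * params.local_radius_px + 1
    local_median = ndimage.median_filter(enhanced, size=size, mode="reflect")
    local_mask = enhanced > local_median

    if params.global_threshold is not None:
        thr = float(params.global_threshold)
        if not (enhanced.min() <= thr <= enhanced.max()):
            raise ValueError("manual global threshold outside the enhanced intensity range")
    else:
        thr = threshold_triangle(enhanced)
    global_mask = enhanced >= thr

    mask = _count_erode(local_mask & global_mask, params.erode_count, params.erode_iterations)
    return BinaryImage(mask, image.pixel_size_um)


def segment_synthetic(image: GrayImage, threshold: float) -> BinaryImage:
    """Segment a synthetic image with a single global threshold (mask = pixels >= threshold)."""
    if threshold > image.pixels.max():
        return BinaryImage(np.zeros(image.shape, dtype=bool), image.pixel_size_um)
    return BinaryImage(image.pixels >= threshold, image.pixel_size_um)


def area_fraction(mask: BinaryImage, region: tuple[int, int, int, int] | None = None) -> float:
    """Foreground fraction of the mask, optionally within a bounding box.

    ``region`` is (row_min, col_min, row_max, col_max) with exclusive
    upper bounds.
    """
    m = mask.mask
    if region is not None:
        r0, c0, r1, c1 = region
        if r0 < 0 or c0 < 0 or r1 > m.shape[0] or c1 > m.shape[1] or r1 <= r0 or c1 <= c0:
            raise ValueError("region must lie within the image")
        m = m[r0:r1, c0:c1]
    return float(m.mean())
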