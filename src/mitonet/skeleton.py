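"""Topology-preserving skeletonization and the pixel-level skeleton graph."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .segmentation import DEFAULT_PIXEL_SIZE_UM, BinaryImage

# 8-connectivity structuring element
S8 = np.ones((3, 3), dtype=int)

_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=int)

# the four positive-direction 8-neighbour offsets (each undirected edge once)
_HALF_NEIGHBOURHOOD = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class SkeletonGraph:
    """1-px-wide medial axis as a boolean image plus per-pixel degree."""

    skel: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.skel = np.asarray(self.skel).astype(bool)
        if self.skel.ndim != 2:
            raise ValueError("skeleton must be 2-D")

    @property
    def degrees(self) -> np.ndarray:
        """Per-pixel count of 8-connected skeleton neighbours (0 off-skeleton)."""
        counts = ndimage.convolve(self.skel.astype(int), _NEIGHBOUR_KERNEL, mode="constant")
        return np.where(self.skel, counts, 0)

    @property
    def n_pixels(self) -> int:
        return int(self.skel.sum())

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, np.argwhere(self.skel)))

    def total_length_px(self) -> float:
        """Euclidean skeleton length: each undirected 8-neighbour step counted once."""
        return skeleton_length_px(self.skel)


def _shift(skel: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(skel)
    r0, r1 = max(dr, 0), skel.shape[0] + min(dr, 0)
    c0, c1 = max(dc, 0), skel.shape[1] + min(dc, 0)
    out[r0:r1, c0:c1] = skel[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def skeleton_length_px(skel: np.ndarray) -> float:
    """Euclidean skeleton length from 8-neighbour steps.

    Each undirected step is counted once; a diagonal step is skipped when
    either of its two shared orthogonal pixels is present, so staircase
    rasterizations are not double-counted.
    """
    skel = np.asarray(skel).astype(bool)
    total = 0.0
    for dr, dc in _HALF_NEIGHBOURHOOD:
        pair = skel & _shift(skel, dr, dc)
        if dr and dc:  # diagonal: drop if the orthogonal detour exists
            redundant = _shift(skel, dr, 0) | _shift(skel, 0, dc)
            pair &= ~redundant
        total += float(np.hypot(dr, dc)) * int(pair.sum())
    return total


def skeletonize(mask: BinaryImage) -> SkeletonGraph:
    """Reduce a binary mask to its 1-px centreline, preserving topology.

    Connected components of the mask map one-to-one onto connected
    components of the skeleton (single-pixel components are kept).
    """
    skel = _sk_skeletonize(mask.mask)
    return SkeletonGraph(skel, mask.pixel_size_um)
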