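"""Nucleus and cytosol segmentation.

The nucleus mask is built from a maximum-intensity projection (MIP) of the
DAPI channel: triangle threshold, removal of objects smaller than 20 pixels,
binary hole filling, and one dilation with a 3x3 square structuring element.
The target-channel foreground is extracted from the 3D stack after Gaussian
smoothing (sigma 0.5 voxels) with a per-slice triangle threshold and removal
of per-slice objects smaller than 30 pixels.  Subtracting the nucleus
footprint (broadcast over z) from the foreground yields the cytosolic mask,
over which the per-image statistic is the median of the raw channel.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateHistogramError",
    "NucleiMask",
    "ForegroundMask",
    "CytosolicMask",
    "max_intensity_projection",
    "triangle_threshold",
    "segment_nuclei",
    "extract_foreground",
    "cytosolic_mask",
    "cytosolic_intensity",
]

# 2D objects use 8-connectivity, 3D objects 26-connectivity.
STRUCTURE_2D = np.ones((3, 3), dtype=bool)
STRUCTURE_3D = np.ones((3, 3, 3), dtype=bool)


class DegenerateHistogramError(ValueError):
    """Raised when an image is constant and no threshold can separate it."""


@dataclasses.dataclass
class NucleiMask:
    """2D nucleus label map derived from the DAPI MIP.

    Labels run contiguously from 1; background is 0.
    """

    label_map: np.ndarray
    n_objects: int
    source: str = "MIP of DAPI"

    @property
    def footprint(self) -> np.ndarray:
        """Binary (y, x) union of all nuclei."""
        return self.label_map > 0


@dataclasses.dataclass
class ForegroundMask:
    """3D binary foreground of the target channel."""

    mask: np.ndarray
    min_object_area: int = 30
    smoothing_sigma: float = 0.5


@dataclasses.dataclass
class CytosolicMask:
    """3D foreground with the nucleus footprint removed on every slice."""

    mask: np.ndarray
    derivation: str = "foreground minus nucleus"


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Project a (z, y, x) stack to (y, x) by the per-pixel maximum over z."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("expected a non-empty 3D (z, y, x) stack")
    return stack.max(axis=0)


def triangle_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Zack triangle threshold of an intensity histogram.

    Builds an ``n_bins`` histogram over the observed min-max range, draws the
    chord from the histogram peak to the farthest non-empty tail bin, and
    returns the bin-center intensity that maximizes the perpendicular distance
    between histogram and chord.  Binarization convention: ``value > t``.

    Raises
    ------
    DegenerateHistogramError
        If the input is constant (degenerate histogram).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise DegenerateHistogramError("degenerate histogram: constant image")
    hist, edges = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])

    peak = int(np.argmax(hist))
    nonzero = np.flatnonzero(hist)
    first, last = int(nonzero[0]), int(nonzero[-1])
    # tail = farthest non-empty bin from the peak
    tail = first if (peak - first) >= (last - peak) else last
    if tail == peak:  # single occupied bin; split the range
        return float(centers[peak])

    lo, hi = (tail, peak) if tail < peak else (peak, tail)
    idx = np.arange(lo, hi + 1, dtype=np.float64)
    # perpendicular distance from (i, h_i) to the peak-tail chord; the
    # constant 1/|chord| factor is dropped as it does not change the argmax
    x1, y1 = float(peak), float(hist[peak])
    x2, y2 = float(tail), float(hist[tail])
    dist = np.abs((y2 - y1) * idx - (x2 - x1) * hist[lo : hi + 1] + x2 * y1 - y2 * x1)
    best = int(idx[int(np.argmax(dist))])
    return float(centers[best])


def _remove_small_2d(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected 2D objects with area strictly below *min_area*."""
    labels, n = ndi.label(mask, structure=STRUCTURE_2D)
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def segment_nuclei(dapi: np.ndarray, min_area: int = 20, n_bins: int = 256) -> NucleiMask:
    """Segment nuclei from a DAPI stack.

    Pipeline: MIP -> triangle threshold -> remove objects with area < 20 px
    -> fill holes -> dilate once with a 3x3 structuring element -> relabel.
    """
    mip = max_intensity_projection(dapi)
    t = triangle_threshold(mip, n_bins=n_bins)
    binary = mip > t
    binary = _remove_small_2d(binary, min_area)
    binary = ndi.binary_fill_holes(binary)
    binary = ndi.binary_dilation(binary, structure=STRUCTURE_2D, iterations=1)
    label_map, n = ndi.label(binary, structure=STRUCTURE_2D)
    return NucleiMask(label_map=label_map, n_objects=int(n))


def extract_foreground(
    channel: np.ndarray,
    smoothing_sigma: float = 0.5,
    min_area: int = 30,
    n_bins: int = 256,
    per_slice: bool = True,
) -> ForegroundMask:
    """Extract the 3D foreground of a fluorescence channel.

    The whole stack is smoothed with a 3D Gaussian (``smoothing_sigma`` in
    voxel units), then each z-slice is thresholded with its own triangle
    threshold and 2D objects smaller than ``min_area`` pixels are removed.
    A slice whose smoothed histogram is degenerate (constant) contributes an
    empty foreground and is logged, not fatal.  ``per_slice=False`` switches
    to a single global triangle threshold for the whole stack.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) stack")
    smoothed = ndi.gaussian_filter(channel, sigma=smoothing_sigma)
    mask = np.zeros(channel.shape, dtype=bool)
    if per_slice:
        for z in range(channel.shape[0]):
            try:
                t = triangle_threshold(smoothed[z], n_bins=n_bins)
            except DegenerateHistogramError:
                logger.warning("slice %d: degenerate histogram, empty foreground", z)
                continue
            mask[z] = _remove_small_2d(smoothed[z] > t, min_area)
    else:
        t = triangle_threshold(smoothed, n_bins=n_bins)
        for z in range(channel.shape[0]):
            mask[z] = _remove_small_2d(smoothed[z] > t, min_area)
    return ForegroundMask(mask=mask, min_object_area=min_area, smoothing_sigma=smoothing_sigma)


def cytosolic_mask(fg: ForegroundMask, nuclei: NucleiMask) -> CytosolicMask:
    """Subtract the nucleus footprint (broadcast over z) from the foreground."""
    if fg.mask.shape[1:] != nuclei.label_map.shape:
        raise ValueError(
            f"(y, x) shape mismatch: foreground {fg.mask.shape[1:]} vs "
            f"nuclei {nuclei.label_map.shape}"
        )
    return CytosolicMask(mask=fg.mask & ~nuclei.footprint[np.newaxis, :, :])


class EmptyMaskError(ValueError):
    """Raised when an image has no cytosolic voxels to measure."""


def cytosolic_intensity(channel: np.ndarray, mask: CytosolicMask) -> float:
    """Median of the raw (unsmoothed) channel over the cytosolic mask."""
    channel = np.asarray(channel)
    if channel.shape != mask.mask.shape:
        raise ValueError("channel and mask shapes differ")
    if not mask.mask.any():
        raise EmptyMaskError("no cytosol: empty cytosolic mask")
    return float(np.median(channel[mask.mask]))
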