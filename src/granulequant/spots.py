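"""3D granule (spot) segmentation and cluster-level filtering.

Detection follows the classic dot-filter recipe for fluorescent puncta:
auto-contrast normalization of the raw channel, 3D Gaussian smoothing
(sigma = 1 voxel), a scale-normalized negative Laplacian-of-Gaussian
response at a configurable scale, and binarization of the response at a
cutoff.  The scale and cutoff are batch-level tuning knobs; their accepted
ranges default to scale in [0.75, 1] and cutoff in [0.015, 0.045].

Detected voxels are grouped with 26-connectivity into clusters; each
cluster records its voxel count ("area" in pixel units), maximum raw
intensity in detector counts, centroid and physical volume.  Cluster-level
quality filters remove implausible detections: area below 5 or above 300
voxels, or maximum raw intensity above 30,000 counts (saturation /
non-specific staining).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SpotFilterParams",
    "GranuleCluster",
    "normalize_autocontrast",
    "spot_filter_3d",
    "label_clusters",
    "filter_clusters",
    "detect_granules",
]

STRUCTURE_3D = np.ones((3, 3, 3), dtype=bool)

SCALE_RANGE = (0.75, 1.0)
CUTOFF_RANGE = (0.015, 0.045)


@dataclasses.dataclass
class SpotFilterParams:
    """Tuning of the 3D spot filter.

    ``scale`` and ``cutoff`` must fall inside their configured ranges —
    they are the per-batch adjustable pair of the detector.
    """

    smoothing_sigma: float = 1.0
    scale: float = 1.0
    cutoff: float = 0.045
    autocontrast_k: tuple[float, float] = (1.0, 12.0)
    scale_range: tuple[float, float] = SCALE_RANGE
    cutoff_range: tuple[float, float] = CUTOFF_RANGE

    def __post_init__(self) -> None:
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be positive")
        lo, hi = self.scale_range
        if not lo <= self.scale <= hi:
            raise ValueError(f"scale {self.scale} outside configured range {self.scale_range}")
        lo, hi = self.cutoff_range
        if not lo <= self.cutoff <= hi:
            raise ValueError(f"cutoff {self.cutoff} outside configured range {self.cutoff_range}")


@dataclasses.dataclass
class GranuleCluster:
    """One detected 3D spot."""

    label: int
    voxel_count: int
    max_intensity: float          #: max of the raw channel over member voxels
    centroid: tuple[float, float, float]
    volume_um3: float
    projected_area_um2: float     #: area of the (y, x) footprint

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")


def normalize_autocontrast(
    channel: np.ndarray, k_low: float = 1.0, k_high: float = 6.0
) -> np.ndarray:
    """Clip to ``[mean - k_low*SD, mean + k_high*SD]`` and rescale to [0, 1]."""
    channel = np.asarray(channel, dtype=np.float64)
    mu, sd = float(channel.mean()), float(channel.std())
    if sd == 0:
        raise ValueError("degenerate image: zero variance, cannot auto-contrast")
    lo = max(mu - k_low * sd, float(channel.min()))
    hi = min(mu + k_high * sd, float(channel.max()))
    if hi <= lo:
        raise ValueError("degenerate clip window")
    clipped = np.clip(channel, lo, hi)
    return (clipped - lo) / (hi - lo)


def spot_filter_3d(channel: np.ndarray, params: SpotFilterParams) -> np.ndarray:
    """Binary spot mask from a [0, 1]-normalized 3D grid.

    Smooths at ``params.smoothing_sigma``, computes the scale-normalized
    negative LoG response ``-s^2 * LoG_s`` at ``s = params.scale``, and
    keeps voxels with response strictly above ``params.cutoff``.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) grid")
    if channel.min() < -1e-9 or channel.max() > 1 + 1e-9:
        raise ValueError("spot filter expects a [0, 1]-normalized grid")
    smoothed = ndi.gaussian_filter(channel, sigma=params.smoothing_sigma)
    s = params.scale
    response = -(s**2) * ndi.gaussian_laplace(smoothed, sigma=s)
    return response > params.cutoff


def label_clusters(
    mask: np.ndarray,
    raw: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> list[GranuleCluster]:
    """26-connected labeling of a spot mask with per-cluster statistics.

    ``max_intensity`` is measured on the raw (pre-normalization) channel so
    downstream photon-count thresholds keep their physical meaning.
    """
    mask = np.asarray(mask, dtype=bool)
    raw = np.asarray(raw)
    if mask.shape != raw.shape:
        raise ValueError("mask and raw shapes differ")
    labels, n = ndi.label(mask, structure=STRUCTURE_3D)
    if n == 0:
        return []
    vz, vy, vx = voxel_size
    voxel_vol = vz * vy * vx
    idx = np.arange(1, n + 1)
    counts = ndi.sum_labels(mask, labels, idx)
    maxima = ndi.labeled_comprehension(raw, labels, idx, np.max, float, np.nan)
    centroids = ndi.center_of_mass(mask, labels, idx)
    clusters = []
    for i, lab in enumerate(idx):
        member = labels == lab
        proj = member.any(axis=0)
        clusters.append(
            GranuleCluster(
                label=int(lab),
                voxel_count=int(counts[i]),
                max_intensity=float(maxima[i]),
                centroid=tuple(float(c) for c in centroids[i]),
                volume_um3=float(counts[i]) * voxel_vol,
                projected_area_um2=float(proj.sum()) * vy * vx,
            )
        )
    return clusters


def filter_clusters(
    clusters: list[GranuleCluster],
    min_area: int = 5,
    max_area: int = 300,
    max_intensity: float = 30_000.0,
) -> list[GranuleCluster]:
    """Keep clusters with area in ``[min_area, max_area]`` voxels and maximum
    raw intensity not above ``max_intensity`` counts.

    Removals are strict ("under 5", "over 300", "above 30,000"), so clusters
    exactly at a boundary are kept.  Order-preserving and idempotent.
    """
    return [
        c
        for c in clusters
        if min_area <= c.voxel_count <= max_area and c.max_intensity <= max_intensity
    ]


def detect_granules(
    raw: np.ndarray,
    voxel_size: tuple[float, float, float],
    params: SpotFilterParams | None = None,
    apply_filters: bool = True,
) -> list[GranuleCluster]:
    """Full detection chain: auto-contrast -> spot filter -> label -> filter."""
    if params is None:
        params = SpotFilterParams()
    normalized = normalize_autocontrast(raw, *params.autocontrast_k)
    mask = spot_filter_3d(normalized, params)
    clusters = label_clusters(mask, raw, voxel_size)
    if apply_filters:
        clusters = filter_clusters(clusters)
    return clusters
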