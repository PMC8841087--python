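"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal method available
(exhaustive search, flood fill, dense grids) and stay independent of the
library code paths they check.
"""

from __future__ import annotations

import numpy as np


def triangle_threshold_bruteforce(values: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive-search triangle threshold.

    Recomputes, for every candidate bin between the histogram peak and the
    farthest non-empty tail, the point-to-line distance to the peak-tail
    chord with the explicit two-point line formula, and returns the center
    of the winning bin.
    """
    v = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(hist))
    nonzero = np.flatnonzero(hist)
    first, last = int(nonzero[0]), int(nonzero[-1])
    tail = first if (peak - first) >= (last - peak) else last
    if tail == peak:
        return float(centers[peak])
    x1, y1 = float(peak), float(hist[peak])
    x2, y2 = float(tail), float(hist[tail])
    denom = np.hypot(y2 - y1, x2 - x1)
    best_bin, best_dist = None, -1.0
    lo, hi = min(peak, tail), max(peak, tail)
    for i in range(lo, hi + 1):
        d = abs((y2 - y1) * i - (x2 - x1) * hist[i] + x2 * y1 - y2 * x1) / denom
        if d > best_dist:
            best_dist, best_bin = d, i
    return float(centers[best_bin])


def flood_fill_label(mask: np.ndarray, connectivity: str = "full") -> tuple[np.ndarray, int]:
    """Connected-component labeling by explicit stack-based flood fill.

    ``connectivity="full"`` means 8-connectivity in 2D and 26-connectivity
    in 3D (all neighbors whose index offsets are in {-1, 0, 1}).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = [
        off
        for off in np.ndindex(*(3,) * mask.ndim)
        if any(o != 1 for o in off)
    ]
    offsets = [tuple(o - 1 for o in off) for off in offsets]
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            pos = stack.pop()
            for off in offsets:
                nb = tuple(p + o for p, o in zip(pos, off))
                if any(n < 0 or n >= s for n, s in zip(nb, mask.shape)):
                    continue
                if mask[nb] and not labels[nb]:
                    labels[nb] = current
                    stack.append(nb)
    return labels, current


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label maps induce the same partition of foreground."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or np.any((a > 0) != (b > 0)):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].ravel(), b[fg].ravel()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


def anova_f_by_hand(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F from the raw sum-of-squares decomposition."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Closed-form Wilson score interval, written out from the formula."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def log_response_at_center_analytic(
    amplitude: float,
    blob_sigma: tuple[float, float, float],
    smooth_sigma: float,
    scale: float,
) -> float:
    """Closed-form scale-normalized negative-LoG response at a blob center.

    A Gaussian blob of per-axis width sigma_b convolved with the smoothing
    and LoG Gaussians stays Gaussian with width
    ``sigma_t = sqrt(sigma_b^2 + smooth^2 + scale^2)`` and center amplitude
    ``A' = A * prod(sigma_b / sigma_t)``; the negative Laplacian at the
    center of a Gaussian is ``A' * sum(1 / sigma_t^2)``.
    """
    sb = np.asarray(blob_sigma, dtype=float)
    st2 = sb**2 + smooth_sigma**2 + scale**2
    a_eff = amplitude * np.prod(sb / np.sqrt(st2))
    return float(scale**2 * a_eff * np.sum(1.0 / st2))
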