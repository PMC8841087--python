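"""Per-cell granule morphometry: count, mean area and mean volume.

A cell body is delimited by a 2D region of interest (ROI).  Clusters are
attributed to the ROI by their (y, x) centroid, detections whose centroid
falls inside a nucleus footprint are discarded, and a minimum detectable
size (equivalent spherical diameter, default 0.01 um) is enforced.  Group
comparisons delegate to one-way ANOVA with Tukey HSD per metric.

ROIs live on disk as a JSON document holding, for each ROI, the run-length
encoding of its binary mask — an exact, text-only round trip.  For
synthetic data the generator's soma label map supplies the ROIs directly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spots import GranuleCluster
from .segmentation import NucleiMask
from . import stats as gqstats

__all__ = [
    "CellROI",
    "load_rois",
    "save_rois",
    "rois_from_label_map",
    "per_cell_granule_stats",
    "group_morphometry",
]


@dataclasses.dataclass
class CellROI:
    """One cell-body region of interest: a 2D binary mask over (y, x)."""

    id: str
    mask: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError(f"ROI {self.id!r}: mask must be a non-empty 2D grid")


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Flat run-length encoding, starting with a run of zeros."""
    flat = mask.ravel(order="C").astype(np.int8)
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:  # convention: first run counts zeros
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: Sequence[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    if pos != flat.size:
        raise ValueError("run lengths do not cover the mask")
    return flat.reshape(shape)


def save_rois(rois: Sequence[CellROI], path: str | Path) -> None:
    doc = [
        dict(id=r.id, image_id=r.image_id, shape=list(r.mask.shape), rle=_rle_encode(r.mask))
        for r in rois
    ]
    Path(path).write_text(json.dumps(doc))


def load_rois(path: str | Path, image_shape: tuple[int, int] | None = None) -> list[CellROI]:
    """Read ROIs from the JSON run-length format written by :func:`save_rois`.

    If *image_shape* is given, every ROI must match it exactly.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed ROI file at line {exc.lineno}: {exc.msg}") from exc
    rois = []
    for entry in doc:
        shape = tuple(entry["shape"])
        if image_shape is not None and shape != tuple(image_shape):
            raise ValueError(
                f"ROI {entry.get('id')!r} shape {shape} outside image bounds {image_shape}"
            )
        rois.append(
            CellROI(
                id=str(entry["id"]),
                mask=_rle_decode(entry["rle"], shape),
                image_id=str(entry.get("image_id", "")),
            )
        )
    return rois


def rois_from_label_map(label_map: np.ndarray, image_id: str = "") -> list[CellROI]:
    """One ROI per labeled object of a 2D label map (e.g. soma ground truth)."""
    label_map = np.asarray(label_map)
    return [
        CellROI(id=f"cell{lab}", mask=label_map == lab, image_id=image_id)
        for lab in np.unique(label_map)
        if lab != 0
    ]


def per_cell_granule_stats(
    clusters: Sequence[GranuleCluster],
    roi: CellROI,
    nuclei: NucleiMask | None,
    voxel_size: tuple[float, float, float],
    min_size_um: float = 0.01,
) -> dict:
    """Granule count, mean projected area (um^2) and mean volume (um^3) in one cell.

    A cluster belongs to the cell when its (y, x) centroid lies inside the
    ROI mask and outside every nucleus footprint, and its equivalent
    spherical diameter ``(6 V / pi)^(1/3)`` is at least *min_size_um*.
    Means are NaN when the cell has no granules.
    """
    nucleus_fp = nuclei.footprint if nuclei is not None else None
    count, areas, volumes = 0, [], []
    for c in clusters:
        _, cy, cx = c.centroid
        iy, ix = int(round(cy)), int(round(cx))
        if not (0 <= iy < roi.mask.shape[0] and 0 <= ix < roi.mask.shape[1]):
            continue
        if not roi.mask[iy, ix]:
            continue
        if nucleus_fp is not None and nucleus_fp[iy, ix]:
            continue
        eq_diameter = (6.0 * c.volume_um3 / math.pi) ** (1.0 / 3.0)
        if eq_diameter < min_size_um:
            continue
        count += 1
        areas.append(c.projected_area_um2)
        volumes.append(c.volume_um3)
    return dict(
        cell_id=roi.id,
        image_id=roi.image_id,
        count=count,
        mean_area_um2=float(np.mean(areas)) if areas else float("nan"),
        mean_volume_um3=float(np.mean(volumes)) if volumes else float("nan"),
    )


def group_morphometry(
    per_cell: pd.DataFrame,
    metrics: Sequence[str] = ("count", "mean_area_um2", "mean_volume_um3"),
    min_cells: int = 16,
) -> dict[str, dict]:
    """ANOVA + Tukey comparison of per-cell metrics across conditions.

    *per_cell* needs a ``condition`` column plus the metric columns.  A
    warning is issued for conditions with fewer than *min_cells* cells.
    """
    import warnings

    if "condition" not in per_cell.columns:
        raise ValueError("per_cell table needs a 'condition' column")
    sizes = per_cell.groupby("condition").size()
    small = sizes[sizes < min_cells]
    if not small.empty:
        warnings.warn(
            f"conditions below {min_cells} cells: {dict(small)}", stacklevel=2
        )
    results = {}
    for metric in metrics:
        groups = {
            str(cond): sub[metric].dropna().to_numpy()
            for cond, sub in per_cell.groupby("condition", sort=False)
        }
        results[metric] = gqstats.anova_tukey(groups)
    return results
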