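"""End-to-end analyses.

Two orchestrated pipelines mirror the two quantifications of the study:

* :func:`run_ncdn_analysis` — cytosolic signal intensity.  Per image:
  nucleus segmentation from DAPI, target-channel foreground, cytosolic
  mask, median cytosolic intensity.  Per batch, every median is divided by
  the median of the control images of that batch; condition-level 2-SD
  outliers are removed; each knockdown condition is compared to control by
  a bootstrapped difference of medians.

* :func:`run_fus_analysis` — granule intensity and morphometry.  Per
  image: 3D spot detection, cluster filtering, skew-normal peak of the
  cluster maximum intensities; per-batch control-peak normalization;
  outlier removal; bootstrapped difference of medians of the normalized
  peaks.  Optionally, per-cell granule count / mean area / mean volume with
  one-way ANOVA + Tukey across conditions.

Per-image failures (degenerate or empty images) are logged and the image
is excluded; a missing control in any batch aborts the run.  All numbers
are reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import morphometry as morpho
from . import segmentation as seg
from . import spots
from . import stats as gqstats
from .config import PipelineConfig
from .io import ImageStack

logger = logging.getLogger(__name__)

__all__ = ["AnalysisReport", "run_ncdn_analysis", "run_fus_analysis"]


@dataclasses.dataclass
class AnalysisReport:
    """Tables, group comparisons and reproducibility metadata of one run."""

    per_image: pd.DataFrame
    comparisons: dict[str, gqstats.BootstrapResult]
    morphometry: dict[str, dict] | None
    per_cell: pd.DataFrame | None
    metadata: dict

    def summary(self) -> pd.DataFrame:
        rows = [
            dict(
                comparison=name,
                statistic=res.statistic,
                observed_diff=res.observed,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                p=res.p,
                B=res.B,
            )
            for name, res in self.comparisons.items()
        ]
        return pd.DataFrame(rows)


def _check_batches_have_control(per_image: pd.DataFrame, control: str) -> None:
    for batch, sub in per_image.groupby("batch"):
        if not (sub["condition"] == control).any():
            raise ValueError(f"batch {batch!r} has no {control!r} images")


def _compare_conditions(
    values: pd.DataFrame,
    value_column: str,
    config: PipelineConfig,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, gqstats.BootstrapResult]]:
    """Outlier removal per condition, then bootstrap of each KD vs control."""
    flagged = []
    for cond, sub in values.groupby("condition", sort=False):
        _, removed = gqstats.remove_outliers(sub[value_column].to_numpy(), k=config.outlier_k)
        flagged.append(pd.Series(removed, index=sub.index))
    values = values.copy()
    values["outlier"] = pd.concat(flagged).reindex(values.index)
    kept = values[~values["outlier"]]
    ctl = kept.loc[kept["condition"] == config.control_condition, value_column].to_numpy()
    comparisons: dict[str, gqstats.BootstrapResult] = {}
    kd_conditions = [c for c in values["condition"].unique() if c != config.control_condition]
    seeds = np.random.SeedSequence(seed).generate_state(max(len(kd_conditions), 1)) % (2**31)
    for i, cond in enumerate(kd_conditions):
        kd = kept.loc[kept["condition"] == cond, value_column].to_numpy()
        comparisons[f"{cond} vs {config.control_condition}"] = gqstats.bootstrap_difference(
            kd, ctl, statistic="median", B=config.bootstrap_B,
            seed=int(seeds[i]), ci_level=config.ci_level,
        )
    return values, comparisons


def run_ncdn_analysis(
    stacks: Sequence[ImageStack],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Cytosolic-intensity pipeline (median per image, batch-normalized)."""
    config = config or PipelineConfig()
    rows = []
    for stack in stacks:
        try:
            nuclei = seg.segment_nuclei(
                stack.channels[config.dapi_channel], min_area=config.nuclei_min_area_px
            )
            fg = seg.extract_foreground(
                stack.channels[config.target_channel],
                smoothing_sigma=config.foreground_sigma,
                min_area=config.foreground_min_area_px,
                per_slice=config.foreground_per_slice,
            )
            cyt = seg.cytosolic_mask(fg, nuclei)
            median = seg.cytosolic_intensity(stack.channels[config.target_channel], cyt)
        except (seg.DegenerateHistogramError, seg.EmptyMaskError) as exc:
            logger.warning("image %s excluded: %s", stack.image_id, exc)
            continue
        rows.append(
            dict(
                image_id=stack.image_id, condition=stack.condition,
                batch=stack.batch, median_cytosolic=median,
            )
        )
    per_image = pd.DataFrame(rows)
    if per_image.empty:
        raise ValueError("no analysable images")
    _check_batches_have_control(per_image, config.control_condition)
    # per-batch normalization by the median of the control medians
    normalized = []
    for batch, sub in per_image.groupby("batch", sort=False):
        ctl = sub.loc[sub["condition"] == config.control_condition, "median_cytosolic"]
        normalized.append(sub["median_cytosolic"] / float(ctl.median()))
    per_image["normalized"] = pd.concat(normalized).reindex(per_image.index)
    per_image, comparisons = _compare_conditions(per_image, "normalized", config, seed)
    return AnalysisReport(
        per_image=per_image,
        comparisons=comparisons,
        morphometry=None,
        per_cell=None,
        metadata=dict(analysis="cytosolic-intensity", seed=seed, config_hash=config.hash,
                      n_images=len(per_image)),
    )


def run_fus_analysis(
    stacks: Sequence[ImageStack],
    config: PipelineConfig | None = None,
    seed: int = 0,
    rois: Mapping[str, Sequence[morpho.CellROI]] | None = None,
) -> AnalysisReport:
    """Granule-intensity pipeline, with optional per-cell morphometry.

    *rois* maps ``image_id`` to the cell-body ROIs of that image; when
    omitted, the morphometry stage is skipped.
    """
    config = config or PipelineConfig()
    cluster_rows = []
    clusters_by_image: dict[str, list[spots.GranuleCluster]] = {}
    nuclei_by_image: dict[str, seg.NucleiMask] = {}
    for stack in stacks:
        try:
            detected = spots.detect_granules(
                stack.channels[config.target_channel],
                stack.voxel_size,
                params=config.spot_params(),
            )
        except ValueError as exc:
            logger.warning("image %s excluded: %s", stack.image_id, exc)
            continue
        detected = spots.filter_clusters(
            detected,
            min_area=config.cluster_min_area,
            max_area=config.cluster_max_area,
            max_intensity=config.cluster_max_intensity,
        )
        clusters_by_image[stack.image_id] = detected
        for c in detected:
            cluster_rows.append(
                dict(
                    image_id=stack.image_id, condition=stack.condition,
                    batch=stack.batch, label=c.label, voxel_count=c.voxel_count,
                    max_intensity=c.max_intensity,
                    centroid_z=c.centroid[0], centroid_y=c.centroid[1],
                    centroid_x=c.centroid[2], volume_um3=c.volume_um3,
                )
            )
    clusters = pd.DataFrame(cluster_rows)
    if clusters.empty:
        raise ValueError("no granules detected in any image")
    # images with too few clusters cannot support a distribution fit
    sizes = clusters.groupby("image_id").size()
    fit_ok = sizes[sizes >= 10].index
    dropped = sizes[sizes < 10]
    if not dropped.empty:
        logger.warning("images with <10 clusters excluded from fits: %s", list(dropped.index))
    peaks = gqstats.peak_of_condition(
        clusters[clusters["image_id"].isin(fit_ok)],
        control_condition=config.control_condition,
    )
    _check_batches_have_control(peaks, config.control_condition)
    peaks, comparisons = _compare_conditions(peaks, "normalized_peak", config, seed)

    morphometry_result, per_cell_df = None, None
    if rois is not None:
        per_cell = []
        condition_of = {s.image_id: s.condition for s in stacks}
        for stack in stacks:
            if stack.image_id not in clusters_by_image:
                continue
            if stack.image_id not in nuclei_by_image:
                try:
                    nuclei_by_image[stack.image_id] = seg.segment_nuclei(
                        stack.channels[config.dapi_channel],
                        min_area=config.nuclei_min_area_px,
                    )
                except seg.DegenerateHistogramError:
                    nuclei_by_image[stack.image_id] = None  # type: ignore[assignment]
            for roi in rois.get(stack.image_id, []):
                row = morpho.per_cell_granule_stats(
                    clusters_by_image[stack.image_id], roi,
                    nuclei_by_image[stack.image_id], stack.voxel_size,
                    min_size_um=config.min_granule_size_um,
                )
                row["condition"] = condition_of[stack.image_id]
                per_cell.append(row)
        per_cell_df = pd.DataFrame(per_cell)
        if not per_cell_df.empty and per_cell_df["condition"].nunique() >= 2:
            morphometry_result = morpho.group_morphometry(
                per_cell_df, min_cells=config.min_cells_per_group
            )
    return AnalysisReport(
        per_image=peaks,
        comparisons=comparisons,
        morphometry=morphometry_result,
        per_cell=per_cell_df,
        metadata=dict(analysis="granule-intensity", seed=seed, config_hash=config.hash,
                      n_images=int(peaks["image_id"].nunique()),
                      n_clusters=int(len(clusters))),
    )
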