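"""Pipeline configuration.

Every default is either a value taken from the published analysis protocol
(object-size cutoffs, sigmas, spot-filter ranges, cluster filters, outlier
rule, bootstrap settings) or a documented package convention; the docstring
of each consuming function says which.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclasses.dataclass
class PipelineConfig:
    # channel mapping
    dapi_channel: str = "dapi"
    target_channel: str = "target"
    # nucleus segmentation
    nuclei_min_area_px: int = 20          # objects smaller than 20 px removed
    # foreground extraction
    foreground_sigma: float = 0.5         # 3D Gaussian smoothing, voxel units
    foreground_min_area_px: int = 30      # per-slice objects smaller than 30 px removed
    foreground_per_slice: bool = True     # per-slice triangle threshold (convention switch)
    # spot filter
    spot_smoothing_sigma: float = 1.0
    spot_scale: float = 1.0               # within [0.75, 1]
    spot_cutoff: float = 0.045            # within [0.015, 0.045]
    autocontrast_k: tuple[float, float] = (1.0, 12.0)  # convention
    # cluster filters
    cluster_min_area: int = 5
    cluster_max_area: int = 300
    cluster_max_intensity: float = 30_000.0
    # statistics
    control_condition: str = "CTL-KD"
    outlier_k: float = 2.0
    bootstrap_B: int = 10_000
    ci_level: float = 0.95
    # morphometry
    min_granule_size_um: float = 0.01
    min_cells_per_group: int = 16
    # geometry
    voxel_size: tuple[float, float, float] = (0.45, 0.1, 0.1)

    def spot_params(self):
        from .spots import SpotFilterParams

        return SpotFilterParams(
            smoothing_sigma=self.spot_smoothing_sigma,
            scale=self.spot_scale,
            cutoff=self.spot_cutoff,
            autocontrast_k=tuple(self.autocontrast_k),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("autocontrast_k", "voxel_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def hash(self) -> str:
        """Stable digest of the resolved configuration, for report metadata."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
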