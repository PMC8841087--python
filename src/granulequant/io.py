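"""Image containers and disk I/O.

An :class:`ImageStack` bundles the channels of one confocal acquisition
(z, y, x voxel grids) with its voxel size and the experimental labels
(condition, batch) that drive downstream normalization.  Stacks are stored
on disk as multi-page TIFF, one file per channel, next to a CSV manifest.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["ImageStack", "write_stack", "read_stack", "read_manifest", "write_manifest"]

#: axis order of every voxel grid in the package
AXES = ("z", "y", "x")


@dataclasses.dataclass
class ImageStack:
    """One acquisition: per-channel 3D voxel grids plus metadata.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"dapi"``, ``"target"``) to a
        ``(z, y, x)`` float array of detector counts.
    voxel_size
        Physical voxel edge lengths in micrometres, ordered ``(z, y, x)``.
    condition
        Experimental condition label (e.g. ``"CTL-KD"``, ``"NCDN-KD1"``).
    batch
        Experimental-batch label ("week"); normalization is per batch.
    image_id
        Unique identifier within a dataset.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    condition: str = "CTL-KD"
    batch: str = "batch0"
    image_id: str = "image0"

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len({s for s in shapes.values()}) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for a in self.channels.values():
            if a.ndim != 3:
                raise ValueError("channels must be 3D (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx


def write_stack(stack: ImageStack, directory: str | Path) -> list[Path]:
    """Write each channel as ``<image_id>_<channel>.tif`` under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in stack.channels.items():
        path = directory / f"{stack.image_id}_{name}.tif"
        tifffile.imwrite(
            path,
            np.asarray(arr, dtype=np.float32),
            photometric="minisblack",
            metadata={"axes": "ZYX", "voxel_size_um": list(stack.voxel_size)},
        )
        paths.append(path)
    return paths


def read_stack(
    directory: str | Path,
    image_id: str,
    channel_names: tuple[str, ...],
    voxel_size: tuple[float, float, float],
    condition: str,
    batch: str,
) -> ImageStack:
    """Read the per-channel TIFFs written by :func:`write_stack`."""
    directory = Path(directory)
    channels = {}
    for name in channel_names:
        path = directory / f"{image_id}_{name}.tif"
        if not path.exists():
            raise FileNotFoundError(path)
        channels[name] = np.asarray(tifffile.imread(path), dtype=np.float64)
    return ImageStack(channels, voxel_size, condition, batch, image_id)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest (columns: image_id, condition, batch, ...)."""
    manifest = pd.read_csv(path)
    required = {"image_id", "condition", "batch"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return manifest


def load_dataset(
    directory: str | Path,
    channel_names: tuple[str, ...] = ("dapi", "target"),
    voxel_size: tuple[float, float, float] = (0.45, 0.1, 0.1),
) -> list[ImageStack]:
    """Load all stacks listed in ``<directory>/manifest.csv``."""
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.csv")
    return [
        read_stack(directory, row.image_id, channel_names, voxel_size, row.condition, row.batch)
        for row in manifest.itertuples()
    ]
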