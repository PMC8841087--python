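"""Synthetic multi-channel confocal z-stack generator with ground truth.

Each simulated acquisition emulates a cultured cortical neuron field:

* a DAPI channel containing smooth ellipsoidal nuclei;
* a target channel (FUS- or NCDN-like) with a diffuse cytosolic compartment
  (soma shell plus a few random-walk neurites), punctate granules rendered as
  3D Gaussian blobs that are isotropic in micrometres (hence anisotropic in
  voxels), and an optionally bright diffuse nuclear compartment;
* Poisson shot noise on the expected counts followed by additive Gaussian
  read noise, applied last, after the ground truth is recorded.

Granule count per image is Poisson with mean ``density x cytosol volume``;
granule half-widths are log-normal in micrometres and peak amplitudes are
gamma-distributed in detector counts.  Per-condition multipliers modulate
density, size, amplitude and cytosolic baseline; per-batch multiplicative
gain jitter makes per-batch control normalization non-trivial, mirroring
acquisitions spread over experimental weeks.

All randomness flows from a single integer seed; identical parameters and
seed give bit-identical stacks.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .io import ImageStack, write_manifest, write_stack

__all__ = [
    "ConditionEffect",
    "SimulationParams",
    "GroundTruth",
    "generate_neuron_stack",
    "generate_experiment",
    "Dataset",
]


@dataclasses.dataclass
class ConditionEffect:
    """Multiplicative knockdown effects relative to the control condition."""

    density: float = 1.0    #: granules per cytosol volume
    size: float = 1.0       #: granule half-width (sigma)
    amplitude: float = 1.0  #: granule peak amplitude
    cytosol: float = 1.0    #: diffuse cytosolic baseline


def _default_effects() -> dict[str, ConditionEffect]:
    return {"CTL-KD": ConditionEffect()}


@dataclasses.dataclass
class SimulationParams:
    """Parameters of one synthetic acquisition.

    Attributes
    ----------
    image_shape
        Voxel grid ``(z, y, x)``.
    voxel_size
        Micrometres per voxel along ``(z, y, x)``; the default matches a
        63x confocal acquisition with a 0.45 um z-interval.
    n_nuclei
        Number of neurons (nuclei) per field.
    nucleus_radius_um / nucleus_z_radius_um
        Uniform ranges for the in-plane and axial nucleus semi-axes.
    soma_scale
        In-plane soma radius as a multiple of the nucleus radius.
    n_neurites, neurite_radius_um, neurite_length_um
        Random-walk neurite tubes grown from each soma.
    granule_density_per_um3
        Expected granules per um^3 of cytosol (Poisson mean = density x V).
    granule_sigma_median_um, granule_sigma_log_sd
        Log-normal law of the granule half-width in micrometres.
    granule_amplitude_shape, granule_amplitude_scale
        Gamma law of the granule peak amplitude in detector counts.
    cytosol_baseline, nuclear_amplitude, dapi_amplitude, background
        Diffuse compartment levels in detector counts.
    noise_gain, read_noise_sd
        Poisson shot noise gain (0 disables shot noise) and Gaussian read
        noise SD in counts (0 disables read noise).
    condition_effects
        Per-condition :class:`ConditionEffect` multipliers.
    batch_gain_log_sd
        SD of the log-normal per-batch global intensity jitter.
    """

    image_shape: tuple[int, int, int] = (16, 256, 256)
    voxel_size: tuple[float, float, float] = (0.45, 0.1, 0.1)
    n_nuclei: int = 4
    nucleus_radius_um: tuple[float, float] = (2.4, 3.2)
    nucleus_z_radius_um: tuple[float, float] = (1.6, 2.2)
    soma_scale: float = 1.7
    n_neurites: int = 3
    neurite_radius_um: float = 0.35
    neurite_length_um: float = 7.0
    granule_density_per_um3: float = 0.12
    granule_sigma_median_um: float = 0.10
    granule_sigma_log_sd: float = 0.2
    granule_amplitude_shape: float = 20.0
    granule_amplitude_scale: float = 150.0
    cytosol_baseline: float = 40.0
    nuclear_amplitude: float = 15.0
    dapi_amplitude: float = 500.0
    background: float = 5.0
    psf_sigma_um: tuple[float, float] = (0.35, 0.08)  #: (axial, lateral) PSF width
    diffuse_blur_vox: tuple[float, float, float] = (0.8, 3.0, 3.0)
    noise_gain: float = 1.0
    read_noise_sd: float = 3.0
    condition_effects: dict[str, ConditionEffect] = dataclasses.field(
        default_factory=_default_effects
    )
    batch_gain_log_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.image_shape):
            raise ValueError("image_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be strictly positive")
        if self.granule_density_per_um3 <= 0:
            raise ValueError("granule density must be strictly positive")
        if self.granule_sigma_median_um <= 0 or self.granule_amplitude_scale <= 0:
            raise ValueError("granule size/amplitude parameters must be positive")
        if min(self.nucleus_radius_um) <= 0 or min(self.nucleus_z_radius_um) <= 0:
            raise ValueError("nucleus radii must be strictly positive")
        if self.noise_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def fus_scenario(cls, **overrides) -> "SimulationParams":
        """Granule-rich target channel: punctate FUS over a diffuse cytosol.

        These are the class defaults; the constructor alias exists so the two
        study scenarios read symmetrically in analysis scripts.
        """
        return cls(**overrides)

    @classmethod
    def ncdn_scenario(cls, **overrides) -> "SimulationParams":
        """Diffuse target channel: NCDN-like cytosolic signal, sparse puncta.

        The cytosolic median is the readout here, so the channel carries a
        low load of modest puncta (local enrichments a few-fold over the
        diffuse level, not the bright spots of the granule scenario) and a
        small camera offset.
        """
        overrides.setdefault("granule_density_per_um3", 0.02)
        overrides.setdefault("granule_amplitude_scale", 5.0)
        overrides.setdefault("nuclear_amplitude", 40.0)
        overrides.setdefault("background", 2.0)
        return cls(**overrides)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["condition_effects"] = {
            k: dataclasses.asdict(v) for k, v in self.condition_effects.items()
        }
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        d = yaml.safe_load(Path(path).read_text())
        effects = {
            k: ConditionEffect(**v) for k, v in d.pop("condition_effects", {}).items()
        }
        for key in (
            "image_shape",
            "voxel_size",
            "nucleus_radius_um",
            "nucleus_z_radius_um",
            "psf_sigma_um",
            "diffuse_blur_vox",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(condition_effects=effects or _default_effects(), **d)


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    nucleus_label_map: np.ndarray      #: 2D (y, x) integer map of nuclei
    soma_label_map: np.ndarray         #: 2D (y, x) integer map of cell bodies
    cytosol_mask: np.ndarray           #: 3D binary cytosol support
    granules: pd.DataFrame             #: z, y, x, sigma_um, amplitude, inside_nucleus
    condition: str
    batch: str
    noiseless: dict[str, np.ndarray]   #: per-channel render before noise


def _ellipsoid_mask(shape, center, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = 0.0
    for g, c, r in zip(grids, center, radii_vox):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _grow_neurite(rng, start_yx, shape_yx, length_vox, step_vox=4) -> list[tuple[int, int]]:
    """Random-walk centreline of one neurite in the (y, x) plane."""
    pts = [start_yx]
    angle = rng.uniform(0, 2 * np.pi)
    y, x = start_yx
    n_steps = max(1, int(length_vox / step_vox))
    for _ in range(n_steps):
        angle += rng.normal(0, 0.5)
        y = float(np.clip(y + step_vox * np.sin(angle), 0, shape_yx[0] - 1))
        x = float(np.clip(x + step_vox * np.cos(angle), 0, shape_yx[1] - 1))
        pts.append((y, x))
    return pts


def generate_neuron_stack(
    params: SimulationParams,
    condition: str = "CTL-KD",
    batch: str = "batch0",
    image_id: str = "image0",
    rng: np.random.Generator | None = None,
    batch_gain: float = 1.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render one two-channel stack (``dapi``, ``target``) with ground truth.

    The ground truth (granule table, masks, noiseless render) is recorded
    before the noise model is applied.
    """
    if condition not in params.condition_effects:
        raise ValueError(f"unknown condition label: {condition!r}")
    effect = params.condition_effects[condition]
    if rng is None:
        rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.image_shape
    vz, vy, vx = params.voxel_size
    voxel_vol = vz * vy * vx

    nucleus_3d = np.zeros(params.image_shape, dtype=np.int32)
    soma_3d = np.zeros(params.image_shape, dtype=bool)
    dapi = np.zeros(params.image_shape, dtype=np.float64)

    # rejection-sample nucleus centers so somata stay apart; small fields
    # cap the margin so placement stays feasible
    margin = params.soma_scale * max(params.nucleus_radius_um) / vy + 2
    margin = min(margin, (min(ny, nx) - 2) / 2.0)
    min_sep = 2.05 * params.soma_scale * max(params.nucleus_radius_um) / vy
    placed: list[tuple[float, float]] = []
    centers = []
    for i in range(params.n_nuclei):
        cy = cx = None
        for _ in range(200):
            ty = rng.uniform(margin, ny - margin)
            tx = rng.uniform(margin, nx - margin)
            if all(np.hypot(ty - py, tx - px) >= min_sep for py, px in placed):
                cy, cx = ty, tx
                break
        if cy is None:  # crowded field: accept the last draw
            cy, cx = ty, tx
        placed.append((cy, cx))
        cz = rng.uniform(0.4, 0.6) * (nz - 1)
        r_um = rng.uniform(*params.nucleus_radius_um)
        rz_um = rng.uniform(*params.nucleus_z_radius_um)
        radii = (rz_um / vz, r_um / vy, r_um / vx)
        nuc = _ellipsoid_mask(params.image_shape, (cz, cy, cx), radii)
        nucleus_3d[nuc] = i + 1
        soma_radii = (
            min(radii[0] * 1.4, nz / 2),
            radii[1] * params.soma_scale,
            radii[2] * params.soma_scale,
        )
        soma_3d |= _ellipsoid_mask(params.image_shape, (cz, cy, cx), soma_radii)
        # smooth DAPI profile: quadratic falloff inside the ellipsoid
        zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
        d2 = (
            ((zz - cz) / radii[0]) ** 2
            + ((yy - cy) / radii[1]) ** 2
            + ((xx - cx) / radii[2]) ** 2
        )
        dapi += params.dapi_amplitude * np.clip(1.0 - d2, 0.0, None)
        centers.append((cz, cy, cx, radii))

    # neurites: random-walk tubes from each soma rim, in the central z slab
    neurite_2d = np.zeros((ny, nx), dtype=bool)
    tube_r = max(1, int(round(params.neurite_radius_um / vy)))
    yy2, xx2 = np.mgrid[0:ny, 0:nx]
    for cz, cy, cx, radii in centers:
        for _ in range(params.n_neurites):
            pts = _grow_neurite(
                rng, (cy, cx), (ny, nx), params.neurite_length_um / vy
            )
            for py, px in pts:
                neurite_2d |= (yy2 - py) ** 2 + (xx2 - px) ** 2 <= tube_r**2
    z_lo, z_hi = max(0, nz // 2 - 1), min(nz, nz // 2 + 2)
    neurite_3d = np.zeros(params.image_shape, dtype=bool)
    neurite_3d[z_lo:z_hi] = neurite_2d

    cytosol = (soma_3d | neurite_3d) & (nucleus_3d == 0)

    # granules: Poisson count over cytosol volume, uniform positions in cytosol
    cyt_volume_um3 = float(cytosol.sum()) * voxel_vol
    n_granules = int(rng.poisson(params.granule_density_per_um3 * effect.density * cyt_volume_um3))
    cyt_idx = np.flatnonzero(cytosol.ravel())
    rows = []
    # diffuse compartments taper smoothly toward the cell boundary (only the
    # punctate granules carry high spatial frequencies) but emit no signal
    # outside their own support, so ground-truth masks stay exact
    diffuse = np.zeros(params.image_shape, dtype=np.float64)
    diffuse[cytosol] = params.cytosol_baseline * effect.cytosol
    diffuse[nucleus_3d > 0] = params.nuclear_amplitude
    diffuse = ndi.gaussian_filter(diffuse, sigma=params.diffuse_blur_vox)
    diffuse[~(cytosol | (nucleus_3d > 0))] = 0.0
    target = params.background + diffuse
    if n_granules > 0 and cyt_idx.size > 0:
        picks = rng.choice(cyt_idx, size=n_granules, replace=True)
        gz, gy, gx = np.unravel_index(picks, params.image_shape)
        jitter = rng.uniform(-0.5, 0.5, size=(n_granules, 3))
        sigmas_um = params.granule_sigma_median_um * effect.size * np.exp(
            rng.normal(0.0, params.granule_sigma_log_sd, size=n_granules)
        )
        amplitudes = effect.amplitude * rng.gamma(
            params.granule_amplitude_shape, params.granule_amplitude_scale, size=n_granules
        )
        psf_z, psf_xy = params.psf_sigma_um
        for i in range(n_granules):
            cz = gz[i] + jitter[i, 0]
            cy = gy[i] + jitter[i, 1]
            cx = gx[i] + jitter[i, 2]
            s_um = sigmas_um[i]
            # observed blob = granule convolved with the confocal PSF, which
            # is wider axially than laterally
            s_vox = (
                np.hypot(s_um, psf_z) / vz,
                np.hypot(s_um, psf_xy) / vy,
                np.hypot(s_um, psf_xy) / vx,
            )
            _render_blob(target, (cz, cy, cx), s_vox, amplitudes[i])
            rows.append(
                dict(
                    z=cz, y=cy, x=cx, sigma_um=s_um, amplitude=amplitudes[i],
                    inside_nucleus=False,
                )
            )
    granules = pd.DataFrame(
        rows, columns=["z", "y", "x", "sigma_um", "amplitude", "inside_nucleus"]
    )

    dapi += params.background
    dapi *= batch_gain
    target *= batch_gain
    noiseless = {"dapi": dapi.copy(), "target": target.copy()}

    channels = {name: _apply_noise(img, params, rng) for name, img in noiseless.items()}
    stack = ImageStack(channels, params.voxel_size, condition, batch, image_id)

    nucleus_2d, _ = _relabel_2d(nucleus_3d.max(axis=0) > 0)
    soma_2d, _ = _relabel_2d(soma_3d.any(axis=0))
    truth = GroundTruth(
        nucleus_label_map=nucleus_2d,
        soma_label_map=soma_2d,
        cytosol_mask=cytosol,
        granules=granules,
        condition=condition,
        batch=batch,
        noiseless=noiseless,
    )
    return stack, truth


def _relabel_2d(mask: np.ndarray):
    return ndi.label(mask, structure=np.ones((3, 3), dtype=bool))


def _render_blob(img: np.ndarray, center, sigma_vox, amplitude: float, n_sigma: float = 4.0):
    """Add an anisotropic 3D Gaussian blob in place (local window only)."""
    slices, grids = [], []
    for ax, (c, s) in enumerate(zip(center, sigma_vox)):
        lo = max(0, int(np.floor(c - n_sigma * s - 1)))
        hi = min(img.shape[ax], int(np.ceil(c + n_sigma * s + 2)))
        if lo >= hi:
            return
        slices.append(slice(lo, hi))
        grids.append((np.arange(lo, hi) - c) / s)
    zz = grids[0][:, None, None] ** 2 + grids[1][None, :, None] ** 2 + grids[2][None, None, :] ** 2
    img[tuple(slices)] += amplitude * np.exp(-0.5 * zz)


def _apply_noise(expected: np.ndarray, params: SimulationParams, rng: np.random.Generator):
    """Poisson shot noise (gain > 0) then additive Gaussian read noise."""
    img = expected
    if params.noise_gain > 0:
        img = rng.poisson(np.clip(expected * params.noise_gain, 0, None)).astype(np.float64)
        img /= params.noise_gain
    else:
        img = img.copy()
    if params.read_noise_sd > 0:
        img += rng.normal(0.0, params.read_noise_sd, size=img.shape)
    return img


@dataclasses.dataclass
class Dataset:
    """A simulated experiment: stacks, ground truth and manifest."""

    stacks: list[ImageStack]
    truths: list[GroundTruth]
    manifest: pd.DataFrame

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for stack, truth in zip(self.stacks, self.truths):
            write_stack(stack, directory)
            truth.granules.to_csv(
                directory / f"{stack.image_id}_granules.csv", index=False
            )
        write_manifest(self.manifest, directory / "manifest.csv")
        return directory


def generate_experiment(
    conditions: Sequence[str],
    n_images_per_condition: int,
    n_batches: int,
    base: SimulationParams,
) -> Dataset:
    """Simulate a full multi-week experiment.

    For every batch, every condition receives ``n_images_per_condition``
    stacks; each batch carries its own multiplicative gain jitter so the
    per-batch control normalization downstream is exercised for real.
    """
    if n_images_per_condition < 1:
        raise ValueError("n_images_per_condition must be >= 1")
    for cond in conditions:
        if cond not in base.condition_effects:
            raise ValueError(f"no condition effect entry for {cond!r}")
    root = np.random.SeedSequence(base.seed)
    batch_rng = np.random.default_rng(root.spawn(1)[0])
    gains = np.exp(batch_rng.normal(0.0, base.batch_gain_log_sd, size=n_batches))
    stacks, truths, rows = [], [], []
    child_seeds = root.spawn(n_batches * len(conditions) * n_images_per_condition)
    k = 0
    for b in range(n_batches):
        batch = f"batch{b}"
        for cond in conditions:
            for i in range(n_images_per_condition):
                image_id = f"{batch}_{cond}_{i:03d}"
                rng = np.random.default_rng(child_seeds[k])
                k += 1
                stack, truth = generate_neuron_stack(
                    base, cond, batch, image_id, rng=rng, batch_gain=float(gains[b])
                )
                stacks.append(stack)
                truths.append(truth)
                rows.append(dict(image_id=image_id, condition=cond, batch=batch))
    manifest = pd.DataFrame(rows)
    return Dataset(stacks, truths, manifest)
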