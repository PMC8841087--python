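# granulequant

Quantitative analysis of cytoplasmic protein granules in multi-channel
confocal z-stacks of cultured neurons — plus a seeded synthetic-stack
generator with full ground truth, so every stage of the pipeline can be
validated against known answers.

The package targets a common experimental design in neurodegeneration cell
biology: neurons are depleted of a protein of interest by shRNA knockdown
(here, the FTLD-associated proteins FUS and NCDN/neurochondrin), imaged by
confocal microscopy over several experimental weeks, and the localization
phenotype is quantified image by image:

* **Cytosolic signal** — how much of a diffuse protein sits in the cytosol:
  nucleus segmentation from DAPI, foreground extraction of the target
  channel, median cytosolic intensity per image, per-week normalization to
  controls, and a bootstrapped difference of medians between knockdown and
  control.
* **Granule phenotype** — what happens to punctate cytoplasmic granules:
  3D spot detection, per-cluster statistics, a skew-normal fit to each
  image's cluster-intensity histogram whose mode ("peak") is the per-image
  value, per-week control normalization, bootstrap inference, and per-cell
  morphometry (granule count, mean area, mean volume) compared by one-way
  ANOVA with Tukey's HSD.
* **Mosaic variant arithmetic** — for the genetics side of such studies:
  variant allele fraction VAF = alt/total reads with a Wilson score
  interval, and the carrier cell fraction 2·VAF under the heterozygous
  assumption.

## Methods at a glance

* Nucleus mask: triangle (Zack) threshold on the DAPI maximum-intensity
  projection; objects < 20 px removed; holes filled; one 3×3 dilation.
* Foreground: 3D Gaussian smoothing (σ = 0.5 voxel), per-slice triangle
  threshold, per-slice objects < 30 px removed. Cytosol = foreground minus
  the nucleus footprint broadcast over z.
* Spot detection: auto-contrast to [0, 1], Gaussian smoothing (σ = 1),
  scale-normalized negative Laplacian of Gaussian −s²∇²G_s (scale
  s ∈ [0.75, 1]), binarized at a cutoff ∈ [0.015, 0.045], 26-connected
  labeling. Clusters with area outside [5, 300] voxels or maximum raw
  intensity above 30,000 counts are discarded.
* Statistics: per-image peak = argmax of the maximum-likelihood
  skew-normal density SN(ξ, ω, α); batch normalizer = peak of the pooled
  control clusters of that week; outliers beyond 2 sample SDs of the
  condition mean removed in one pass; bootstrap with B = 10,000 resamples,
  95% percentile CI, two-sided p floored at 1/B.
* Synthetic stacks: ellipsoidal nuclei, soma + random-walk-neurite
  cytosol, granules as 3D Gaussian blobs (log-normal size, gamma
  amplitude, PSF-widened axially), Poisson shot noise + Gaussian read
  noise, per-condition effect multipliers and per-batch gain jitter.

## Worked example

```python
from granulequant import (ConditionEffect, SimulationParams,
                          generate_experiment, rois_from_label_map,
                          run_fus_analysis)

effects = {"CTL-KD": ConditionEffect(),
           "NCDN-KD1": ConditionEffect(density=0.5, size=1.5, amplitude=1.3)}
base = SimulationParams(seed=11, condition_effects=effects)
ds = generate_experiment(["CTL-KD", "NCDN-KD1"], 6, 2, base)
rois = {s.image_id: rois_from_label_map(t.soma_label_map, s.image_id)
        for s, t in zip(ds.stacks, ds.truths)}
report = run_fus_analysis(ds.stacks, seed=5, rois=rois)
print(report.summary())
```

prints (see `examples/05_end_to_end_knockdown.py` for the full script):

```
        comparison statistic  observed_diff   ci_low  ci_high      p     B
NCDN-KD1 vs CTL-KD    median       0.261164 0.218172 0.313916 0.0001 10000
```

The knockdown was simulated with granule amplitude ×1.3, and the analysis
reads back a +0.26 difference of normalized intensity peaks whose 95% CI
excludes zero — together with roughly halved per-cell granule counts and
~1.4× mean granule volume in the morphometry table, the same qualitative
pattern the method is designed to detect. The mosaic example:

```
variant allele fraction: 24.5% (Wilson 95% CI 14.6-38.1%)
carrier cell fraction (2 x VAF, heterozygous): 49.0%
```

## Command line

```bash
granule-quant simulate    --out data/ --seed 1 --conditions CTL-KD,NCDN-KD1 --n-images 6 --n-batches 2
granule-quant analyze-fus  --data data/ --out results/ --seed 1
granule-quant analyze-ncdn --data data/ --out results/ --seed 1
granule-quant segment      --data data/ --image-id batch0_CTL-KD_000 --out nuclei.tif
granule-quant spots        --data data/ --image-id batch0_CTL-KD_000 --out clusters.csv
```

`simulate` writes per-channel TIFFs, ground-truth CSVs, a manifest and the
resolved parameters; the analysis commands consume any directory with that
layout (real acquisitions included, given a `manifest.csv` with
`image_id, condition, batch`).

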