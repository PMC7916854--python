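"""Derive a binary FCN training target from the green fluorescence channel.

The pipeline is: min-max normalize, Gaussian smooth, threshold at 0.3,
binary dilate, max-pool downsample to the FCN output grid.  The same
mask is the target for every class present on the sample.
"""

import numpy as np

from protloc.classes import CLASS_CODES
from protloc.fcn_targets import build_training_targets, make_target_mask
from protloc.simdata import SimConfig, generate_samples

sample = generate_samples(1, SimConfig(image_side=64), seed=4)[0]
green = sample.image[0]
present = [CLASS_CODES[i] for i in np.flatnonzero(sample.labels)]
print("sample", sample.sample_id, "classes:", present)

tm = make_target_mask(green, out_side=4)
print("green channel 64x64 -> target mask 4x4:")
print(tm.mask)
print(f"positive fraction: {tm.mask.mean():.2f}")

stack = build_training_targets(green, sample.labels, fcn_out_side=4)
nonzero = [CLASS_CODES[c] for c in range(13) if stack[c].any()]
print("nonzero target channels:", nonzero, "(equal to the present classes,")
print("all sharing the same mask; the other channels are all-zero targets)")
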