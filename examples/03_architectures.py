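"""Build the CNN and FCN variants and compare their structure.

Both share a 10-conv-layer trunk (two convs + batchnorm + maxpool per
block, widths doubling).  The CNN adds three fully connected layers; the
FCN drops the last pooling stage and adds a 13-kernel conv, so it emits
one heatmap per class and has fewer parameters.
"""

import numpy as np

from protloc.nets import (
    NetworkSpec,
    build_cnn,
    build_fcn,
    count_conv_layers,
    count_parameters,
    predict,
)

spec = dict(input_side=256, base_kernels=16)
cnn = build_cnn(NetworkSpec(**spec))
fcn = build_fcn(NetworkSpec(**spec, variant="FCN"))

print("trunk conv layers:", count_conv_layers(cnn), "(CNN),", count_conv_layers(fcn), "(FCN)")
print("parameters:", count_parameters(cnn), "(CNN) vs", count_parameters(fcn), "(FCN)")

rng = np.random.default_rng(0)
image = rng.random((4, 256, 256))
rec_cnn = predict(cnn, image, "demo")
rec_fcn = predict(fcn, image, "demo")
print("CNN output: 13 confidences, e.g.", np.round(rec_cnn.confidences[:4], 3))
print("FCN output: heatmaps", rec_fcn.heatmaps.shape, "-> confidences are the per-class maxima")
assert np.allclose(rec_fcn.confidences, rec_fcn.heatmaps.max(axis=(1, 2)))
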