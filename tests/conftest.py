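import numpy as np
import pytest

from protloc.nets import NetworkSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_spec():
    """A 64-px architecture spec suitable for CPU tests."""
    return NetworkSpec(input_side=64, base_kernels=8, fc_widths=(128, 64, 13), seed=0)
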