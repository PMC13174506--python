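import numpy as np
import pytest

import axonflow as af


@pytest.fixture
def channel_910():
    """53 collinear electrodes at 17.5 um pitch spanning 910 um."""
    layout, spec = af.build_channel_layout(910.0, 17.5, "directional")
    return layout, spec


@pytest.fixture
def straight_910():
    layout, spec = af.build_channel_layout(910.0, 17.5, "straight")
    return layout, spec


@pytest.fixture
def default_cfg():
    return af.validate_config(None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
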