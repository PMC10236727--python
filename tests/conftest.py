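import numpy as np
import pytest

from erpcode.synthdata import (make_design, ERPTemplate, NoiseModel,
                               generate_dataset, scalp_gains)


@pytest.fixture
def oddball():
    """The canonical 135-trial session geometry at 8 channels."""
    return make_design(135, 0.30, 250.0, 100.0, 500.0, 8,
                       n_target=40, n_standard=95)


@pytest.fixture
def small_dataset():
    """A small, quick synthetic session: 20 trials, 2 channels."""
    design = make_design(20, 0.3, 250.0, 100.0, 500.0, 2, n_target=6)
    return generate_dataset(
        design,
        target_template=ERPTemplate("P300", 300.0, 10.0, 80.0,
                                    channel_gains=scalp_gains(2)),
        standard_template=ERPTemplate("P300", 300.0, 2.0, 80.0,
                                      channel_gains=scalp_gains(2)),
        noise=NoiseModel(sd_uV=5.0, spectral_shape="band"),
        seed=99)
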