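import numpy as np
import pytest

import brightmux as bm


@pytest.fixture(scope="session")
def table1():
    return bm.table1_tungsten()


@pytest.fixture(scope="session")
def table2():
    return bm.table2_led()


@pytest.fixture(scope="session")
def exact_detector():
    """Noise-free, unquantized, flat-field detector for identity checks."""
    return bm.DetectorModel(noise="none", quantize=False, illumination="flat")


@pytest.fixture(scope="session")
def noisy_detector():
    """Default 8-bit acquisition with shot noise and quantization."""
    return bm.DetectorModel(noise="poisson", quantize=True)


@pytest.fixture(scope="session")
def mono_channel():
    return bm.ChannelSet((bm.LightChannel("549", 549.0, 20.0),))


def absorbance_of(scene, detector):
    """Phantom acquisition pushed through the radiometry chain."""
    tissue, blank = bm.forward_model(scene, detector)
    return bm.to_absorbance(bm.to_transmission(tissue, blank))
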