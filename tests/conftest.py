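import numpy as np
import pytest

from emccd_pia import ChipParams, NoiseModel

# Gain-100 calibration of the reference EMCCD chip used throughout.
GAIN100 = dict(g=18.82, f=35.17, r=1.45, delta=26.37)


@pytest.fixture(scope="session")
def chip() -> ChipParams:
    return ChipParams(**GAIN100)


@pytest.fixture(scope="session")
def chip_nogain(chip) -> ChipParams:
    return chip.with_gain(False)


@pytest.fixture(scope="session")
def model22(chip) -> NoiseModel:
    """Background model at the reference rate of 22 photoelectrons."""
    return NoiseModel(chip=chip, lam=22.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
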