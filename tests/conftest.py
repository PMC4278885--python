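import pytest

from mfassay.bond_kinetics import BellBond, SerialProbe, default_ramp
from mfassay.synthetic_images import GroundTruth, NoiseModel, OpticalModel


@pytest.fixture(scope="session")
def ramp():
    return default_ramp()


@pytest.fixture
def identical_probe():
    bond = BellBond(k0=1e-4, dx=1.0, label="bond")
    return SerialProbe(protein_bond=bond, reference_bond=bond)


@pytest.fixture
def default_optical():
    return OpticalModel()


@pytest.fixture
def default_noise():
    return NoiseModel()


@pytest.fixture
def quiet_noise():
    """No background, no shot noise, no read noise."""
    return NoiseModel(background_offset=0.0, read_noise_sd=0.0, shot_noise=False)


@pytest.fixture
def truth_half():
    return GroundTruth(q_ref_break=0.5, coupling_efficiency=0.8)
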