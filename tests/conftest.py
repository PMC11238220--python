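import pytest

from loxsense.enzymes import REFERENCE_ENZYMES
from loxsense.synthetic import KineticGroundTruth, SensorGroundTruth


@pytest.fixture
def avlox():
    return REFERENCE_ENZYMES["AvLOx"]


@pytest.fixture
def avlox_truth(avlox):
    """Noiseless Michaelis–Menten ground truth at the AvLOx constants."""
    return KineticGroundTruth(Km=avlox.km_mM, kcat=avlox.kcat_s,
                              noise_cv=0.0, seed=7, enzyme="AvLOx")


@pytest.fixture
def avlox_mixed_truth(avlox):
    """Noiseless mixed-inhibition ground truth at the AvLOx constants."""
    return KineticGroundTruth(Km=avlox.km_mM, kcat=avlox.kcat_s,
                              inhibition_model="mixed", Ki=avlox.ki_mM,
                              alpha=1.5, noise_cv=0.0, seed=7, enzyme="AvLOx")


@pytest.fixture
def clean_sensor_truth():
    """Noiseless sensor with the film resistance disabled: the KL intercept
    is purely enzyme-limited."""
    return SensorGroundTruth(noise_cv=0.0, film_permeability_lac=None,
                             film_permeability_h2o2=None, seed=3)
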