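import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import swathlite as sw

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design():
    return sw.StudyDesign(seed=11)


@pytest.fixture(scope="session")
def scheme():
    return sw.AcquisitionScheme.default_swath()


@pytest.fixture(scope="session")
def small_proteome():
    return sw.generate_proteome(40, 5, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_proteome):
    return sw.generate_ground_truth(small_proteome, de_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def noiseless_study(design, small_truth, scheme):
    """40-protein study with every noise term zero: extraction results are
    exactly reconstructible from ground truth."""
    return sw.simulate_study(design, small_truth, sw.NoiseModel.noiseless(),
                             scheme, seed=11)


@pytest.fixture(scope="session")
def noiseless_quant(noiseless_study, scheme):
    from swathlite import diaquant

    lib = sw.SpectralLibrary(entries=noiseless_study.library)
    tq = diaquant.quantify_study(lib, noiseless_study.runs, scheme)
    return lib, tq
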