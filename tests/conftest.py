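import numpy as np
import pytest
from hypothesis import settings

from trichoterp.genetics import GeneticModel, SegregationObservation, default_candidate_models

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def f2_observation():
    """The observed F2 segregation: 12 high, 380 low plants."""
    return SegregationObservation(n_high=12, n_low=380)


@pytest.fixture(scope="session")
def candidate_models():
    return default_candidate_models()


@pytest.fixture(scope="session")
def four_locus_model():
    """Two recessive + two dominant loci: the best-fitting gene model."""
    return GeneticModel.from_spec("a-b-C-D")


@pytest.fixture
def rng():
    return np.random.default_rng(20230303)
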