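import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


UNEQUAL_STAR = "(REF:0.8,S1:0.9,S2:0.85,S3:0.75,S4:0.2)root;"


@pytest.fixture
def unequal_star_newick():
    """The five-leaf unequal star used throughout the benchmark: four
    close orthologs (0.80 reference, 0.90, 0.85, 0.75) plus one distant
    ortholog (0.20)."""
    return UNEQUAL_STAR
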