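import numpy as np
import pytest

from simpull import PopulationSpec, simulate_counts


@pytest.fixture
def monomer_dimer_sample():
    """2,000 counts from a 60/40 monomer/dimer population at mNG activity."""
    spec = PopulationSpec(components=((1, 0.6), (2, 0.4)), activity=0.74)
    return simulate_counts(spec, 2000, seed=12345)


@pytest.fixture
def dimer_spec():
    return PopulationSpec(components=((2, 1.0),), activity=0.74)
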