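import numpy as np
import pytest

from soilcue import GeneratorConfig, generate
from soilcue.isotope import compute_cue_table


@pytest.fixture(scope="session")
def default_data():
    """One default synthetic chronosequence (5 stages x 3 plots)."""
    return generate(GeneratorConfig(), seed=20260927)


@pytest.fixture(scope="session")
def default_cue(default_data):
    """Recovered CUE values for the default synthetic dataset."""
    results = compute_cue_table(default_data.samples)
    return np.array([r.cue for r in results])
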