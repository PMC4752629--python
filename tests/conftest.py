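import numpy as np
import pytest

from lungscreen.cohort import SynthConfig, generate_population, sow_nodules


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-subject screened cohort with nodules, fixed seed."""
    cfg = SynthConfig(n_individuals=2000, seed=7)
    return sow_nodules(generate_population(cfg), cfg), cfg
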