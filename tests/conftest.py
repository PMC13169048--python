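import numpy as np
import pandas as pd
import pytest

from dialdep import generate, preset_paperlike


@pytest.fixture(scope="session")
def paperlike_cohort():
    """One fixed-seed study-conditions cohort (n=300) shared across tests."""
    config = preset_paperlike(n=300, seed=11)
    data, truth = generate(config)
    return config, data, truth


@pytest.fixture(scope="session")
def large_cohort():
    """A large fixed-seed cohort for parameter-recovery checks."""
    config = preset_paperlike(n=50_000, seed=42)
    data, truth = generate(config)
    return config, data, truth
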