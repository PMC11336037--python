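import numpy as np
import pandas as pd
import pytest

from braintrends.regions import load_region_registry
from braintrends.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return load_region_registry()


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort: enough subjects per cell for stable regressions,
    small enough to keep unit tests fast."""
    return SynthConfig(
        seed=42,
        n_per_group={
            ("study_A", "M"): 160,
            ("study_A", "F"): 160,
            ("reference", "M"): 400,
            ("reference", "F"): 400,
        },
    )


@pytest.fixture(scope="session")
def small_cohort(small_config, registry):
    return generate_cohort(small_config, registry)


@pytest.fixture()
def linear_vprime():
    """Noise-free ICV-normalized volumes exactly linear in age:
    v' = 2 + 0.01 * age for one region."""
    ages = pd.Series(np.linspace(46.0, 83.0, 20), name="age")
    vp = pd.DataFrame({"region_x": 2.0 + 0.01 * ages})
    return vp, ages
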