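import numpy as np
import pandas as pd
import pytest

from widlo import (
    CohortConfig,
    deconvolve_cell_fractions,
    generate_cohort,
    generate_reference_profiles,
)


@pytest.fixture(scope="session")
def small_refs():
    return generate_reference_profiles(300, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_refs):
    cfg = CohortConfig(
        n_samples=80, n_probes=300, planted_epithelial_dmcs=(20, 0.15), seed=11
    )
    return generate_cohort(cfg, small_refs)


@pytest.fixture(scope="session")
def small_fractions(small_cohort, small_refs):
    return deconvolve_cell_fractions(small_cohort.beta, small_refs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def abundance_table():
    return pd.DataFrame(
        {
            "Lactobacillus crispatus": [0.6, 0.2, 0.5],
            "Lactobacillus gasseri": [0.0, 0.2, 0.0],
            "Lactobacillus iners": [0.0, 0.0, 0.0],
            "Lactobacillus jensenii": [0.0, 0.0, 0.0],
            "Gardnerella vaginalis": [0.4, 0.6, 0.5],
        },
        index=["s1", "s2", "s3"],
    )
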