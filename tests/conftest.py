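import numpy as np
import pytest

from cageprom import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    """A rendered mini-cohort shared by IO / calling tests."""
    cfg = sd.CohortConfig(
        n_samples=12,
        n_promoters=20,
        seed=7,
        library_size_median=2e5,
        contig_size=10,
    )
    samples, truths = sd.generate_cohort(cfg)
    dataset = sd.render_landscape(truths, samples, cfg)
    return dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
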