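import numpy as np
import pytest

from vmlong.core_data import CountTable, SampleMetadata
from vmlong.synthetic import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (12 term / 3 preterm subjects) for fast model tests."""
    cfg = SyntheticConfig(seed=42, n_term=12, n_preterm=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale cohort at the generator's default design."""
    cfg = SyntheticConfig(seed=1)
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_table():
    return CountTable(
        samples=("s1", "s2", "s3"),
        taxa=("taxA", "taxB"),
        counts=np.array([[5, 0], [0, 7], [1, 1]]),
    )


@pytest.fixture()
def tiny_meta():
    return [
        SampleMetadata("s1", "subj1", "term", 10.0, 5),
        SampleMetadata("s2", "subj1", "term", 14.0, 7),
        SampleMetadata("s3", "subj2", "preterm", 12.0, 2),
    ]
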