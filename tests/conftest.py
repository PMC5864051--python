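import pytest

from trisex import synthio


@pytest.fixture(scope="session")
def dataset():
    """Small default-size dataset shared by read-only tests."""
    return synthio.generate_dataset(synthio.SimConfig(seed=1))


@pytest.fixture(scope="session")
def named_loci():
    return synthio.build_named_loci()


@pytest.fixture(scope="session")
def cohort_noise_free():
    return synthio.generate_flower_cohort(n_per_class=10, seed=3)
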