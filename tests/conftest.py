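import numpy as np
import pytest

from bindnode.fixtures import FixtureSpec, generate_fixture_set, to_samples


@pytest.fixture(scope="session")
def fixture_set():
    """Six small synthetic proteins shared across the suite."""
    return generate_fixture_set(FixtureSpec(n_proteins=6, length_range=(40, 60), seed=11))


@pytest.fixture(scope="session")
def samples(fixture_set):
    return to_samples(fixture_set, threshold=17.0, use_dssp=True)


@pytest.fixture(scope="session")
def sample(samples):
    return next(iter(samples.values()))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
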