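import numpy as np
import pytest

from fegs import bundled_fixture_properties, generate_random_proteins


@pytest.fixture(scope="session")
def fixture_properties():
    """The bundled 5-index synthetic property set."""
    return bundled_fixture_properties()


@pytest.fixture(scope="session")
def random_sequences():
    """Twelve reproducible random protein sequences of moderate length."""
    return generate_random_proteins(12, length_range=(30, 60), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
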