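import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import mitochar as m

GENOME_SEED = 20240917  # fixed; < 2**31


@pytest.fixture(scope="session")
def desmaulus():
    """Transcribed organization table of the study organism (no sequence)."""
    return m.datasets.desmaulus_annotation()


@pytest.fixture(scope="session")
def ancestral():
    return m.datasets.ancestral_gastropod_order()


@pytest.fixture(scope="session")
def code5():
    return m.GeneticCode.from_table(5)


@pytest.fixture(scope="session")
def synthetic():
    """One seeded synthetic genome shared across the suite."""
    return m.generate_mitogenome(seed=GENOME_SEED)
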