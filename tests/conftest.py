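import pytest

from mitomarker.simulate import FIXTURE_SEED, fixture_genomes, study_panel


@pytest.fixture(scope="session")
def fixture_panel():
    """The deterministic 4-species, 3-gene toy panel."""
    return fixture_genomes()


@pytest.fixture(scope="session")
def study():
    """The 16-species sparid-like study panel (shared; treat as read-only)."""
    return study_panel(seed=FIXTURE_SEED)
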