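import pytest

from grimkit.fixtures import FixtureConfig, build_fixture_set


@pytest.fixture(scope="session")
def fixture_set():
    """Default synthetic fixture set (seeded, deterministic)."""
    return build_fixture_set()

@pytest.fixture(scope="session")
def banded_set():
    """Fixture set with EcoRI band geometry solved for screening digests."""
    return build_fixture_set(FixtureConfig(banded=True))


@pytest.fixture(scope="session")
def example_candidate(fixture_set):
    """The packaged example shuttle design (site at query position 70)."""
    return fixture_set.candidate
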