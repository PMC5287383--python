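import pytest
from hypothesis import settings

from nglyco.fixtures import FixtureTable, load_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cortex() -> FixtureTable:
    return load_fixture("cortex")


@pytest.fixture(scope="session")
def serum() -> FixtureTable:
    return load_fixture("serum")


@pytest.fixture(scope="session")
def all_fixture_rows(cortex, serum):
    """(tissue, row) pairs for all 99 transcribed table rows."""
    out = []
    for fixture in (cortex, serum):
        for _, row in fixture.table.iterrows():
            out.append((fixture.tissue, row))
    return out
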