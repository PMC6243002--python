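import pytest

from soilgv import synth
from soilgv.markers import DEFAULT_MARKERS


@pytest.fixture(scope="session")
def markers():
    return DEFAULT_MARKERS


@pytest.fixture(scope="session")
def truth():
    """One default synthetic community shared by read-only tests."""
    return synth.generate_community(seed=42)


@pytest.fixture()
def small_truth():
    """A small community regenerated per test (safe to mutate)."""
    return synth.generate_community(n_cellular=10, n_ncldv=6, lineage_count=3,
                                    n_references=8, seed=7)
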