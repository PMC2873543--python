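import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rnafrag import fixtures as fx
from rnafrag.search import entry_from_structure


@pytest.fixture(scope="session")
def default_library():
    """The standard synthetic library, materialized in memory once."""
    return fx.build_library(fx.default_library_spec(seed=1))


@pytest.fixture(scope="session")
def library_entries(default_library):
    """Annotated, searchable entries for the whole default library."""
    return [entry_from_structure(st.copy()) for st in default_library]


@pytest.fixture(scope="session")
def entries_by_id(library_entries):
    return {e.entry_id: e for e in library_entries}


@pytest.fixture(scope="session")
def hairpin_entry():
    return entry_from_structure(fx.build_hairpin("GCG", "GAAA", "HP1"))
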