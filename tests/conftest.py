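import pytest

from mepnkit.fixtures import build_ifng_mhc2_pathway, random_pathway
from mepnkit.registry import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def ifng_graph():
    return build_ifng_mhc2_pathway()


@pytest.fixture(scope="session")
def random_graphs():
    """A small deterministic batch of conformant random pathways."""
    return [random_pathway(seed, 8 + seed % 5, 3 + seed % 4) for seed in range(12)]
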