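import pytest

from ddiwalk import (
    BundleConfig,
    PPINetwork,
    generate_bundle,
    propagate_all_drugs,
    row_normalize,
)


@pytest.fixture
def edge_net():
    """Single undirected edge A-B."""
    return PPINetwork([("A", "B")])


@pytest.fixture
def path_net():
    """Path graph A-B-C."""
    return PPINetwork([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle_net():
    return PPINetwork([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-size cross-talk benchmark shared across tests."""
    return generate_bundle(
        BundleConfig(n_nodes=200, n_drugs=20, n_positive=20, n_pathways=4, seed=11)
    )


@pytest.fixture(scope="session")
def small_profiles(small_bundle):
    transition = row_normalize(small_bundle.network)
    return propagate_all_drugs(small_bundle.targets, transition)
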