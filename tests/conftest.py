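import networkx as nx
import pytest

from netpharm import (
    DEGRecord,
    DEGTable,
    Network,
    RWRConfig,
    ScenarioConfig,
    build_scenario,
)


@pytest.fixture
def two_node_network() -> Network:
    return Network(nx.Graph([("A", "B")]))


@pytest.fixture
def path3_network() -> Network:
    g = nx.relabel_nodes(nx.path_graph(3), {0: "1", 1: "2", 2: "3"})
    return Network(g)


@pytest.fixture
def star_network() -> Network:
    g = nx.relabel_nodes(nx.star_graph(3), {0: "hub", 1: "a", 2: "b", 3: "c"})
    return Network(g)


@pytest.fixture
def cycle_network() -> Network:
    g = nx.relabel_nodes(nx.cycle_graph(7), {i: f"n{i}" for i in range(7)})
    return Network(g)


@pytest.fixture
def hand_table() -> DEGTable:
    """Five genes with hand-checkable filtering and ranking behaviour."""
    rows = [
        ("g1", 1.0, 0.01),
        ("g2", -0.6, 0.04),
        ("g3", 0.3, 0.001),
        ("g4", 2.0, 0.2),
        ("g5", -0.59, 0.03),
    ]
    return DEGTable([DEGRecord(g, l, p) for g, l, p in rows], "hand")


@pytest.fixture(scope="session")
def small_scenario():
    """A modest planted scenario shared by pipeline-level tests."""
    return build_scenario(
        ScenarioConfig(
            n_nodes=300, attachment_m=3, n_disease=30, n_drug=30,
            overlap_fraction=0.5, rng_seed=123,
        )
    )


@pytest.fixture
def fast_rwr() -> RWRConfig:
    return RWRConfig(restart_prob=0.7, tol=1e-10, max_iter=10000)
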