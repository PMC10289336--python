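import networkx as nx
import pytest

from phonobackbone import fixture_community, build_network
from phonobackbone.simulate import SyntheticLexiconConfig, generate_lexicon


@pytest.fixture(scope="session")
def toy_lexicon():
    """Five mutually-neighboring /-Et/ words plus three hermits."""
    return fixture_community()


@pytest.fixture(scope="session")
def toy_network(toy_lexicon):
    return build_network(toy_lexicon)


@pytest.fixture
def path4():
    """Path a-b-c-d: the worked backbone/grouping example."""
    G = nx.Graph()
    nx.add_path(G, ["a", "b", "c", "d"])
    return G


@pytest.fixture
def star5():
    """Star: center c with 4 leaves."""
    G = nx.Graph()
    G.add_edges_from(("c", f"l{i}") for i in range(4))
    return G


@pytest.fixture
def two_triangles():
    G = nx.Graph()
    G.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
    return G


def small_synthetic_lexicon(n=200, seed=0, inventory=10):
    return generate_lexicon(
        SyntheticLexiconConfig(n_words=n, inventory_size=inventory, seed=seed)
    )


@pytest.fixture
def synth200():
    return small_synthetic_lexicon()
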