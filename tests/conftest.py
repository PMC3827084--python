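import networkx as nx
import pytest

from netseed.network import PPINetwork
from netseed.synthetic import PlantedNetworkSpec, generate_planted_network


@pytest.fixture(scope="session")
def planted():
    """A 3x30 planted-partition network with recoverable modules."""
    spec = PlantedNetworkSpec(module_sizes=(30, 30, 30), p_in=0.3, p_out=0.01,
                              rng_seed=11)
    net, partition = generate_planted_network(spec)
    return net, partition


def chain_network(n: int, extra_edges=()) -> PPINetwork:
    """A connected path graph N1-N2-...-Nn plus any extra edges."""
    g = nx.path_graph([f"N{i:03d}" for i in range(1, n + 1)])
    g.add_edges_from(extra_edges)
    return PPINetwork(graph=g, provenance="chain fixture")
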