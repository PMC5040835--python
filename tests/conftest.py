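import numpy as np
import pytest

from rmlm.hetnet import HeteroNetwork, NodeCatalog, RelationMatrix, register_relation
from rmlm.synthetic import generate_network, plant_links, toy_fixture


def build_network(sim: np.ndarray, mg: np.ndarray, ppi: np.ndarray) -> HeteroNetwork:
    """Assemble a two-type network from the three relation matrices."""
    net = HeteroNetwork()
    net.add_catalog(NodeCatalog("mirna", tuple(f"m{i}" for i in range(sim.shape[0]))))
    net.add_catalog(NodeCatalog("gene", tuple(f"g{j}" for j in range(ppi.shape[0]))))
    register_relation(net, RelationMatrix("sim", "mirna", "mirna", sim))
    register_relation(net, RelationMatrix("regulate", "mirna", "gene", mg))
    register_relation(net, RelationMatrix("ppi", "gene", "gene", ppi))
    return net


@pytest.fixture(scope="session")
def toy_study():
    return toy_fixture()


@pytest.fixture(scope="session")
def planted_study():
    """One mid-size planted study shared by the slower tests."""
    net, dag, profiles = generate_network(seed=1)
    return plant_links(net, dag, profiles, seed=1)


@pytest.fixture(scope="session")
def planted_study_seq():
    net, dag, profiles = generate_network(seed=1)
    return plant_links(net, dag, profiles, seed=1, with_sequence=True)
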