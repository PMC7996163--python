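import networkx as nx
import numpy as np
import pytest

from mitotox.nanotube import MolecularGraph, NanotubeSpec, build_nanotube_graph
from mitotox.synthetic import SyntheticConfig, helix_coords


def path_graph(k: int) -> MolecularGraph:
    return MolecularGraph.from_edges([(i, i + 1) for i in range(k - 1)])


def cycle_graph(k: int) -> MolecularGraph:
    return MolecularGraph.from_edges([(i, (i + 1) % k) for i in range(k)])


def star_graph(leaves: int) -> MolecularGraph:
    return MolecularGraph.from_edges([(0, i) for i in range(1, leaves + 1)])


def relabelled(g: MolecularGraph, seed: int) -> MolecularGraph:
    """The same molecule under a random permutation of atom ids."""
    rng = np.random.default_rng(seed)
    nodes = sorted(g.graph.nodes)
    mapping = dict(zip(nodes, rng.permutation(nodes).tolist()))
    return MolecularGraph(nx.relabel_nodes(g.graph, mapping), dict(g.meta))


@pytest.fixture(scope="session")
def small_tube() -> MolecularGraph:
    return build_nanotube_graph(NanotubeSpec(4, 0, 1))


@pytest.fixture(scope="session")
def small_tube_cooh() -> MolecularGraph:
    return build_nanotube_graph(NanotubeSpec.carboxylated(4, 0, 1))


@pytest.fixture(scope="session")
def helix20() -> np.ndarray:
    return helix_coords(SyntheticConfig(seed=3, n_residues=20))


@pytest.fixture
def helix_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=3, n_residues=20)
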