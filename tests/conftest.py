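import networkx as nx
import numpy as np
import pytest

from polnet import AnalysisConfig, ExpressionMatrix, PairedExpressionDataset
from polnet.network import NORMAL, TUMOUR, CrossTissueNetwork


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def tiny_dataset():
    """5-gene, 6-pair dataset with one strong cross-tissue relationship."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(5)]
    samples = [f"p{j}" for j in range(6)]
    normal = rng.standard_normal((5, 6))
    tumour = rng.standard_normal((5, 6))
    tumour[1] = normal[0] + 0.01 * rng.standard_normal(6)  # g0-normal drives g1-tumour
    return PairedExpressionDataset(
        ExpressionMatrix(genes, samples, normal),
        ExpressionMatrix(genes, samples, tumour),
        samples,
    )


def make_network(edges):
    """Build a CrossTissueNetwork from (normal_gene, tumour_gene) pairs."""
    graph = nx.Graph()
    for ng, tg in edges:
        u, v = (ng, NORMAL), (tg, TUMOUR)
        graph.add_node(u, tissue=NORMAL)
        graph.add_node(v, tissue=TUMOUR)
        graph.add_edge(u, v, r_s=0.9, q=0.001)
    return CrossTissueNetwork(graph)


@pytest.fixture
def toy_network():
    """5-edge toy network: gA-normal is a hub with 3 tumour neighbours."""
    return make_network(
        [("gA", "gX"), ("gA", "gY"), ("gA", "gZ"), ("gB", "gX"), ("gC", "gY")]
    )
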