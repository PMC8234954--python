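import networkx as nx
import numpy as np
import pandas as pd
import pytest

from radgrn import simulate
from radgrn.io import ExpressionMatrix, GeneCatalog


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 5 samples with a planted perfect pair."""
    rng = np.random.default_rng(42)
    base = rng.standard_normal(5)
    df = pd.DataFrame(
        {
            "S1": [base[0], base[0], 1.0],
            "S2": [base[1], base[1], -0.5],
            "S3": [base[2], base[2], 2.0],
            "S4": [base[3], base[3], 0.3],
            "S5": [base[4], base[4], -1.1],
        },
        index=["AT1G00010", "AT1G00020", "AT1G00030"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def star_network() -> nx.Graph:
    """Star with hub AT1G00001 and 12 leaves, AGI node names."""
    genes = simulate.make_gene_ids(13)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for leaf in genes[1:]:
        g.add_edge(genes[0], leaf, weight=0.9)
    return g


@pytest.fixture
def catalog() -> GeneCatalog:
    return GeneCatalog(radiation_induced={"AT1G00001", "AT3G00003"})


def random_graph(n: int, p: float, seed: int, directed: bool = False) -> nx.Graph:
    rng = np.random.default_rng(seed)
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i == j or (not directed and j <= i):
                continue
            if rng.random() < p:
                g.add_edge(i, j)
    return g
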