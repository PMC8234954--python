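"""Topological and algebraic spectral network measures.

Per-gene measures: total/in/out degree, subgraph centrality (the diagonal
of the adjacency matrix exponential), closeness, PageRank, and eigenvector
centrality.  Whole-graph measures: adjacency and normalized (random-walk)
spectral gaps, girth via traces of adjacency powers, diameter and average
shortest path, density, connected components, and the Jaccard neighborhood
similarity between two genes within or across networks.

Conventions
-----------
* Subgraph centrality and the normalized spectral gap run on the BINARIZED
  undirected adjacency: the closed-form star values (cosh(sqrt(n)) at the
  hub) only hold unweighted.  The adjacency spectral gap supports both
  weighted (default) and binarized mode.
* Girth uses the smallest ``r`` with ``trace(A^r) > 0``; on an undirected
  graph any edge makes this 2, so it is only informative on a directed
  view.
* Diameter of a disconnected graph is the maximum eccentricity over its
  components; the average shortest path is the mean over reachable ordered
  pairs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    spectral_gap_adjacency: float
    spectral_gap_normalized: float | None
    girth: float  # int or math.inf
    diameter: float  # int or math.inf for edgeless graphs
    density: float
    n_components: int
    avg_shortest_path: float
    eigenvalues: list[float]

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        for key in ("girth", "diameter", "avg_shortest_path"):
            if isinstance(out[key], float) and math.isinf(out[key]):
                out[key] = None
        return out


@dataclass
class JaccardPair:
    gene_u: str
    gene_v: str
    index: float
    label_a: str = ""
    label_b: str = ""


def _undirected(network: nx.Graph) -> nx.Graph:
    return network.to_undirected() if network.is_directed() else network


def _binary_adjacency(network: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = list(network.nodes)
    A = nx.to_numpy_array(network, nodelist=nodes, weight=None)
    np.fill_diagonal(A, 0.0)
    return nodes, A


# ---------------------------------------------------------------------------
# degree


def degree_distribution(network: nx.Graph) -> tuple[pd.DataFrame, dict[int, float]]:
    """Per-gene total/in/out degree plus a histogram of degree fractions.

    On an undirected network in-degree and out-degree equal the total
    degree.  Histogram fractions sum to 1 over the distinct total degrees.
    """
    nodes = list(network.nodes)
    if network.is_directed():
        k_in = dict(network.in_degree)
        k_out = dict(network.out_degree)
        k_tot = {v: k_in[v] + k_out[v] for v in nodes}
    else:
        k_tot = dict(network.degree)
        k_in = k_tot
        k_out = k_tot
    table = pd.DataFrame(
        {
            "gene": nodes,
            "degree_total": [k_tot[v] for v in nodes],
            "degree_in": [k_in[v] for v in nodes],
            "degree_out": [k_out[v] for v in nodes],
        }
    ).set_index("gene")
    counts = table["degree_total"].value_counts()
    histogram = {int(k): float(c) / len(nodes) for k, c in counts.items()}
    return table, histogram


# ---------------------------------------------------------------------------
# subgraph centrality


def subgraph_centrality(network: nx.Graph) -> pd.Series:
    """Closed-walk sum SC(i) = sum_j u_j(i)^2 exp(lambda_j) = (e^A)_{ii}.

    Computed by eigendecomposition of the binarized undirected adjacency.
    An isolated node scores exactly 1 (the zero-length walk).
    """
    und = _undirected(network)
    nodes, A = _binary_adjacency(und)
    if not nodes:
        return pd.Series(dtype=float)
    eigvals, eigvecs = np.linalg.eigh(A)
    sc = (eigvecs**2) @ np.exp(eigvals)
    return pd.Series(sc, index=nodes, name="subgraph_centrality")


# ---------------------------------------------------------------------------
# spectral gaps


def spectral_gaps(
    network: nx.Graph, weighted: bool = True
) -> tuple[float, float | None]:
    """Adjacency gap |l1| - |l2| and random-walk gap 1 - |l2|.

    The adjacency gap uses the weighted symmetric adjacency by default
    (``weighted=False`` binarizes).  The normalized gap is computed from
    the symmetric normalization D^{-1/2} A D^{-1/2} of the binarized
    adjacency with isolated nodes excluded; it is 0 exactly when the
    non-isolated part is disconnected or bipartite, and ``None`` (logged)
    when every node is isolated.
    """
    und = _undirected(network)
    nodes = list(und.nodes)
    if not nodes:
        raise ValueError("spectral gaps need a non-empty network")
    weight_key = "weight" if weighted else None
    A = nx.to_numpy_array(und, nodelist=nodes, weight=weight_key)
    np.fill_diagonal(A, 0.0)
    mags = np.sort(np.abs(np.linalg.eigvalsh(A)))[::-1]
    adjacency_gap = float(mags[0] - mags[1]) if len(mags) > 1 else float(mags[0])

    _, B = _binary_adjacency(und)
    deg = B.sum(axis=1)
    keep = deg > 0
    if not keep.any():
        logger.warning("normalized spectral gap undefined: all nodes isolated")
        return adjacency_gap, None
    Bk = B[np.ix_(keep, keep)]
    d = deg[keep]
    inv_sqrt = 1.0 / np.sqrt(d)
    S = inv_sqrt[:, None] * Bk * inv_sqrt[None, :]
    smags = np.sort(np.abs(np.linalg.eigvalsh(S)))[::-1]
    second = smags[1] if len(smags) > 1 else 0.0
    normalized_gap = float(min(1.0, max(0.0, 1.0 - second)))
    return adjacency_gap, normalized_gap


# ---------------------------------------------------------------------------
# girth, diameter, density


def girth(network: nx.Graph) -> float:
    """Smallest r >= 1 with trace(A^r) > 0 on the binary adjacency.

    Returns ``math.inf`` for acyclic graphs.  Meaningful on a directed
    view; on an undirected graph any edge gives a length-2 closed walk.
    """
    _, A = _binary_adjacency(network)
    n = A.shape[0]
    if n == 0:
        return math.inf
    B = A.astype(bool)
    P = np.eye(n, dtype=bool)
    for r in range(1, n + 1):
        P = (P.astype(np.uint8) @ B.astype(np.uint8)) > 0
        if P.trace() > 0:
            return float(r)
    return math.inf


def diameter_and_paths(network: nx.Graph) -> tuple[float, float, int]:
    """(diameter, avg shortest path, number of components).

    Components are those of the undirected view (weak components of a
    directed graph).  Diameter is the maximum finite unweighted
    eccentricity within components; the average shortest path is the mean
    distance over reachable ordered pairs (excluding self-pairs).  An
    edgeless graph has diameter ``inf`` and average path ``nan``.
    """
    und = _undirected(network)
    if len(und) == 0:
        raise ValueError("diameter needs a non-empty network")
    n_components = nx.number_connected_components(und)
    diameter = 0
    total, pairs = 0.0, 0
    for source, lengths in nx.all_pairs_shortest_path_length(und):
        for target, dist in lengths.items():
            if target == source:
                continue
            diameter = max(diameter, dist)
            total += dist
            pairs += 1
    if pairs == 0:
        return math.inf, math.nan, n_components
    return float(diameter), total / pairs, n_components


def density(network: nx.Graph) -> float:
    """Edges over possible edges: 2|E|/(|V|(|V|-1)) undirected, no factor 2
    directed."""
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    m = network.number_of_edges()
    possible = n * (n - 1)
    if not network.is_directed():
        possible //= 2
    return m / possible


# ---------------------------------------------------------------------------
# Jaccard neighborhood similarity


def jaccard(
    network_a: nx.Graph,
    gene_u: str,
    network_b: nx.Graph | None = None,
    gene_v: str | None = None,
    label_a: str = "",
    label_b: str = "",
) -> JaccardPair:
    """Intersection-over-union of two OPEN neighborhoods.

    The genes themselves are excluded from their neighborhoods, so a gene
    compared with itself across two networks scores 1.0 whenever its
    neighborhoods coincide.  Two empty neighborhoods score 0 (warned).
    """
    if network_b is None:
        network_b = network_a
    if gene_v is None:
        gene_v = gene_u
    for net, gene in ((network_a, gene_u), (network_b, gene_v)):
        if gene not in net:
            raise KeyError(f"gene {gene!r} not present in its network")
    nu = set(_undirected(network_a).neighbors(gene_u)) - {gene_u}
    nv = set(_undirected(network_b).neighbors(gene_v)) - {gene_v}
    union = nu | nv
    if not union:
        warnings.warn(
            f"both neighborhoods of {gene_u}/{gene_v} are empty; "
            "Jaccard defined as 0",
            stacklevel=2,
        )
        index = 0.0
    else:
        index = len(nu & nv) / len(union)
    return JaccardPair(gene_u, gene_v, index, label_a, label_b)


# ---------------------------------------------------------------------------
# centrality feature table


def centrality_features(network: nx.Graph) -> pd.DataFrame:
    """Per-gene measure table for the ranking stage.

    Columns: degree_total/in/out, subgraph_centrality, closeness (within-
    component convention), pagerank (damping 0.85, tol 1e-9; sums to 1),
    and eigenvector centrality of the largest component's binarized
    adjacency, L2-normalized (zeros elsewhere).
    """
    if len(network) == 0:
        raise ValueError("centrality features need a non-empty network")
    und = _undirected(network)
    table, _ = degree_distribution(network)
    table = table.copy()
    table["subgraph_centrality"] = subgraph_centrality(network)
    table["closeness"] = pd.Series(
        nx.closeness_centrality(und, wf_improved=False)
    )
    table["pagerank"] = pd.Series(
        nx.pagerank(und, alpha=0.85, tol=1e-9, max_iter=1000, weight=None)
    )

    eigenvector = pd.Series(0.0, index=table.index)
    if und.number_of_edges() == 0:
        warnings.warn(
            "eigenvector centrality undefined on an edgeless graph; zeros",
            stacklevel=2,
        )
    else:
        giant = max(nx.connected_components(und), key=lambda c: (len(c), sorted(c)))
        sub_nodes = sorted(giant)
        A = nx.to_numpy_array(und.subgraph(sub_nodes), nodelist=sub_nodes,
                              weight=None)
        # dense eigh for determinism (ARPACK uses a random start vector)
        eigvals, eigvecs = np.linalg.eigh(A)
        vec = np.abs(eigvecs[:, -1])
        vec = vec / np.linalg.norm(vec)
        for g, val in zip(sub_nodes, vec):
            eigenvector[g] = float(val)
    table["eigenvector"] = eigenvector
    return table


def summarize(network: nx.Graph, weighted_gap: bool = True) -> NetworkSummary:
    """Whole-graph measure report (the per-subnetwork summary row)."""
    und = _undirected(network)
    nodes = list(und.nodes)
    if not nodes:
        raise ValueError("cannot summarize an empty network")
    adjacency_gap, normalized_gap = spectral_gaps(und, weighted=weighted_gap)
    diameter, avg_sp, n_comp = diameter_and_paths(und)
    weight_key = "weight" if weighted_gap else None
    A = nx.to_numpy_array(und, nodelist=nodes, weight=weight_key)
    np.fill_diagonal(A, 0.0)
    eigenvalues = sorted((float(v) for v in np.linalg.eigvalsh(A)), reverse=True)
    return NetworkSummary(
        n_nodes=len(nodes),
        n_edges=und.number_of_edges(),
        spectral_gap_adjacency=adjacency_gap,
        spectral_gap_normalized=normalized_gap,
        girth=girth(network),
        diameter=diameter,
        density=density(und) if len(nodes) >= 2 else 0.0,
        n_components=n_comp,
        avg_shortest_path=avg_sp,
        eigenvalues=eigenvalues,
    )
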