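"""Process-module extraction: enrichment of gene sets on the network's node
list, induced subnetworks, and hub detection by degree thresholding.

Enrichment is a one-sided hypergeometric overrepresentation test of each
gene set against the network's node list, with Benjamini-Hochberg control
across sets.  Hubs are members whose total degree within the extracted
subnetwork reaches a configurable threshold; annotated radiation-induced
members can optionally be promoted to hub status regardless of degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from scipy import stats

from .io import GeneCatalog, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    network_size: int
    universe_size: int
    p_value: float
    q_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Subnetwork:
    """Induced process module of a parent network."""

    process: str
    graph: nx.Graph
    hubs: set[str] = field(default_factory=set)
    hub_threshold: int | None = None
    radiation_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def member_genes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self):
        return self.graph.edges


def enrich(
    network: nx.Graph,
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of each set on the network nodes.

    ``universe`` must contain every network node.  Results are BH-adjusted
    across sets and sorted by ascending p-value (ties by set name).
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("enrichment universe is empty")
    nodes = set(network.nodes)
    if not nodes <= universe_set:
        missing = sorted(nodes - universe_set)
        raise ValueError(
            f"{len(missing)} network node(s) missing from the universe: "
            f"{missing[:5]}"
        )
    M = len(universe_set)
    N = len(nodes)
    results = []
    pvals = []
    for name in sets.names():
        members = sets.members(name) & universe_set
        K = len(members)
        k = len(members & nodes)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        pvals.append(min(1.0, p))
        results.append(
            EnrichmentResult(
                set_name=name, overlap=k, set_size=K,
                network_size=N, universe_size=M,
                p_value=min(1.0, p), q_value=1.0,
            )
        )
    if results:
        qvals = stats.false_discovery_control(pvals, method="bh")
        for res, q in zip(results, qvals):
            res.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def extract_subnetwork(
    network: nx.Graph, set_members: Iterable[str], process: str
) -> Subnetwork:
    """Induce the subgraph on the set's members present in the network."""
    members = {g.upper() for g in set_members}
    present = members & set(network.nodes)
    if not present:
        raise ValueError(
            f"gene set for process {process!r} has no overlap with the network"
        )
    dropped = members - present
    if dropped:
        logger.info(
            "process %r: %d set member(s) absent from the network",
            process, len(dropped),
        )
    return Subnetwork(process=process, graph=network.subgraph(present).copy())


def detect_hubs(
    subnet: Subnetwork,
    degree_threshold: int,
    catalog: GeneCatalog | None = None,
    promote_radiation: bool = False,
) -> set[str]:
    """Hubs = members with total degree >= threshold (plus promoted genes).

    With ``promote_radiation``, annotated radiation-induced members are kept
    as hubs regardless of degree.  The hub set and threshold are recorded on
    the subnetwork; an empty result is allowed (and logged).
    """
    if degree_threshold < 1:
        raise ValueError("degree_threshold must be >= 1")
    degrees = dict(subnet.graph.degree)
    hubs = {g for g, d in degrees.items() if d >= degree_threshold}
    flags: dict[str, bool] = {}
    if catalog is not None:
        flags = {g: catalog.is_radiation_induced(g) for g in subnet.member_genes}
        if promote_radiation:
            promoted = {g for g, rad in flags.items() if rad} - hubs
            if promoted:
                logger.info(
                    "promoting %d radiation-induced gene(s) to hub status",
                    len(promoted),
                )
            hubs |= promoted
    if not hubs:
        logger.warning(
            "process %r: no hubs at degree threshold %d",
            subnet.process, degree_threshold,
        )
    subnet.hubs = hubs
    subnet.hub_threshold = degree_threshold
    subnet.radiation_flags = flags
    return hubs
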