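"""Pearson-correlation network inference with t-test significance filtering.

Every gene pair is scored by its Pearson coefficient over the replicate
samples; the coefficient is tested against zero with the exact Student-t
statistic ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom,
and pairs whose (optionally corrected) two-sided p-value exceeds the
threshold are discarded.  Surviving pairs become weighted edges (weight =
r) of an undirected gene network.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.0005

_CORRECTIONS = ("none", "bonferroni", "bh")


class ZeroVarianceError(ValueError):
    """A vector with no variance has undefined correlation."""


def pearson_r(x, y) -> float:
    """Pearson coefficient: covariance over the product of standard deviations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("zero-variance vector: correlation undefined")
    r = float(xd @ yd) / (sx * sy)
    return float(min(1.0, max(-1.0, r)))


def correlation_test(r: float, n: int) -> tuple[float, float]:
    """Two-sided t-test of ``r != 0`` on ``n - 2`` degrees of freedom.

    Returns ``(t_stat, p_value)``; ``|r| = 1`` yields an infinite statistic
    and an exact zero p-value.
    """
    if n < 3:
        raise ValueError("correlation test needs n >= 3")
    if abs(r) > 1.0 + 1e-12:
        raise ValueError(f"|r| > 1: {r}")
    r = min(1.0, max(-1.0, r))
    df = n - 2
    denom = 1.0 - r * r
    if denom <= 0.0:
        return (math.copysign(math.inf, r), 0.0)
    t = r * math.sqrt(df / denom)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return (t, min(1.0, p))


def _adjust(p: np.ndarray, correction: str) -> np.ndarray:
    if correction == "none":
        return p
    if correction == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if correction == "bh":
        return stats.false_discovery_control(p, method="bh")
    raise ValueError(f"correction must be one of {_CORRECTIONS}")


def build_grn(
    expr: ExpressionMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    correction: str = "none",
    directed: bool = False,
) -> nx.Graph:
    """Test all gene pairs and keep edges with (corrected) p <= threshold.

    Zero-variance genes are excluded up front (their correlation is
    undefined) and logged.  The returned graph is undirected with edge
    attributes ``weight`` (= r), ``t``, ``p`` and ``n``.  Only genes
    incident to at least one retained edge become nodes: the network is
    the co-expression structure, and downstream enrichment compares its
    node list against the full input universe.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {_CORRECTIONS}")

    X = expr.values
    n = expr.n_samples
    sd = X.std(axis=1)
    usable = sd > 0.0
    if not usable.all():
        dropped = [g for g, u in zip(expr.gene_ids, usable) if not u]
        logger.warning(
            "excluding %d zero-variance gene(s): %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
    genes = [g for g, u in zip(expr.gene_ids, usable) if u]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    X = X[usable]

    Z = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Z * Z).sum(axis=1))
    Z = Z / norms[:, None]
    R = np.clip(Z @ Z.T, -1.0, 1.0)

    iu, ju = np.triu_indices(len(genes), k=1)
    r = R[iu, ju]
    df = n - 2
    denom = 1.0 - r * r
    with np.errstate(divide="ignore"):
        t = np.where(denom > 0.0, r * np.sqrt(df / np.maximum(denom, 1e-300)),
                     np.copysign(np.inf, r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(denom <= 1e-15, 0.0, np.minimum(p, 1.0))
    p_adj = _adjust(p, correction)

    keep = p_adj <= p_threshold
    graph = nx.Graph(directed=False, p_threshold=p_threshold,
                     correction=correction, n_samples=n)
    for a, b, rv, tv, pv in zip(
        iu[keep], ju[keep], r[keep], t[keep], p_adj[keep]
    ):
        graph.add_edge(
            genes[a], genes[b],
            weight=float(rv), t=float(tv), p=float(pv), n=int(n),
        )
    logger.info(
        "GRN: %d genes, %d/%d pairs retained at p <= %g (%s correction)",
        len(genes), int(keep.sum()), len(r), p_threshold, correction,
    )
    if directed:
        return directed_view(graph, hubs=set())
    return graph


def directed_view(network: nx.Graph, hubs: set[str]) -> nx.DiGraph:
    """Presentation-layer orientation: non-hub -> hub on hub-incident edges.

    Correlation carries no direction, so edges not incident to exactly one
    hub are kept as reciprocal arc pairs.
    """
    out = nx.DiGraph(directed=True)
    out.add_nodes_from(network.nodes(data=True))
    for u, v, attrs in network.edges(data=True):
        u_hub, v_hub = u in hubs, v in hubs
        if v_hub and not u_hub:
            out.add_edge(u, v, **attrs)
        elif u_hub and not v_hub:
            out.add_edge(v, u, **attrs)
        else:
            out.add_edge(u, v, **attrs)
            out.add_edge(v, u, **attrs)
    return out
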