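"""Synthetic expression data with planted correlation structure.

The generator plants block-correlated gene modules built from shared latent
factors, star-shaped hub neighborhoods, labeled radiation-induced genes, and
a linear-Gaussian Bayesian network for causal-discovery testing — the
statistical structure every downstream stage assumes, with no external data.

Module genes follow ``x_g = sqrt(rho) * f_m + sqrt(1 - rho) * eps_g`` with a
per-module latent factor ``f_m`` and ``eps_g ~ N(0, noise_sd^2)``; with
``noise_sd = 1`` the expected pairwise correlation within a module is exactly
``rho``.  Hub genes additionally drive star leaves through a shared pairwise
component so that hub-leaf correlation is ``rho`` as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneCatalog, GeneSetCollection

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


def make_gene_ids(n: int, prefix_chrom: int = 1) -> list[str]:
    """Deterministic AGI-form identifiers AT1G00001, AT2G00002, ..."""
    chroms = "12345"
    return [
        f"AT{chroms[(prefix_chrom - 1 + i) % 5]}G{i + 1:05d}" for i in range(n)
    ]


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int
    n_modules: int
    module_sizes: tuple[int, ...]
    hub_leaf_counts: tuple[int, ...]
    n_samples: int = 5
    within_module_corr: float = 0.7
    noise_sd: float = 1.0
    frac_radiation_induced: float = 0.2
    seed: int = 0
    #: label hubs radiation-induced first (mirrors hub-centric annotation);
    #: False draws labels uniformly at random.
    hub_biased_labels: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        object.__setattr__(self, "hub_leaf_counts", tuple(self.hub_leaf_counts))
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if not 3 <= self.n_samples:
            raise ConfigurationError(
                "n_samples must be >= 3 (correlation test needs df = n-2 >= 1)"
            )
        if self.n_modules < 1 or len(self.module_sizes) != self.n_modules:
            raise ConfigurationError(
                "module_sizes must list one size per module"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be positive")
        if len(self.hub_leaf_counts) != self.n_modules:
            raise ConfigurationError(
                "hub_leaf_counts must list one star size per module"
            )
        if any(k < 0 for k in self.hub_leaf_counts):
            raise ConfigurationError("hub leaf counts must be >= 0")
        needed = sum(self.module_sizes) + sum(self.hub_leaf_counts)
        if needed > self.n_genes:
            raise ConfigurationError(
                f"module and star genes ({needed}) exceed n_genes "
                f"({self.n_genes})"
            )
        if not 0.0 < self.within_module_corr < 1.0:
            raise ConfigurationError(
                "within_module_corr must be strictly between 0 and 1"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0.0 <= self.frac_radiation_induced <= 1.0:
            raise ConfigurationError("frac_radiation_induced must be in [0,1]")


@dataclass
class LinearGaussianDAG:
    """Acyclic structure with per-variable linear parent coefficients."""

    variables: tuple[str, ...]
    #: variable -> list of (parent, coefficient)
    parents: dict[str, list[tuple[str, float]]]
    noise_sd: dict[str, float]

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ConfigurationError("bn_dag contains a directed cycle")
        for v, sd in self.noise_sd.items():
            if not np.isfinite(sd) or sd <= 0:
                raise ConfigurationError(f"noise sd for {v} must be positive")
        for v, ps in self.parents.items():
            for p, coef in ps:
                if not np.isfinite(coef):
                    raise ConfigurationError(f"coefficient {p}->{v} not finite")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for child, ps in self.parents.items():
            for parent, coef in ps:
                g.add_edge(parent, child, coefficient=coef)
        return g

    def markov_blanket(self, target: str) -> set[str]:
        """Structural MB: parents, children, and the children's other parents."""
        g = self.to_networkx()
        parents = set(g.predecessors(target))
        children = set(g.successors(target))
        spouses = {p for c in children for p in g.predecessors(c)}
        return (parents | children | spouses) - {target}

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "parents": {
                v: [[p, c] for p, c in ps] for v, ps in self.parents.items()
            },
            "noise_sd": dict(self.noise_sd),
        }


@dataclass
class GroundTruth:
    """Bookkeeping of the planted structure, for oracle-based tests."""

    module_assignment: dict[str, int]
    true_edges: set[frozenset[str]]
    radiation_labels: dict[str, bool]
    bn_dag: LinearGaussianDAG
    hubs: dict[int, str] = field(default_factory=dict)
    background: set[str] = field(default_factory=set)

    def module_genes(self, module: int) -> set[str]:
        return {
            g for g, m in self.module_assignment.items() if m == module
        }

    def to_dict(self) -> dict:
        return {
            "module_assignment": dict(sorted(self.module_assignment.items())),
            "true_edges": sorted(sorted(e) for e in self.true_edges),
            "radiation_labels": dict(sorted(self.radiation_labels.items())),
            "hubs": {str(k): v for k, v in sorted(self.hubs.items())},
            "background": sorted(self.background),
            "bn_dag": self.bn_dag.to_dict(),
        }


def random_linear_dag(
    variables: Sequence[str],
    edge_prob: float,
    seed: int,
    coef_range: tuple[float, float] = (0.5, 1.5),
    noise_sd: float = 1.0,
) -> LinearGaussianDAG:
    """Random DAG in the lexicographic-order upper triangle, random signs."""
    rng = np.random.default_rng(seed)
    variables = tuple(variables)
    parents: dict[str, list[tuple[str, float]]] = {v: [] for v in variables}
    lo, hi = coef_range
    for i, child in enumerate(variables):
        for parent in variables[:i]:
            if rng.random() < edge_prob:
                coef = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                parents[child].append((parent, float(coef)))
    return LinearGaussianDAG(
        variables=variables,
        parents=parents,
        noise_sd={v: noise_sd for v in variables},
    )


def generate_bn_data(
    dag: LinearGaussianDAG, n_obs: int, seed: int
) -> pd.DataFrame:
    """Sample a linear-Gaussian Bayesian network (rows = observations)."""
    if n_obs < 1:
        raise ConfigurationError("n_obs must be positive")
    rng = np.random.default_rng(seed)
    order = list(nx.topological_sort(dag.to_networkx()))
    data: dict[str, np.ndarray] = {}
    for v in order:
        x = rng.normal(0.0, dag.noise_sd[v], size=n_obs)
        for parent, coef in dag.parents.get(v, []):
            x = x + coef * data[parent]
        data[v] = x
    return pd.DataFrame({v: data[v] for v in dag.variables})


def generate_modular_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Plant correlated modules and hub stars; background genes are noise.

    Layout per module m: the first gene of the block is the hub; the module's
    ``hub_leaf_counts[m]`` star leaves are taken from the gene pool after all
    module blocks.  Remaining genes are independent background noise.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.within_module_corr
    sigma = config.noise_sd
    n, p = config.n_genes, config.n_samples
    genes = make_gene_ids(n)
    gene_pos = {g: i for i, g in enumerate(genes)}
    X = np.empty((n, p))

    assignment: dict[str, int] = {}
    true_edges: set[frozenset[str]] = set()
    hubs: dict[int, str] = {}

    idx = 0
    module_blocks: list[list[str]] = []
    for m, size in enumerate(config.module_sizes):
        block = genes[idx : idx + size]
        idx += size
        module_blocks.append(block)
        factor = rng.standard_normal(p)
        for g in block:
            assignment[g] = m
            gi = genes.index(g)
            X[gi] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * sigma * (
                rng.standard_normal(p)
            )
        hubs[m] = block[0]
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                true_edges.add(frozenset((block[a], block[b])))

    # population sd of a module gene, used to standardize the hub signal
    hub_sd = np.sqrt(rho + (1.0 - rho) * sigma**2)
    for m, k_leaves in enumerate(config.hub_leaf_counts):
        hub = hubs[m]
        hub_x = X[gene_pos[hub]] / hub_sd
        for _ in range(k_leaves):
            leaf = genes[idx]
            idx += 1
            assignment[leaf] = m
            X[gene_pos[leaf]] = rho * hub_x + np.sqrt(1.0 - rho**2) * (
                sigma * rng.standard_normal(p)
            )
            true_edges.add(frozenset((hub, leaf)))

    background = set(genes[idx:])
    for g in genes[idx:]:
        X[gene_pos[g]] = sigma * rng.standard_normal(p)

    # radiation labels: hubs first when biased, remainder drawn uniformly
    n_rad = int(round(config.frac_radiation_induced * n))
    labels = {g: False for g in genes}
    chosen: list[str] = []
    if config.hub_biased_labels:
        chosen = [hubs[m] for m in sorted(hubs)][:n_rad]
    pool = [g for g in genes if g not in chosen]
    extra = n_rad - len(chosen)
    if extra > 0:
        chosen += list(rng.choice(pool, size=extra, replace=False))
    for g in chosen:
        labels[g] = True

    # a compact BN over hub genes (plus fillers) for causal-discovery tests
    bn_vars = [hubs[m] for m in sorted(hubs)]
    if len(bn_vars) < 3:
        bn_vars = genes[: min(n, 5)]
    dag = random_linear_dag(
        sorted(set(bn_vars)), edge_prob=0.3, seed=config.seed + 1
    )

    expr = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=[f"S{j + 1}" for j in range(p)])
    )
    truth = GroundTruth(
        module_assignment=assignment,
        true_edges=true_edges,
        radiation_labels=labels,
        bn_dag=dag,
        hubs=hubs,
        background=background,
    )
    return expr, truth


def generate_gene_sets(
    ground_truth: GroundTruth,
    n_sets: int,
    overlap_frac: float = 0.0,
    seed: int = 0,
) -> GeneSetCollection:
    """One planted set per module plus decoy sets from background genes.

    ``overlap_frac`` of each planted set's size is added from genes outside
    the module, blurring the planted signal.
    """
    if n_sets < 1:
        raise ConfigurationError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    modules = sorted(ground_truth.hubs)
    all_genes = sorted(ground_truth.module_assignment) + sorted(
        ground_truth.background
    )
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for m in modules[: min(n_sets, len(modules))]:
        members = set(ground_truth.module_genes(m))
        n_extra = int(round(overlap_frac * len(members)))
        outside = sorted(set(all_genes) - members)
        if n_extra > 0 and outside:
            members |= set(
                rng.choice(outside, size=min(n_extra, len(outside)), replace=False)
            )
        sets[f"module_{m}"] = (f"planted module {m}", frozenset(members))
    n_decoys = n_sets - len(sets)
    decoy_pool = sorted(ground_truth.background) or all_genes
    decoy_size = max(3, min(10, len(decoy_pool)))
    for d in range(n_decoys):
        members = rng.choice(
            decoy_pool, size=min(decoy_size, len(decoy_pool)), replace=False
        )
        sets[f"decoy_{d}"] = ("background decoy", frozenset(members))
    return GeneSetCollection(sets)


def catalog_from_truth(truth: GroundTruth) -> GeneCatalog:
    return GeneCatalog(
        radiation_induced={g for g, v in truth.radiation_labels.items() if v}
    )
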