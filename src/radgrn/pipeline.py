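"""End-to-end orchestration: simulate/ingest -> infer -> extract -> measure
-> causal -> rank, with a manifest that makes every run reproducible.

A run is driven by a :class:`PipelineConfig` (loadable from YAML) holding
either input file paths or a simulation block, plus all stage thresholds
and a single seed.  Every intermediate artifact is written to the run
directory; the manifest records the config, its hash, and the SHA-256 of
every artifact, so two runs of the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, causal, grn, io, measures, ranking, simulate, subnetworks

logger = logging.getLogger(__name__)

#: IAMB needs n - |Z| - 3 > 0 with room for a non-trivial blanket.
MIN_CAUSAL_SAMPLES = 8


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # exactly one of the two input modes
    expression_path: str | None = None
    gene_sets_path: str | None = None
    catalog_path: str | None = None
    simulation: simulate.SimulationConfig | None = None
    # stage parameters
    p_threshold: float = grn.DEFAULT_P_THRESHOLD
    correction: str = "none"
    enrichment_alpha: float = 0.05
    enrichment_universe: str = "input"  # or "network"
    hub_threshold: int = 5
    promote_radiation: bool = False
    iamb_alpha: float = 0.05
    max_causal_targets: int = 10
    rank_label: str = "radiation"
    rank_by: str = "score"
    top: int = 50
    n_gene_sets: int | None = None
    gene_set_overlap: float = 0.0

    def __post_init__(self) -> None:
        has_paths = self.expression_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError(
                "config must set exactly one of 'expression_path' or "
                "'simulation'"
            )
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0.0 < self.enrichment_alpha < 1.0:
            raise ValueError("enrichment_alpha must be in (0, 1)")
        if not 0.0 < self.iamb_alpha < 1.0:
            raise ValueError("iamb_alpha must be in (0, 1)")
        if self.hub_threshold < 1:
            raise ValueError("hub_threshold must be >= 1")
        if self.enrichment_universe not in ("input", "network"):
            raise ValueError("enrichment_universe must be 'input' or 'network'")

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            out["simulation"] = dataclasses.asdict(self.simulation)
            out["simulation"]["module_sizes"] = list(
                self.simulation.module_sizes
            )
            out["simulation"]["hub_leaf_counts"] = list(
                self.simulation.hub_leaf_counts
            )
        return out

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PipelineConfig":
        payload = dict(payload)
        sim = payload.pop("simulation", None)
        if sim is not None:
            sim = simulate.SimulationConfig(**sim)
        return cls(simulation=sim, **payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("out_dir")  # where a run lands is not part of what it is
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunResult:
    run_dir: Path
    manifest: dict[str, Any]
    subnetworks: list[subnetworks.Subnetwork] = field(default_factory=list)
    rankings: dict[str, pd.DataFrame] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full flow and persist every intermediate artifact."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save(path: Path) -> Path:
        artifacts.append(path)
        return path

    # -- stage: simulate / ingest ------------------------------------------
    stage = "ingest"
    try:
        if config.simulation is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            expr, truth = simulate.generate_modular_expression(sim_cfg)
            catalog = simulate.catalog_from_truth(truth)
            n_sets = config.n_gene_sets or (sim_cfg.n_modules + 3)
            sets = simulate.generate_gene_sets(
                truth, n_sets, config.gene_set_overlap, seed=config.seed
            )
            save(io.write_expression(expr, run_dir / "expression.tsv"))
            truth_path = run_dir / "ground_truth.json"
            truth_path.write_text(
                json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n"
            )
            save(truth_path)
        else:
            expr = io.read_expression(config.expression_path)
            sets = (
                io.read_gene_sets(config.gene_sets_path)
                if config.gene_sets_path
                else io.GeneSetCollection({})
            )
            catalog = (
                io.read_catalog(config.catalog_path)
                if config.catalog_path
                else io.GeneCatalog()
            )
        save(io.write_catalog(catalog, run_dir / "catalog.json"))
        save(io.write_gene_sets(sets, run_dir / "gene_sets.gmt"))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: infer -------------------------------------------------------
    try:
        network = grn.build_grn(
            expr, p_threshold=config.p_threshold, correction=config.correction
        )
        save(io.write_network(network, run_dir / "grn.graphml"))
        save(io.write_network(network, run_dir / "grn.edges.tsv", "edgelist"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("infer", str(exc)) from exc

    # -- stage: enrich + extract -------------------------------------------
    subnets: list[subnetworks.Subnetwork] = []
    try:
        universe = (
            expr.gene_ids
            if config.enrichment_universe == "input"
            else list(network.nodes)
        )
        enrichment = subnetworks.enrich(network, sets, universe) if len(sets) else []
        enr_df = pd.DataFrame([e.to_dict() for e in enrichment])
        enr_path = run_dir / "enrichment.tsv"
        enr_df.to_csv(enr_path, sep="\t", index=False)
        save(enr_path)
        significant = [e for e in enrichment if e.q_value <= config.enrichment_alpha]
        for result in significant:
            sub = subnetworks.extract_subnetwork(
                network, sets.members(result.set_name), result.set_name
            )
            subnetworks.detect_hubs(
                sub,
                config.hub_threshold,
                catalog=catalog,
                promote_radiation=config.promote_radiation,
            )
            subnets.append(sub)
            save(
                io.write_network(
                    sub.graph, run_dir / f"subnet_{result.set_name}.graphml"
                )
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("extract", str(exc)) from exc

    # -- stage: measure -----------------------------------------------------
    try:
        summaries = {}
        for sub in subnets:
            table = measures.centrality_features(sub.graph)
            tpath = run_dir / f"measures_{sub.process}.tsv"
            table.to_csv(tpath, sep="\t", float_format="%.10g")
            save(tpath)
            summaries[sub.process] = measures.summarize(sub.graph).to_dict()
        net_summary = measures.summarize(network).to_dict()
        spath = run_dir / "network_summary.json"
        spath.write_text(
            json.dumps(
                {"grn": net_summary, "subnetworks": summaries},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        save(spath)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("measure", str(exc)) from exc

    # -- stage: causal ------------------------------------------------------
    try:
        if expr.n_samples >= MIN_CAUSAL_SAMPLES:
            data = pd.DataFrame(
                expr.values.T, columns=expr.gene_ids
            )
            targets = sorted(
                g for g in network.nodes if catalog.is_radiation_induced(g)
            )[: config.max_causal_targets]
            if targets:
                graph, mb_results = causal.causal_network(
                    data[sorted(network.nodes)], targets, alpha=config.iamb_alpha
                )
                mb_path = run_dir / "markov_blankets.json"
                mb_path.write_text(
                    json.dumps(
                        {t: r.to_dict() for t, r in sorted(mb_results.items())},
                        indent=2,
                        sort_keys=True,
                    )
                    + "\n"
                )
                save(mb_path)
                save(io.write_network(graph, run_dir / "causal.graphml"))
            else:
                logger.warning("no radiation-induced targets; causal stage skipped")
        else:
            logger.warning(
                "causal stage skipped: %d samples < %d required",
                expr.n_samples,
                MIN_CAUSAL_SAMPLES,
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("causal", str(exc)) from exc

    # -- stage: rank --------------------------------------------------------
    rankings: dict[str, pd.DataFrame] = {}
    try:
        for sub in subnets:
            table = measures.centrality_features(sub.graph)
            try:
                features = ranking.build_features(
                    sub, table, catalog=catalog, label=config.rank_label
                )
            except ValueError as exc:
                logger.warning(
                    "ranking skipped for %r: %s", sub.process, exc
                )
                continue
            model = ranking.fit_logistic(features)
            ranked = ranking.rank_genes(
                model, features, by=config.rank_by, catalog=catalog,
                top=config.top,
            )
            rpath = run_dir / f"ranking_{sub.process}.tsv"
            ranked.to_csv(rpath, sep="\t", index=False, float_format="%.10g")
            save(rpath)
            rankings[sub.process] = ranked
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("rank", str(exc)) from exc

    manifest = {
        "package": "radgrn",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "artifacts": {
            p.name: _sha256(p) for p in sorted(artifacts, key=lambda p: p.name)
        },
    }
    manifest_path = run_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(
        run_dir=run_dir,
        manifest=manifest,
        subnetworks=subnets,
        rankings=rankings,
    )


def report(run_dir: str | Path) -> Path:
    """Human-readable tables mirroring the per-hub / per-subnetwork layout.

    Writes ``report/hub_table.tsv`` (gene, degree, subgraph centrality per
    subnetwork), ``report/network_summary.tsv`` (one row per subnetwork),
    and ``report/jaccard.tsv`` (hub neighborhoods compared across
    subnetwork pairs; empty when fewer than two subnetworks exist).
    """
    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    warnings_log: list[str] = []

    summary_path = run_dir / "network_summary.json"
    sub_names: list[str] = []
    if summary_path.exists():
        payload = json.loads(summary_path.read_text())
        rows = []
        for name, summ in sorted(payload.get("subnetworks", {}).items()):
            rows.append({"subnetwork": name, **summ})
            sub_names.append(name)
        pd.DataFrame(rows).drop(
            columns=["eigenvalues"], errors="ignore"
        ).to_csv(report_dir / "network_summary.tsv", sep="\t", index=False)
    else:
        warnings_log.append("network_summary.json missing; summary table skipped")

    hub_rows = []
    nets = {}
    for name in sub_names:
        mpath = run_dir / f"measures_{name}.tsv"
        gpath = run_dir / f"subnet_{name}.graphml"
        if not mpath.exists() or not gpath.exists():
            warnings_log.append(f"artifacts for subnetwork {name!r} incomplete")
            continue
        table = pd.read_csv(mpath, sep="\t", index_col=0)
        nets[name] = io.read_network(gpath)
        for gene, row in table.iterrows():
            hub_rows.append(
                {
                    "subnetwork": name,
                    "gene": gene,
                    "degree": int(row["degree_total"]),
                    "subgraph_centrality": row["subgraph_centrality"],
                }
            )
    pd.DataFrame(
        hub_rows, columns=["subnetwork", "gene", "degree", "subgraph_centrality"]
    ).to_csv(report_dir / "hub_table.tsv", sep="\t", index=False)

    jrows = []
    names = sorted(nets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = set(nets[a].nodes) & set(nets[b].nodes)
            for gene in sorted(shared):
                pair = measures.jaccard(
                    nets[a], gene, nets[b], gene, label_a=a, label_b=b
                )
                jrows.append(
                    {
                        "gene": gene,
                        "subnetwork_a": a,
                        "subnetwork_b": b,
                        "jaccard": pair.index,
                    }
                )
    pd.DataFrame(
        jrows, columns=["gene", "subnetwork_a", "subnetwork_b", "jaccard"]
    ).to_csv(report_dir / "jaccard.tsv", sep="\t", index=False)

    if warnings_log:
        (report_dir / "WARNINGS.txt").write_text(
            "".join(f"{w}\n" for w in warnings_log)
        )
    return report_dir
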