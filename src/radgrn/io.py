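"""Readers and writers for the text formats the pipeline touches.

Expression tables are TSV/CSV with a header row of sample names and AGI
gene identifiers (``ATnGnnnnn``) in the first column.  Gene sets use the
GMT dialect (name, description, tab-separated members).  Networks are
exchanged as GraphML or three-column edge lists.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Arabidopsis Genome Initiative identifier: chromosomes 1-5 plus the
#: chloroplast (C) and mitochondrial (M) genomes.
AGI_PATTERN = re.compile(r"^AT[1-5CM]G\d{5}$", re.IGNORECASE)


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a contract (shape, identifiers...)."""


def is_agi(gene_id: str) -> bool:
    return bool(AGI_PATTERN.match(gene_id))


@dataclass
class ExpressionMatrix:
    """Genes x samples table of normalized expression values.

    Gene identifiers are upper-cased on ingest; rows containing missing
    values are dropped (and logged) rather than imputed, because the
    downstream correlation test runs on only 3-8 replicate values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.astype(str).str.upper()
        bad = [g for g in df.index if not is_agi(g)]
        if bad:
            raise ValidationError(
                f"{len(bad)} gene identifier(s) are not AGI-form (ATnGnnnnn): "
                f"{bad[:5]}"
            )
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        n_before = len(df)

        def _to_float(value):
            try:
                return float(value)  # exact round-trip parse
            except (TypeError, ValueError):
                return np.nan

        df = df.map(_to_float)
        df = df.dropna(axis=0, how="any")
        if len(df) < n_before:
            logger.warning(
                "dropped %d gene row(s) with missing values", n_before - len(df)
            )
        if df.shape[1] < 3:
            raise ValidationError(
                f"expression matrix needs >= 3 samples, got {df.shape[1]}"
            )
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GeneCatalog:
    """Flat annotation: which genes are radiation-induced, plus short names."""

    radiation_induced: set[str] = field(default_factory=set)
    display_name: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.radiation_induced = {g.upper() for g in self.radiation_induced}
        self.display_name = {g.upper(): v for g, v in self.display_name.items()}

    def is_radiation_induced(self, gene: str) -> bool:
        return gene.upper() in self.radiation_induced

    def check_universe(self, universe: Iterable[str]) -> None:
        missing = self.radiation_induced - {g.upper() for g in universe}
        if missing:
            raise ValidationError(
                f"{len(missing)} radiation-induced gene(s) missing from the "
                f"supplied universe: {sorted(missing)[:5]}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT dialect): name -> (description, member IDs)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, frozenset[str]]] = {}
        for name, (desc, members) in self.sets.items():
            members = frozenset(m.upper() for m in members)
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            cleaned[name] = (desc, members)
        self.sets = cleaned

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


# ---------------------------------------------------------------------------
# expression tables


def _sniff_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    raise FormatError("could not detect a tab or comma delimiter in the header")


def read_expression(path: str | Path, delimiter: str = "auto") -> ExpressionMatrix:
    """Read a genes x samples table (first column = gene ID, header row).

    ``delimiter`` is ``auto`` (sniffed from the header), ``tab`` or ``comma``.
    Ragged rows are rejected rather than coerced.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text:
        raise FormatError(f"{path}: empty file")
    sep = {"auto": None, "tab": "\t", "comma": ","}.get(delimiter, delimiter)
    if sep is None:
        sep = _sniff_delimiter(text[0])
    rows = list(csv.reader(text, delimiter=sep))
    header = rows[0]
    if len(header) < 4:
        raise FormatError(
            f"{path}: header has {len(header)} column(s); need a gene-ID "
            "column plus >= 3 samples"
        )
    width = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row at line {i}: {len(row)} fields, "
                f"expected {width}"
            )
    body = rows[1:]
    df = pd.DataFrame(
        [r[1:] for r in body],
        index=[r[0] for r in body],
        columns=header[1:],
    )
    return ExpressionMatrix(df)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, delimiter: str = "tab"
) -> Path:
    path = Path(path)
    sep = "\t" if delimiter == "tab" else ","
    # %.17g round-trips IEEE doubles exactly
    expr.data.to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# gene sets (GMT) and catalogs (JSON)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
            logger.warning("skipping empty gene set at line %d", lineno)
            continue
        name, desc = fields[0], fields[1]
        members = frozenset(m.upper() for m in fields[2:] if m.strip())
        sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
    return path


def read_catalog(path: str | Path) -> GeneCatalog:
    payload = json.loads(Path(path).read_text())
    return GeneCatalog(
        radiation_induced=set(payload.get("radiation_induced", [])),
        display_name=dict(payload.get("display_name", {})),
    )


def write_catalog(catalog: GeneCatalog, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "radiation_induced": sorted(catalog.radiation_induced),
        "display_name": dict(sorted(catalog.display_name.items())),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# networks


def write_network(
    network: nx.Graph, path: str | Path, format: str = "graphml"
) -> Path:
    """Export a network as GraphML or a ``source TAB target TAB weight`` list.

    Edge-list weights are printed to 6 decimals; GraphML keeps the ``weight``
    edge attribute and records directedness on the graph element.
    """
    path = Path(path)
    if format == "graphml":
        export = network.copy()
        # GraphML attributes must be scalars; drop Nones defensively.
        for _, _, attrs in export.edges(data=True):
            for key in [k for k, v in attrs.items() if v is None]:
                del attrs[key]
        nx.write_graphml(export, path, named_key_ids=True)
    elif format == "edgelist":
        with path.open("w") as fh:
            for u, v, attrs in network.edges(data=True):
                w = attrs.get("weight", 1.0)
                fh.write(f"{u}\t{v}\t{w:.6f}\n")
    else:
        raise FormatError(f"unknown network format: {format!r}")
    return path


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edgelist":
        graph = nx.Graph()
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields"
                )
            graph.add_edge(fields[0], fields[1], weight=float(fields[2]))
        return graph
    raise FormatError(f"unknown network format: {format!r}")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and ``#`` comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.upper())
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{g}\n" for g in genes))
    return path
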