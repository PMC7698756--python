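"""Associative gene networks: data model, TSV I/O, and set-level operations.

An associative network is a set of gene/protein nodes joined by typed,
optionally directed interaction edges (text-mining provenance attached),
plus a separate table of phenotype-gene associations.  Keeping phenotype
links out of the gene-gene edge multiset lets every graph algorithm
operate purely on molecular interactions.

Gene symbols are matched case-insensitively but stored case-preserved,
because literature-mined sources mix symbol casing freely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import (
    DanglingEndpointError,
    EmptyNetworkError,
    MissingColumnError,
    SelfLoopError,
    UnknownInteractionTypeError,
    UnknownPhenotypeError,
)

logger = logging.getLogger(__name__)

#: Generic (non-regulatory) interaction types.  These carry no direction and
#: are excluded when a "regulates" semantics is required.
GENERIC_ITYPES = frozenset(
    {"association", "coexpression", "expression", "interaction", "involvement"}
)

#: Directed regulatory / biochemical interaction types.
REGULATORY_ITYPES = frozenset(
    {
        "regulation",
        "upregulation",
        "downregulation",
        "catalysis",
        "transport",
        "cleavage",
        "degradation",
    }
)

ITYPE_VOCABULARY = GENERIC_ITYPES | REGULATORY_ITYPES

DEFAULT_SPECIES = "Homo sapiens"


def _canon(symbol: str) -> str:
    return symbol.strip().casefold()


@dataclass(frozen=True)
class GeneNode:
    """A gene/protein node. ``symbol`` is unique up to case."""

    symbol: str
    species: str = DEFAULT_SPECIES

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValueError("gene symbol must be non-empty")


@dataclass(frozen=True)
class InteractionEdge:
    """One typed gene-gene interaction record.

    Duplicate records between the same pair are meaningful (multi-edges from
    independent extractions) and are preserved.  Generic types are stored
    undirected by construction.
    """

    source: str
    target: str
    itype: str
    directed: bool = False
    source_db: str = ""
    pmids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.itype not in ITYPE_VOCABULARY:
            raise UnknownInteractionTypeError(
                f"unknown interaction type {self.itype!r}; "
                f"expected one of {sorted(ITYPE_VOCABULARY)}"
            )
        if self.itype in GENERIC_ITYPES and self.directed:
            # generic associations have no regulatory direction
            object.__setattr__(self, "directed", False)

    def touches(self, symbol_canon: str) -> bool:
        return _canon(self.source) == symbol_canon or _canon(self.target) == symbol_canon


@dataclass(frozen=True)
class PhenotypeAssociation:
    """A phenotype-gene association edge (kept apart from gene-gene edges)."""

    phenotype_id: str
    phenotype_name: str
    gene: str


@dataclass(frozen=True)
class GeneSet:
    """An unordered, case-insensitively deduplicated set of gene symbols."""

    genes: frozenset[str]
    label: str = ""

    @classmethod
    def from_iterable(cls, genes: Iterable[str], label: str = "") -> "GeneSet":
        seen: dict[str, str] = {}
        for g in genes:
            seen.setdefault(_canon(g), g.strip())
        return cls(frozenset(seen.values()), label)

    def canon(self) -> frozenset[str]:
        return frozenset(_canon(g) for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return _canon(symbol) in self.canon()


@dataclass
class AssociativeNetwork:
    """Gene nodes + typed interaction multiset + phenotype associations."""

    nodes: dict[str, GeneNode] = field(default_factory=dict)  # canon -> node
    edges: list[InteractionEdge] = field(default_factory=list)
    associations: list[PhenotypeAssociation] = field(default_factory=list)

    # -- construction -----------------------------------------------------

    def add_node(self, node: GeneNode) -> None:
        key = _canon(node.symbol)
        if key not in self.nodes:
            self.nodes[key] = node

    def add_edge(self, edge: InteractionEdge) -> None:
        s, t = _canon(edge.source), _canon(edge.target)
        if s == t:
            raise SelfLoopError(f"self-loop on {edge.source!r} rejected")
        for endpoint, sym in ((s, edge.source), (t, edge.target)):
            if endpoint not in self.nodes:
                raise DanglingEndpointError(
                    f"edge endpoint {sym!r} is not a declared node"
                )
        self.edges.append(edge)

    def add_association(self, assoc: PhenotypeAssociation) -> None:
        if _canon(assoc.gene) not in self.nodes:
            raise DanglingEndpointError(
                f"association gene {assoc.gene!r} is not a declared node"
            )
        key = (assoc.phenotype_id, _canon(assoc.gene))
        if key not in {(a.phenotype_id, _canon(a.gene)) for a in self.associations}:
            self.associations.append(assoc)

    # -- queries ----------------------------------------------------------

    def resolve(self, symbol: str) -> GeneNode:
        try:
            return self.nodes[_canon(symbol)]
        except KeyError:
            raise DanglingEndpointError(f"unknown gene symbol {symbol!r}") from None

    def has_gene(self, symbol: str) -> bool:
        return _canon(symbol) in self.nodes

    @property
    def gene_symbols(self) -> frozenset[str]:
        return frozenset(n.symbol for n in self.nodes.values())

    @property
    def phenotype_ids(self) -> frozenset[str]:
        return frozenset(a.phenotype_id for a in self.associations)

    def phenotype_genes(self, phenotype_id: str) -> GeneSet:
        """Genes associated with ``phenotype_id`` (error if unknown)."""
        if phenotype_id not in self.phenotype_ids:
            raise UnknownPhenotypeError(f"unknown phenotype id {phenotype_id!r}")
        genes = [
            self.nodes[_canon(a.gene)].symbol
            for a in self.associations
            if a.phenotype_id == phenotype_id
        ]
        return GeneSet.from_iterable(genes, label=phenotype_id)

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self.edges)

    def n_collapsed_edges(self) -> int:
        """Distinct unordered gene pairs with at least one edge record."""
        return len({frozenset((_canon(e.source), _canon(e.target))) for e in self.edges})

    def to_networkx(self, collapse: bool = True) -> nx.Graph | nx.MultiDiGraph:
        """Export the gene-gene graph.

        collapse=True yields the simple undirected graph used for
        centrality (multi-edges merged, direction dropped); collapse=False
        yields a MultiDiGraph retaining every record (undirected records
        become a pair of opposite arcs).
        """
        if collapse:
            g = nx.Graph()
            g.add_nodes_from(n.symbol for n in self.nodes.values())
            for e in self.edges:
                g.add_edge(self.resolve(e.source).symbol, self.resolve(e.target).symbol)
            return g
        g = nx.MultiDiGraph()
        g.add_nodes_from(n.symbol for n in self.nodes.values())
        for e in self.edges:
            s = self.resolve(e.source).symbol
            t = self.resolve(e.target).symbol
            g.add_edge(s, t, itype=e.itype, directed=e.directed)
            if not e.directed:
                g.add_edge(t, s, itype=e.itype, directed=e.directed)
        return g


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_NODE_COLUMNS = ("symbol",)
_EDGE_COLUMNS = ("source", "target", "itype", "directed")
_ASSOC_COLUMNS = ("phenotype_id", "phenotype_name", "gene")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    return df


def load_network(
    nodes_path: str | Path,
    edges_path: str | Path,
    associations_path: str | Path,
) -> AssociativeNetwork:
    """Load an associative network from three TSV tables.

    ``nodes.tsv``: symbol [, species]; ``edges.tsv``: source, target, itype,
    directed (0/1) [, source_db, pmids (';'-separated)];
    ``associations.tsv``: phenotype_id, phenotype_name, gene.
    Duplicate edge rows are kept as distinct multi-edge records.
    """
    net = AssociativeNetwork()

    nodes = _read_tsv(nodes_path, _NODE_COLUMNS)
    for row in nodes.itertuples(index=False):
        species = getattr(row, "species", "") or DEFAULT_SPECIES
        net.add_node(GeneNode(symbol=row.symbol, species=species))

    edges = _read_tsv(edges_path, _EDGE_COLUMNS)
    for row in edges.itertuples(index=False):
        pmids = tuple(p for p in getattr(row, "pmids", "").split(";") if p)
        net.add_edge(
            InteractionEdge(
                source=row.source,
                target=row.target,
                itype=row.itype,
                directed=str(row.directed).strip() in {"1", "true", "True"},
                source_db=getattr(row, "source_db", ""),
                pmids=pmids,
            )
        )

    assocs = _read_tsv(associations_path, _ASSOC_COLUMNS)
    for row in assocs.itertuples(index=False):
        net.add_association(
            PhenotypeAssociation(
                phenotype_id=row.phenotype_id,
                phenotype_name=row.phenotype_name,
                gene=row.gene,
            )
        )
    return net


def write_network(
    net: AssociativeNetwork,
    nodes_path: str | Path,
    edges_path: str | Path,
    associations_path: str | Path,
) -> None:
    """Write a network back to the three-table TSV layout (lossless)."""
    pd.DataFrame(
        [(n.symbol, n.species) for n in net.nodes.values()],
        columns=["symbol", "species"],
    ).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(
        [
            (e.source, e.target, e.itype, int(e.directed), e.source_db, ";".join(e.pmids))
            for e in net.edges
        ],
        columns=["source", "target", "itype", "directed", "source_db", "pmids"],
    ).to_csv(edges_path, sep="\t", index=False)
    pd.DataFrame(
        [(a.phenotype_id, a.phenotype_name, a.gene) for a in net.associations],
        columns=["phenotype_id", "phenotype_name", "gene"],
    ).to_csv(associations_path, sep="\t", index=False)


def read_gene_set(path: str | Path, label: str = "") -> GeneSet:
    """Read a gene set: one symbol per line, ``#`` comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return GeneSet.from_iterable(genes, label=label or Path(path).stem)


def write_gene_set(genes: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes.genes)) + "\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def phenotype_subnetwork(net: AssociativeNetwork, phenotype_id: str) -> AssociativeNetwork:
    """Induced subnetwork on the genes associated with one phenotype.

    Nodes are the associated genes; the edge multiset keeps every record
    whose two endpoints are both associated; associations are restricted to
    the phenotype.  Idempotent.
    """
    member = net.phenotype_genes(phenotype_id).canon()
    sub = AssociativeNetwork()
    for key in member:
        sub.add_node(net.nodes[key])
    for e in net.edges:
        if _canon(e.source) in member and _canon(e.target) in member:
            sub.edges.append(e)
    for a in net.associations:
        if a.phenotype_id == phenotype_id and _canon(a.gene) in member:
            sub.associations.append(a)
    return sub


def intersect_phenotypes(
    net: AssociativeNetwork, phenotype_a: str, phenotype_b: str
) -> GeneSet:
    """Genes associated with BOTH phenotypes (symmetric)."""
    a = net.phenotype_genes(phenotype_a)
    b = net.phenotype_genes(phenotype_b)
    common = a.canon() & b.canon()
    if not common:
        logger.warning(
            "phenotypes %r and %r share no associated genes", phenotype_a, phenotype_b
        )
    genes = [net.nodes[k].symbol for k in common]
    return GeneSet.from_iterable(genes, label=f"{phenotype_a}&{phenotype_b}")


def connection_counts(subnet: AssociativeNetwork) -> pd.DataFrame:
    """Per-gene connection counts, multi-edge records counted individually.

    Returns a DataFrame (gene, count) sorted by count descending, ties by
    symbol ascending.  Counting edge records rather than distinct
    neighbours is what lets a hub inside a 37-gene subnetwork reach dozens
    of connections.
    """
    if subnet.n_nodes() == 0:
        raise EmptyNetworkError("connection_counts requires a non-empty network")
    counts = {n.symbol: 0 for n in subnet.nodes.values()}
    for e in subnet.edges:
        counts[subnet.resolve(e.source).symbol] += 1
        counts[subnet.resolve(e.target).symbol] += 1
    df = pd.DataFrame(sorted(counts.items()), columns=["gene", "count"])
    return df.sort_values(
        ["count", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
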