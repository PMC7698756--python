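"""Candidate-gene discovery by typed, directed length-4 path search.

A candidate is the middle gene of a 5-slot chain

    phenotype_A <- gene2 <- gene3 -> gene4 -> phenotype_B

where gene2/gene4 are phenotype-linked intermediary genes, both regulatory
arrows originate at the candidate (gene3), the two gene-gene edges carry a
non-generic interaction type, and the candidate itself has no direct
association with either phenotype.  The phenotype-gene links (slots 1-2
and 4-5) accept any association, so only the two inner edges are filtered.

Also here: selection of genes directly regulated by a regulator set, and a
transparent guilt-by-association prioritizer (score = fraction of training
genes adjacent to the candidate) that any externally produced ranking can
replace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DanglingEndpointError, RankingMismatchError
from .network import (
    GENERIC_ITYPES,
    AssociativeNetwork,
    GeneSet,
    InteractionEdge,
    _canon,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CandidatePath",
    "RankedGeneList",
    "find_candidates",
    "regulated_genes",
    "prioritize_baseline",
    "load_ranking",
]


@dataclass(frozen=True)
class CandidatePath:
    """A witnessing 5-slot path; gene3 is the candidate."""

    phenotype_a: str
    gene2: str
    gene3: str
    gene4: str
    phenotype_b: str
    edge23: InteractionEdge  # stored as gene3 -> gene2
    edge34: InteractionEdge  # stored as gene3 -> gene4


@dataclass(frozen=True)
class RankedGeneList:
    """An ordered candidate ranking; rank 1 is the best."""

    entries: tuple[tuple[int, str, float], ...]  # (rank, gene, score)

    def __post_init__(self) -> None:
        ranks = [r for r, _, _ in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be consecutive from 1")
        scores = [s for _, _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing with rank")
        genes = [_canon(g) for _, g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("genes must be unique")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for _, g, _ in self.entries)

    def rank_of(self, gene: str) -> int:
        key = _canon(gene)
        for rank, g, _ in self.entries:
            if _canon(g) == key:
                return rank
        raise KeyError(gene)

    def top(self, k: int) -> GeneSet:
        return GeneSet.from_iterable(
            (g for rank, g, _ in self.entries if rank <= k), label=f"top{k}"
        )

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["rank", "gene", "score"])

    @classmethod
    def from_scores(cls, scores: dict[str, float]) -> "RankedGeneList":
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(tuple((i + 1, g, s) for i, (g, s) in enumerate(ordered)))


def _directed_regulatory_edges(net: AssociativeNetwork) -> dict[str, list[InteractionEdge]]:
    """Outgoing directed non-generic edges, indexed by canonical source."""
    out: dict[str, list[InteractionEdge]] = {}
    for e in net.edges:
        if e.directed and e.itype not in GENERIC_ITYPES:
            out.setdefault(_canon(e.source), []).append(e)
    return out


def find_candidates(
    net: AssociativeNetwork,
    phenotype_hypo: str,
    phenotype_hyper: str,
    intermediaries: GeneSet,
    require_distinct_intermediaries: bool = False,
    allow_intermediary_candidates: bool = False,
) -> tuple[GeneSet, list[CandidatePath]]:
    """Length-4 path search for candidate genes.

    A gene c qualifies iff it is NOT directly associated with either
    phenotype and there exist intermediaries g2 (hypo-associated) and g4
    (hyper-associated) with directed non-generic edges c->g2 and c->g4.
    All witnessing paths are returned, deduplicated.

    require_distinct_intermediaries forces g2 != g4 (by default one GV gene
    may serve both slots, since each GV gene is associated with both
    phenotypes).  allow_intermediary_candidates lifts the exclusion of
    intermediary genes from the candidate slot; with phenotype-associated
    intermediaries the direct-association rule excludes them anyway.
    """
    for g in intermediaries:
        if not net.has_gene(g):
            raise DanglingEndpointError(f"intermediary {g!r} is not in the network")

    hypo = net.phenotype_genes(phenotype_hypo).canon()
    hyper = net.phenotype_genes(phenotype_hyper).canon()
    inter = intermediaries.canon()
    g2_pool = inter & hypo
    g4_pool = inter & hyper
    excluded = hypo | hyper
    if not allow_intermediary_candidates:
        excluded = excluded | inter

    outgoing = _directed_regulatory_edges(net)
    paths: set[CandidatePath] = set()
    for c_key, edges in outgoing.items():
        if c_key in excluded:
            continue
        to_g2 = [e for e in edges if _canon(e.target) in g2_pool]
        to_g4 = [e for e in edges if _canon(e.target) in g4_pool]
        if not to_g2 or not to_g4:
            continue
        c_sym = net.nodes[c_key].symbol
        for e23 in to_g2:
            for e34 in to_g4:
                if require_distinct_intermediaries and _canon(e23.target) == _canon(
                    e34.target
                ):
                    continue
                paths.add(
                    CandidatePath(
                        phenotype_a=phenotype_hypo,
                        gene2=net.resolve(e23.target).symbol,
                        gene3=c_sym,
                        gene4=net.resolve(e34.target).symbol,
                        phenotype_b=phenotype_hyper,
                        edge23=e23,
                        edge34=e34,
                    )
                )

    candidates = GeneSet.from_iterable(
        (p.gene3 for p in paths), label=f"candidates:{phenotype_hypo}~{phenotype_hyper}"
    )
    ordered = sorted(paths, key=lambda p: (p.gene3, p.gene2, p.gene4, p.edge23.itype, p.edge34.itype))
    return candidates, ordered


def regulated_genes(
    net: AssociativeNetwork, regulators: GeneSet, scope: GeneSet
) -> GeneSet:
    """Genes in ``scope`` with at least one incoming directed non-generic
    edge from a regulator."""
    if len(scope) == 0:
        raise ValueError("scope must be non-empty")
    reg = regulators.canon()
    scope_keys = scope.canon()
    hits = set()
    for e in net.edges:
        if (
            e.directed
            and e.itype not in GENERIC_ITYPES
            and _canon(e.source) in reg
            and _canon(e.target) in scope_keys
        ):
            hits.add(net.resolve(e.target).symbol)
    return GeneSet.from_iterable(hits, label=f"regulated:{regulators.label or 'set'}")


def prioritize_baseline(
    candidates: GeneSet, training: GeneSet, net: AssociativeNetwork
) -> RankedGeneList:
    """Guilt-by-association ranking of candidates against a training set.

    score(c) = (# distinct training genes adjacent to c by any edge record,
    either direction, any type) / |training|.  Ties break alphabetically;
    deterministic by construction.
    """
    if len(training) == 0:
        raise ValueError("training set must be non-empty")
    if len(candidates) == 0:
        raise ValueError("candidate set must be non-empty")

    train = training.canon()
    neighbors: dict[str, set[str]] = {_canon(c): set() for c in candidates}
    for e in net.edges:
        s, t = _canon(e.source), _canon(e.target)
        if s in neighbors and t in train:
            neighbors[s].add(t)
        if t in neighbors and s in train:
            neighbors[t].add(s)

    scores = {
        net.nodes[c].symbol if net.has_gene(c) else c: len(adj) / len(train)
        for c, adj in neighbors.items()
    }
    if all(v == 0 for v in scores.values()):
        logger.warning("all candidates scored 0; ranking is alphabetical")
    return RankedGeneList.from_scores(scores)


def load_ranking(path: str | Path, candidates: GeneSet | None = None) -> RankedGeneList:
    """Read an externally produced ranking TSV (rank, gene, score) and,
    if a candidate set is given, validate that it is fully covered."""
    df = pd.read_csv(path, sep="\t")
    for col in ("rank", "gene", "score"):
        if col not in df.columns:
            raise RankingMismatchError(f"{path}: missing column {col!r}")
    df = df.sort_values("rank")
    ranking = RankedGeneList(
        tuple((int(r), str(g), float(s)) for r, g, s in df[["rank", "gene", "score"]].itertuples(index=False))
    )
    if candidates is not None:
        missing = candidates.canon() - {_canon(g) for g in ranking.genes}
        if missing:
            raise RankingMismatchError(
                f"ranking misses {len(missing)} candidate gene(s), e.g. {sorted(missing)[:5]}"
            )
    return ranking
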