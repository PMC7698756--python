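"""miRNA-target validation of a candidate gene list.

Differentially expressed miRNAs (e.g. from a rat glucose-fluctuation
experiment) are mapped to their target genes, targets are translated to
human symbols through an ortholog map, and the overlap between targets and
a ranked candidate list is tested: one overall hypergeometric test against
a gene universe, plus top-k membership tests asking whether the overlapping
genes cluster near the top of the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .discovery import RankedGeneList
from .errors import RankingMismatchError
from .network import GeneSet, _canon
from .stats import hypergeom_tail, topk_membership_test

logger = logging.getLogger(__name__)

__all__ = [
    "MirnaTargetMap",
    "OrthologMap",
    "ValidationReport",
    "targets_of_mirnas",
    "map_orthologs",
    "validate_candidates",
    "read_mirna_targets",
    "read_orthologs",
]


@dataclass(frozen=True)
class MirnaTargetMap:
    """Rows (mirna_id, target_gene, species); duplicate pairs collapsed."""

    rows: tuple[tuple[str, str, str], ...]

    @classmethod
    def from_rows(cls, rows) -> "MirnaTargetMap":
        seen = {}
        for mirna, target, species in rows:
            seen.setdefault((mirna, _canon(target)), (mirna, target, species))
        return cls(tuple(seen.values()))

    def targets(self, mirna: str) -> list[str]:
        return [t for m, t, _ in self.rows if m == mirna]

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _, _ in self.rows)


@dataclass(frozen=True)
class OrthologMap:
    """Rows (source_gene, source_taxon, human_gene); many-to-one allowed."""

    rows: tuple[tuple[str, str, str], ...]

    def human(self, gene: str) -> str | None:
        key = _canon(gene)
        for src, _, hum in self.rows:
            if _canon(src) == key:
                return hum
        return None


@dataclass(frozen=True)
class TopKResult:
    k_top: int
    m_observed: int
    p: float
    overlap_genes: tuple[str, ...]


@dataclass(frozen=True)
class ValidationReport:
    population_size: int
    n_candidates: int
    n_targets: int
    overlap_genes: tuple[str, ...]
    p_overall: float
    topk: tuple[TopKResult, ...]

    def as_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "n_candidates": self.n_candidates,
            "n_targets": self.n_targets,
            "overlap": len(self.overlap_genes),
            "overlap_genes": list(self.overlap_genes),
            "p_overall": self.p_overall,
            "topk": [
                {
                    "k_top": t.k_top,
                    "m_observed": t.m_observed,
                    "p": t.p,
                    "overlap_genes": list(t.overlap_genes),
                }
                for t in self.topk
            ],
        }


def targets_of_mirnas(
    mirnas: "list[str]", targets: MirnaTargetMap
) -> tuple[GeneSet, list[str]]:
    """Union of target genes over the queried miRNAs.

    miRNAs absent from the map are returned separately (and logged) rather
    than erroring: a miRNA with no catalogued targets is an expected
    outcome, not a failure.
    """
    found: list[str] = []
    missing: list[str] = []
    for m in mirnas:
        hits = targets.targets(m)
        if hits:
            found.extend(hits)
        else:
            missing.append(m)
    if missing:
        logger.info("%d miRNA(s) had no targets in the map: %s", len(missing), missing)
    return GeneSet.from_iterable(found, label="mirna_targets"), missing


def map_orthologs(genes: GeneSet, orthologs: OrthologMap) -> GeneSet:
    """Image of a gene set under the ortholog map; unmapped genes dropped
    (count logged), duplicates collapsed."""
    mapped: list[str] = []
    dropped = 0
    for g in sorted(genes.genes):
        hum = orthologs.human(g)
        if hum is None:
            dropped += 1
        else:
            mapped.append(hum)
    if dropped:
        logger.info("%d gene(s) had no ortholog and were dropped", dropped)
    return GeneSet.from_iterable(mapped, label=f"{genes.label}:human")


def validate_candidates(
    candidates: GeneSet,
    ranking: RankedGeneList,
    target_genes: GeneSet,
    population_size: int,
    top_ks: "list[int]",
) -> ValidationReport:
    """Overall and top-k enrichment of miRNA targets in the candidate list.

    Overall: P(X >= overlap) drawing |candidates| genes from a universe of
    ``population_size`` containing |target_genes| targets.  Per k_top: the
    chance that at least the observed number of overlap genes land in the
    top k_top ranks of a random ordering of the candidates.
    """
    if population_size < len(candidates):
        raise ValueError("population_size must be at least the candidate count")
    missing = candidates.canon() - {_canon(g) for g in ranking.genes}
    if missing:
        raise RankingMismatchError(
            f"ranking does not cover {len(missing)} candidate(s)"
        )

    overlap_keys = candidates.canon() & target_genes.canon()
    overlap = tuple(sorted(g for g in candidates.genes if _canon(g) in overlap_keys))
    p_overall = hypergeom_tail(
        len(overlap), population_size, len(target_genes), len(candidates)
    )

    topk_results = []
    for k_top in sorted(top_ks):
        in_top = ranking.top(k_top).canon() & overlap_keys
        m = len(in_top)
        p = topk_membership_test(len(candidates), len(overlap), k_top, m)
        topk_results.append(
            TopKResult(
                k_top=k_top,
                m_observed=m,
                p=p,
                overlap_genes=tuple(sorted(g for g in overlap if _canon(g) in in_top)),
            )
        )
    return ValidationReport(
        population_size=population_size,
        n_candidates=len(candidates),
        n_targets=len(target_genes),
        overlap_genes=overlap,
        p_overall=p_overall,
        topk=tuple(topk_results),
    )


def read_mirna_targets(path: str | Path) -> MirnaTargetMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna_id", "target_gene", "species"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return MirnaTargetMap.from_rows(
        df[["mirna_id", "target_gene", "species"]].itertuples(index=False)
    )


def read_orthologs(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_gene", "source_taxon", "human_gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    rows = []
    seen = set()
    for src, taxon, hum in df[["source_gene", "source_taxon", "human_gene"]].itertuples(index=False):
        key = (_canon(src), taxon)
        if key in seen:
            raise ValueError(f"{path}: duplicate source gene {src!r} for taxon {taxon!r}")
        seen.add(key)
        rows.append((src, taxon, hum))
    return OrthologMap(tuple(rows))
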