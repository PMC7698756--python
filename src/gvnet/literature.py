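"""Literature co-occurrence statistics over article counts.

Given a corpus of N_total articles of which K_gv mention glucose
variability, a gene mentioned in n_gene articles with k_joint joint
mentions is scored by the upper-tail hypergeometric probability of seeing
at least k_joint joint mentions by chance.  A Spearman correlation between
a prioritization's rank numbers and these chance probabilities validates
the ranking: positive rho means worse-ranked genes have larger "chance"
probabilities, i.e. weaker literature support.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as sps

from .discovery import RankedGeneList
from .errors import InconsistentCountsError, RankingMismatchError
from .network import _canon
from .stats import bh_fdr, hypergeom_tail

__all__ = [
    "GV_QUERY_TERMS",
    "ArticleCounts",
    "CooccurrenceRecord",
    "cooccurrence_test",
    "cooccurrence_table",
    "rank_probability_correlation",
    "read_article_counts",
    "write_article_counts",
]

#: The 13 phrase variants denoting glucose variability used to count
#: GV-mentioning articles in a full-text corpus.  Shipped for users who
#: fetch their own counts; this package performs no web queries.
GV_QUERY_TERMS: tuple[str, ...] = (
    "glucose variability",
    "glycemic variability",
    "glycemia variability",
    "glucose fluctuations",
    "glycemic fluctuations",
    "sugar fluctuations",
    "glucose fluctuation",
    "glycemic fluctuation",
    "sugar fluctuation",
    "glucose excursions",
    "glycemic excursions",
    "unstable blood glucose",
    "fluctuating blood glucose",
)


@dataclass(frozen=True)
class ArticleCounts:
    """Per-gene article counts against a fixed corpus.

    rows: (gene, n_gene, k_joint) with n_gene articles mentioning the gene
    and k_joint mentioning both the gene and GV.
    """

    n_total: int
    k_gv: int
    rows: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not (0 <= self.k_gv <= self.n_total):
            raise InconsistentCountsError("K_gv must lie in [0, N_total]")
        for gene, n_gene, k_joint in self.rows:
            if not (0 <= n_gene <= self.n_total and 0 <= k_joint <= min(n_gene, self.k_gv)):
                raise InconsistentCountsError(
                    f"inconsistent counts for gene {gene!r}: "
                    f"n_gene={n_gene}, k_joint={k_joint}"
                )


@dataclass(frozen=True)
class CooccurrenceRecord:
    gene: str
    n_gene: int
    k_joint: int
    p: float
    p_adj: float


def cooccurrence_test(n_total: int, k_gv: int, n_gene: int, k_joint: int) -> float:
    """P(X >= k_joint) for X ~ Hypergeometric(N_total, K_gv, n_gene).

    A gene with no articles (n_gene = 0) has p = 1: an absent mention is
    vacuous evidence.
    """
    return hypergeom_tail(k_joint, n_total, k_gv, n_gene)


def cooccurrence_table(counts: ArticleCounts) -> list[CooccurrenceRecord]:
    """Per-gene co-occurrence tests with BH adjustment across all genes,
    sorted by p ascending."""
    if not counts.rows:
        raise ValueError("article-count table has no gene rows")
    pvals = [
        cooccurrence_test(counts.n_total, counts.k_gv, n_gene, k_joint)
        for _, n_gene, k_joint in counts.rows
    ]
    padj = bh_fdr(pvals)
    records = [
        CooccurrenceRecord(gene, n_gene, k_joint, p, pa)
        for (gene, n_gene, k_joint), p, pa in zip(counts.rows, pvals, padj)
    ]
    return sorted(records, key=lambda r: (r.p, r.gene))


def _exact_spearman_p(ranks: np.ndarray, values: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation-exact p for Spearman rho at small n.

    Enumerates every permutation of one rank vector against the other in
    vectorised chunks (rankdata commutes with permutation, so permuting
    the values permutes their midranks identically).
    """
    rx = sps.rankdata(ranks)
    ry = sps.rankdata(values)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
    if denom == 0:
        return 1.0
    n = len(ranks)
    threshold = abs(rho_obs) * denom - 1e-9
    count = total = 0
    chunk: list[tuple[int, ...]] = []

    def flush(chunk_perms: list[tuple[int, ...]]) -> int:
        idx = np.array(chunk_perms, dtype=np.int8)
        dots = ryc[idx] @ rxc
        return int(np.sum(np.abs(dots) >= threshold))

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 200_000:
            count += flush(chunk)
            total += len(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
        total += len(chunk)
    return count / total


def rank_probability_correlation(
    ranking: RankedGeneList,
    records: "list[CooccurrenceRecord]",
    use_adjusted: bool = False,
) -> tuple[float, float]:
    """Spearman correlation between prioritization rank and the chance
    probability of the gene's GV co-occurrence.

    Rank 1 is the best candidate; positive rho therefore means stronger
    literature co-occurrence (smaller p) for better-ranked genes.  Raw
    probabilities are used by default (``use_adjusted`` switches to the
    FDR-adjusted ones).  Ties receive average ranks.  Significance is the
    large-sample t approximation for n > 10 and an exact permutation test
    for n <= 10.
    """
    by_gene = {_canon(r.gene): r for r in records}
    missing = [g for g in ranking.genes if _canon(g) not in by_gene]
    if missing:
        raise RankingMismatchError(
            f"{len(missing)} ranked gene(s) lack co-occurrence records, "
            f"e.g. {missing[:5]}"
        )
    ranks = np.array([ranking.rank_of(g) for g in ranking.genes], dtype=float)
    probs = np.array(
        [
            by_gene[_canon(g)].p_adj if use_adjusted else by_gene[_canon(g)].p
            for g in ranking.genes
        ],
        dtype=float,
    )
    n = len(ranks)
    if n < 2:
        raise ValueError("need at least two genes to correlate")

    res = sps.spearmanr(ranks, probs)
    rho = float(res.statistic)
    if math.isnan(rho):
        return 0.0, 1.0
    if n <= 10:
        p = _exact_spearman_p(ranks, probs, rho)
    else:
        p = float(res.pvalue)
    return rho, p


# ---------------------------------------------------------------------------
# I/O: counts.tsv with a '#N_total=... K_gv=...' header line
# ---------------------------------------------------------------------------


def read_article_counts(path: str | Path) -> ArticleCounts:
    """Read counts.tsv: first line ``#N_total=<int> K_gv=<int>``, then
    tab-separated columns gene, n_gene, k_joint."""
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("#"):
        raise ValueError(f"{path}: missing '#N_total=... K_gv=...' header line")
    header = dict(
        tok.split("=", 1) for tok in text[0].lstrip("#").split() if "=" in tok
    )
    try:
        n_total = int(header["N_total"])
        k_gv = int(header["K_gv"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: malformed header line {text[0]!r}") from exc

    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
    for col in ("gene", "n_gene", "k_joint"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    rows = tuple(
        (str(g), int(n), int(k))
        for g, n, k in df[["gene", "n_gene", "k_joint"]].itertuples(index=False)
    )
    return ArticleCounts(n_total=n_total, k_gv=k_gv, rows=rows)


def write_article_counts(counts: ArticleCounts, path: str | Path) -> None:
    lines = [f"#N_total={counts.n_total} K_gv={counts.k_gv}", "gene\tn_gene\tk_joint"]
    lines += [f"{g}\t{n}\t{k}" for g, n, k in counts.rows]
    Path(path).write_text("\n".join(lines) + "\n")
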