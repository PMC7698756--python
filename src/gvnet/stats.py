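"""Shared statistical kernel: hypergeometric tails, BH FDR, term
overrepresentation, and the top-k membership test.

All overrepresentation tests in the pipeline reduce to the upper tail of a
hypergeometric distribution P(X >= k) with population N, K marked items and
n draws; scipy's survival function evaluates it in log space, so it stays
stable for literature-scale populations (N in the millions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InconsistentCountsError
from .network import GeneSet

__all__ = [
    "EnrichmentResult",
    "hypergeom_tail",
    "bh_fdr",
    "term_enrichment",
    "topk_membership_test",
    "read_gmt",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's overrepresentation test: overlap k of K marked in a query
    of n drawn from a background of N."""

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float

    @property
    def significant(self) -> bool:
        return self.p_adj < 0.05


def _check_counts(k: int, N: int, K: int, n: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise InconsistentCountsError(
            f"inconsistent hypergeometric counts: k={k}, N={N}, K={K}, n={n}"
        )


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k: observed overlap; N: population size; K: marked items in the
    population; n: sample size.  Returns 1.0 at k = 0.
    """
    _check_counts(k, N, K, n)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def term_enrichment(
    query: GeneSet,
    annotation: Mapping[str, GeneSet] | Mapping[str, tuple[str, GeneSet]],
    background: GeneSet,
    test_zero_overlap: bool = False,
) -> list[EnrichmentResult]:
    """Overrepresentation of annotation terms in a query gene set.

    Each term set is intersected with the background before testing; terms
    with zero overlap with the query are by default excluded from both the
    test and the BH family (only represented terms are reported), unless
    ``test_zero_overlap`` is set.  Results are sorted by p ascending.
    """
    if len(query) == 0:
        raise ValueError("empty query gene set")
    if not annotation:
        raise ValueError("empty annotation")
    bg = background.canon()
    q = query.canon() & bg
    if query.canon() - bg:
        raise ValueError("query must be a subset of the background")
    N, n = len(bg), len(q)

    rows: list[tuple[str, str, int, int]] = []
    for term_id, value in annotation.items():
        if isinstance(value, tuple):
            term_name, members = value
        else:
            term_name, members = term_id, value
        term = members.canon() & bg
        k = len(term & q)
        if k == 0 and not test_zero_overlap:
            continue
        rows.append((term_id, term_name, k, len(term)))

    if not rows:
        return []
    pvals = [hypergeom_tail(k, N, K, n) for (_, _, k, K) in rows]
    padj = bh_fdr(pvals)
    results = [
        EnrichmentResult(term_id, term_name, k, K, n, N, p, pa)
        for (term_id, term_name, k, K), p, pa in zip(rows, pvals, padj)
    ]
    return sorted(results, key=lambda r: (r.p, r.term_id))


def topk_membership_test(
    n_candidates: int, n_marked: int, k_top: int, m_observed: int
) -> float:
    """Probability that >= m of n_marked genes land in the top k_top of a
    random ranking of n_candidates genes.

    Hypergeometric with population n_candidates, k_top 'top' positions and
    n_marked draws.
    """
    if k_top > n_candidates:
        raise InconsistentCountsError(
            f"k_top={k_top} exceeds candidate count {n_candidates}"
        )
    return hypergeom_tail(m_observed, n_candidates, k_top, n_marked)


def read_gmt(path: str | Path) -> dict[str, tuple[str, GeneSet]]:
    """Read a GMT file: term_id TAB term_name TAB member genes..."""
    annotation: dict[str, tuple[str, GeneSet]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        term_id, term_name, genes = parts[0], parts[1], parts[2:]
        annotation[term_id] = (term_name, GeneSet.from_iterable(genes, label=term_id))
    return annotation


def write_gmt(annotation: Mapping[str, tuple[str, GeneSet]], path: str | Path) -> None:
    lines = [
        "\t".join([term_id, term_name, *sorted(members.genes)])
        for term_id, (term_name, members) in annotation.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
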