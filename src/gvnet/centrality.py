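"""Betweenness centrality of complication networks and the two summary
statistics: overrepresentation of GV genes among network participants and
elevation of their centrality.

Centrality is computed on the simple undirected graph obtained by
collapsing multi-edges and dropping direction: text-mined networks mix
directed and undirected edge types, and collapsing is the conservative
reading.  Values are unnormalized raw pair counts (Brandes semantics:
endpoints excluded, credit split across equal-length shortest paths,
each unordered pair counted once).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import scipy.stats as sps

from .errors import EmptyNetworkError
from .network import AssociativeNetwork, GeneSet, phenotype_subnetwork
from .stats import hypergeom_tail

__all__ = [
    "CentralityReport",
    "betweenness",
    "overrepresentation_test",
    "centrality_comparison_test",
    "complication_report",
]


@dataclass(frozen=True)
class CentralityReport:
    """Per-network summary: size, GV-gene overrepresentation, and the
    centrality contrast between GV genes and the rest."""

    network_label: str
    n_participants: int
    n_interactions: int          # edge records (multi-edges counted)
    n_interactions_collapsed: int  # distinct gene pairs
    n_gv_genes: int
    p_overrepresentation: float
    mean_centrality_all: float
    mean_centrality_gv: float
    p_centrality_difference: float

    def as_dict(self) -> dict:
        return asdict(self)


def betweenness(net: AssociativeNetwork) -> dict[str, float]:
    """Unnormalized betweenness centrality per gene.

    For each gene, the number of shortest paths between all other gene
    pairs passing through it, with fractional credit when a pair has
    several equally short paths.
    """
    if net.n_nodes() == 0:
        raise EmptyNetworkError("betweenness requires a non-empty network")
    g = net.to_networkx(collapse=True)
    return nx.betweenness_centrality(g, normalized=False)


def overrepresentation_test(
    network_genes: GeneSet, marked_genes: GeneSet, background_size: int
) -> float:
    """Upper-tail hypergeometric probability that at least the observed
    number of marked genes appear among the network participants.

    Population = background_size, K = marked genes, n = network genes,
    k = overlap.
    """
    n = len(network_genes)
    K = len(marked_genes)
    k = len(network_genes.canon() & marked_genes.canon())
    if background_size < n:
        raise ValueError("background_size must be at least the network size")
    return hypergeom_tail(k, background_size, K, n)


def _mann_whitney_u(subset: np.ndarray, rest: np.ndarray) -> float:
    """U statistic counting subset-over-rest wins, ties as half."""
    wins = (subset[:, None] > rest[None, :]).sum()
    ties = (subset[:, None] == rest[None, :]).sum()
    return float(wins) + 0.5 * float(ties)


def centrality_comparison_test(
    values_rest: "list[float] | np.ndarray",
    values_subset: "list[float] | np.ndarray",
    exact_limit: int = 12,
) -> float:
    """One-sided Mann-Whitney U: P(subset stochastically greater than rest).

    Combined sample size <= ``exact_limit``: permutation-exact enumeration
    over all assignments of the pooled values to the subset (tie-safe).
    Larger samples: normal approximation with tie correction.
    """
    rest = np.asarray(values_rest, dtype=float)
    subset = np.asarray(values_subset, dtype=float)
    if rest.size == 0 or subset.size == 0:
        raise ValueError("both value sequences must be non-empty")

    n_total = rest.size + subset.size
    if n_total <= exact_limit:
        pooled = np.concatenate([rest, subset])
        u_obs = _mann_whitney_u(subset, rest)
        m = subset.size
        count = total = 0
        for idx in itertools.combinations(range(n_total), m):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(idx)] = True
            u = _mann_whitney_u(pooled[mask], pooled[~mask])
            total += 1
            if u >= u_obs - 1e-12:
                count += 1
        return count / total

    res = sps.mannwhitneyu(subset, rest, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def complication_report(
    net: AssociativeNetwork,
    complication_phenotype: str,
    gv_genes: GeneSet,
    background_size: int,
    network_label: str | None = None,
) -> CentralityReport:
    """Assemble the full per-complication summary.

    The subnetwork induced by the complication phenotype is extracted; the
    comparison contrasts GV genes present in it against all its other
    genes.  A GV set disjoint from the subnetwork yields
    p_overrepresentation = 1 and p_centrality_difference = 1.
    """
    sub = phenotype_subnetwork(net, complication_phenotype)
    members = GeneSet.from_iterable(sub.gene_symbols, label=complication_phenotype)
    gv_in = members.canon() & gv_genes.canon()

    if sub.n_nodes() == 0:
        raise EmptyNetworkError(
            f"phenotype {complication_phenotype!r} has no associated genes"
        )

    p_over = overrepresentation_test(members, gv_genes, background_size)
    cent = betweenness(sub)
    canon_cent = {k.casefold(): v for k, v in cent.items()}
    gv_vals = [canon_cent[g] for g in sorted(gv_in)]
    rest_vals = [v for k, v in sorted(canon_cent.items()) if k not in gv_in]

    mean_all = float(np.mean(list(cent.values())))
    mean_gv = float(np.mean(gv_vals)) if gv_vals else 0.0
    if gv_vals and rest_vals:
        p_diff = centrality_comparison_test(rest_vals, gv_vals)
    else:
        p_diff = 1.0

    return CentralityReport(
        network_label=network_label or complication_phenotype,
        n_participants=sub.n_nodes(),
        n_interactions=sub.n_edges(),
        n_interactions_collapsed=sub.n_collapsed_edges(),
        n_gv_genes=len(gv_in),
        p_overrepresentation=p_over,
        mean_centrality_all=mean_all,
        mean_centrality_gv=mean_gv,
        p_centrality_difference=p_diff,
    )
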