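"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import settings

from gvnet.network import (
    GENERIC_ITYPES,
    REGULATORY_ITYPES,
    AssociativeNetwork,
    GeneNode,
    GeneSet,
    InteractionEdge,
    PhenotypeAssociation,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# network construction helpers
# ---------------------------------------------------------------------------


def build_network(
    genes,
    edges=(),
    associations=(),
) -> AssociativeNetwork:
    """Construct a network from terse tuples.

    edges: (source, target, itype[, directed]); associations:
    (phenotype_id, gene).
    """
    net = AssociativeNetwork()
    for g in genes:
        net.add_node(GeneNode(symbol=g))
    for e in edges:
        src, tgt, itype = e[0], e[1], e[2]
        directed = e[3] if len(e) > 3 else (itype in REGULATORY_ITYPES)
        net.add_edge(InteractionEdge(source=src, target=tgt, itype=itype, directed=directed))
    for pheno, gene in associations:
        net.add_association(PhenotypeAssociation(pheno, pheno, gene))
    return net


def random_typed_network(rng: np.random.Generator, n_nodes: int) -> AssociativeNetwork:
    """A random associative network with typed, optionally directed edges
    and random hypo/hyper associations."""
    genes = [f"N{i}" for i in range(n_nodes)]
    itypes = sorted(GENERIC_ITYPES | REGULATORY_ITYPES)
    net = AssociativeNetwork()
    for g in genes:
        net.add_node(GeneNode(symbol=g))
    n_edges = int(rng.integers(0, max(1, 3 * n_nodes)))
    for _ in range(n_edges):
        u, v = rng.choice(n_nodes, size=2, replace=False)
        itype = itypes[int(rng.integers(len(itypes)))]
        net.add_edge(
            InteractionEdge(
                source=genes[int(u)],
                target=genes[int(v)],
                itype=itype,
                directed=itype in REGULATORY_ITYPES and rng.random() < 0.8,
            )
        )
    for g in genes:
        r = rng.random()
        if r < 0.25:
            net.add_association(PhenotypeAssociation("hypo", "hypo", g))
        if 0.15 < r < 0.40:
            net.add_association(PhenotypeAssociation("hyper", "hyper", g))
    # both phenotypes always present, so downstream queries never error
    net.add_association(PhenotypeAssociation("hypo", "hypo", genes[0]))
    net.add_association(PhenotypeAssociation("hyper", "hyper", genes[0]))
    return net


@pytest.fixture
def simple_net() -> AssociativeNetwork:
    """Genes A..E; A,B,C hypo-associated; B,C,D hyper-associated."""
    return build_network(
        "ABCDE",
        edges=[
            ("A", "B", "regulation"),
            ("A", "B", "upregulation"),
            ("B", "C", "interaction"),
            ("C", "D", "catalysis"),
        ],
        associations=[
            ("hypo", "A"), ("hypo", "B"), ("hypo", "C"),
            ("hyper", "B"), ("hyper", "C"), ("hyper", "D"),
        ],
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_betweenness(adj: dict[str, set[str]]) -> dict[str, float]:
    """Betweenness by explicit enumeration of every shortest path.

    BFS distances per source, then depth-first enumeration of all
    geodesics; each unordered pair counted once, endpoints excluded,
    credit split equally across the pair's shortest paths.
    """
    nodes = sorted(adj)
    bc = dict.fromkeys(nodes, 0.0)

    def bfs_dist(src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    def all_paths(src, dst, dist):
        # walk backwards from dst along strictly decreasing distance
        def back(v):
            if v == src:
                return [[src]]
            out = []
            for u in adj[v]:
                if u in dist and dist[u] == dist[v] - 1:
                    out.extend(p + [v] for p in back(u))
            return out

        return back(dst)

    for i, s in enumerate(nodes):
        dist = bfs_dist(s)
        for t in nodes[i + 1 :]:
            if t not in dist:
                continue
            paths = all_paths(s, t, dist)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def exact_hypergeom_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) as an exact rational, by direct summation of the pmf."""
    total = comb(N, n)
    hits = sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if 0 <= n - j <= N - K
    )
    return Fraction(hits, total)


def brute_find_candidates(net: AssociativeNetwork, pheno_a, pheno_b, intermediaries):
    """Candidate genes by exhaustive loop over every (c, e23, e34) triple."""
    hypo = {g.casefold() for g in net.phenotype_genes(pheno_a).genes}
    hyper = {g.casefold() for g in net.phenotype_genes(pheno_b).genes}
    inter = {g.casefold() for g in intermediaries.genes}
    out = set()
    for c_key, c_node in net.nodes.items():
        if c_key in hypo or c_key in hyper or c_key in inter:
            continue
        has2 = has4 = False
        for e in net.edges:
            if not e.directed or e.itype in GENERIC_ITYPES:
                continue
            if e.source.casefold() != c_key:
                continue
            t = e.target.casefold()
            if t in inter and t in hypo:
                has2 = True
            if t in inter and t in hyper:
                has4 = True
        if has2 and has4:
            out.add(c_node.symbol)
    return out


def enumerate_mwu_exact(rest, subset) -> float:
    """One-sided Mann-Whitney p by enumerating every subset assignment."""
    pooled = list(rest) + list(subset)
    m = len(subset)

    def u_stat(sub, rst):
        u = 0.0
        for a in sub:
            for b in rst:
                if a > b:
                    u += 1
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_stat(list(subset), list(rest))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        chosen = [pooled[i] for i in idx]
        others = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(chosen, others) >= u_obs - 1e-12:
            hits += 1
    return hits / total


def net_to_adj(net: AssociativeNetwork) -> dict[str, set[str]]:
    """Collapsed undirected adjacency of a network's gene-gene edges."""
    adj: dict[str, set[str]] = {n.symbol: set() for n in net.nodes.values()}
    for e in net.edges:
        s = net.resolve(e.source).symbol
        t = net.resolve(e.target).symbol
        adj[s].add(t)
        adj[t].add(s)
    return adj
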