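"""Length-4 path search, regulated-gene selection and the baseline
prioritizer."""

import numpy as np
import pytest

from gvnet.discovery import (
    RankedGeneList,
    find_candidates,
    load_ranking,
    prioritize_baseline,
    regulated_genes,
)
from gvnet.errors import DanglingEndpointError, RankingMismatchError
from gvnet.network import GeneSet

from conftest import brute_find_candidates, build_network, random_typed_network


def _minimal_net(itype23="upregulation", candidate_assoc=None):
    assoc = [("hypo", "G1"), ("hyper", "G2")]
    if candidate_assoc:
        assoc.append((candidate_assoc, "C"))
    return build_network(
        ["C", "G1", "G2"],
        edges=[("C", "G1", itype23, True), ("C", "G2", "downregulation", True)],
        associations=assoc,
    )


class TestFindCandidates:
    INTER = GeneSet.from_iterable(["G1", "G2"])

    def test_minimal_positive_case(self):
        cands, paths = find_candidates(_minimal_net(), "hypo", "hyper", self.INTER)
        assert cands.genes == frozenset({"C"})
        assert len(paths) == 1
        p = paths[0]
        assert (p.gene2, p.gene3, p.gene4) == ("G1", "C", "G2")
        assert p.edge23.source == "C" and p.edge34.source == "C"

    def test_generic_itype_excluded(self):
        cands, _ = find_candidates(
            _minimal_net(itype23="coexpression"), "hypo", "hyper", self.INTER
        )
        assert len(cands) == 0

    def test_directly_associated_candidate_excluded(self):
        cands, _ = find_candidates(
            _minimal_net(candidate_assoc="hypo"), "hypo", "hyper", self.INTER
        )
        assert len(cands) == 0

    def test_wrong_direction_excluded(self):
        net = build_network(
            ["C", "G1", "G2"],
            edges=[("G1", "C", "upregulation", True), ("C", "G2", "regulation", True)],
            associations=[("hypo", "G1"), ("hyper", "G2")],
        )
        cands, _ = find_candidates(net, "hypo", "hyper", self.INTER)
        assert len(cands) == 0

    def test_shared_intermediary_allowed_unless_distinct_required(self):
        # one GV gene carries both associations; C regulates only it
        net = build_network(
            ["C", "G"],
            edges=[("C", "G", "regulation", True)],
            associations=[("hypo", "G"), ("hyper", "G")],
        )
        inter = GeneSet.from_iterable(["G"])
        cands, _ = find_candidates(net, "hypo", "hyper", inter)
        assert cands.genes == frozenset({"C"})
        strict, _ = find_candidates(
            net, "hypo", "hyper", inter, require_distinct_intermediaries=True
        )
        assert len(strict) == 0

    def test_unknown_intermediary_rejected(self):
        with pytest.raises(DanglingEndpointError):
            find_candidates(
                _minimal_net(), "hypo", "hyper", GeneSet.from_iterable(["NOPE"])
            )

    def test_candidates_never_phenotype_associated(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_typed_network(rng, int(rng.integers(5, 40)))
            inter = GeneSet.from_iterable(
                net.phenotype_genes("hypo").genes & net.phenotype_genes("hyper").genes
            )
            cands, _ = find_candidates(net, "hypo", "hyper", inter)
            assoc = net.phenotype_genes("hypo").canon() | net.phenotype_genes("hyper").canon()
            assert not (cands.canon() & assoc)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        net = random_typed_network(rng, int(rng.integers(5, 51)))
        inter = GeneSet.from_iterable(
            net.phenotype_genes("hypo").genes & net.phenotype_genes("hyper").genes
        )
        cands, paths = find_candidates(net, "hypo", "hyper", inter)
        assert set(cands.genes) == brute_find_candidates(net, "hypo", "hyper", inter)
        # every witnessing path satisfies its own invariants
        for p in paths:
            assert p.edge23.directed and p.edge34.directed
            assert p.gene2 in inter and p.gene4 in inter


class TestRegulatedGenes:
    def test_direct_regulation_selected(self):
        net = build_network(
            "ABC",
            edges=[("A", "B", "regulation", True)],
            associations=[],
        )
        got = regulated_genes(
            net, GeneSet.from_iterable(["A"]), GeneSet.from_iterable(["B", "C"])
        )
        assert got.genes == frozenset({"B"})

    def test_generic_undirected_never_counts(self):
        net = build_network("AB", edges=[("A", "B", "interaction")])
        got = regulated_genes(
            net, GeneSet.from_iterable(["A"]), GeneSet.from_iterable(["B"])
        )
        assert len(got) == 0

    def test_empty_scope_rejected(self):
        net = build_network("AB")
        with pytest.raises(ValueError):
            regulated_genes(net, GeneSet.from_iterable(["A"]), GeneSet.from_iterable([]))


class TestPrioritizeBaseline:
    def test_adjacency_fraction_scoring(self):
        net = build_network(
            ["c1", "c2", "t1", "t2", "t3", "t4"],
            edges=[
                ("c1", "t1", "interaction"), ("c1", "t2", "regulation", True),
                ("c2", "t1", "interaction"),
            ],
        )
        ranking = prioritize_baseline(
            GeneSet.from_iterable(["c1", "c2"]),
            GeneSet.from_iterable(["t1", "t2", "t3", "t4"]),
            net,
        )
        assert ranking.entries[0] == (1, "c1", 0.5)
        assert ranking.entries[1] == (2, "c2", 0.25)

    def test_all_zero_scores_rank_alphabetically(self):
        net = build_network(["b", "a", "t"])
        ranking = prioritize_baseline(
            GeneSet.from_iterable(["b", "a"]), GeneSet.from_iterable(["t"]), net
        )
        assert ranking.genes == ("a", "b")

    def test_empty_training_rejected(self):
        net = build_network("AB")
        with pytest.raises(ValueError):
            prioritize_baseline(
                GeneSet.from_iterable(["A"]), GeneSet.from_iterable([]), net
            )

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        net = random_typed_network(rng, 30)
        genes = sorted(net.gene_symbols)
        cands = GeneSet.from_iterable(genes[:10])
        train = GeneSet.from_iterable(genes[10:20])
        assert prioritize_baseline(cands, train, net) == prioritize_baseline(cands, train, net)


class TestRankedGeneList:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RankedGeneList(((1, "a", 1.0), (3, "b", 0.5)))
        with pytest.raises(ValueError):
            RankedGeneList(((1, "a", 0.5), (2, "b", 1.0)))
        with pytest.raises(ValueError):
            RankedGeneList(((1, "a", 1.0), (2, "A", 0.5)))

    def test_external_ranking_roundtrip_and_validation(self, tmp_path):
        ranking = RankedGeneList(((1, "x", 2.0), (2, "y", 1.0)))
        path = tmp_path / "rank.tsv"
        ranking.to_frame().to_csv(path, sep="\t", index=False)
        assert load_ranking(path).genes == ("x", "y")
        with pytest.raises(RankingMismatchError):
            load_ranking(path, GeneSet.from_iterable(["x", "y", "z"]))
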