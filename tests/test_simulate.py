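"""Synthetic-data generators: determinism, planted-structure recovery and
round-trips."""

import filecmp

import numpy as np
import pytest

from gvnet.discovery import RankedGeneList, find_candidates
from gvnet.errors import InfeasibleConfigError
from gvnet.literature import cooccurrence_table
from gvnet.mirna import map_orthologs, targets_of_mirnas, validate_candidates
from gvnet.network import GeneSet, intersect_phenotypes, load_network
from gvnet.simulate import (
    GeneratorConfig,
    generate_article_counts,
    generate_mirna_targets,
    generate_network,
    write_fixtures,
)
from gvnet.stats import hypergeom_tail

SMALL = dict(n_genes=120, core_size=12, n_regulators=7, n_complications=2,
             n_complication_genes=20)


class TestGenerateNetwork:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = GeneratorConfig(seed=5, **SMALL)
        for d in ("a", "b"):
            write_fixtures(cfg, tmp_path / d)
        same = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert not same.diff_files and not same.left_only and not same.right_only

    def test_noise_zero_intersection_recovers_core(self):
        cfg = GeneratorConfig(seed=2, assoc_noise=0.0, **SMALL)
        net, truth = generate_network(cfg)
        gv = intersect_phenotypes(net, "hypo", "hyper")
        assert gv.genes == frozenset(truth["core"])

    def test_noise_zero_path_search_recovers_regulators(self):
        cfg = GeneratorConfig(seed=4, assoc_noise=0.0, **SMALL)
        net, truth = generate_network(cfg)
        core = GeneSet.from_iterable(truth["core"])
        cands, _ = find_candidates(net, "hypo", "hyper", core)
        assert cands.genes == frozenset(truth["regulators"])
        assert len(cands) == 7

    def test_noisy_associations_do_not_disturb_the_core(self):
        # noise adds single-phenotype associations only, so the
        # intersection still recovers exactly the planted core
        cfg = GeneratorConfig(seed=8, assoc_noise=0.3, **SMALL)
        net, truth = generate_network(cfg)
        gv = intersect_phenotypes(net, "hypo", "hyper")
        assert gv.genes == frozenset(truth["core"])

    def test_regulators_carry_no_phenotype_associations(self):
        cfg = GeneratorConfig(seed=6, assoc_noise=0.5, **SMALL)
        net, truth = generate_network(cfg)
        regs = {r.casefold() for r in truth["regulators"]}
        for a in net.associations:
            assert a.gene.casefold() not in regs

    def test_infeasible_configs_rejected(self):
        with pytest.raises(InfeasibleConfigError):
            GeneratorConfig(n_genes=10, core_size=8, n_regulators=5).validate()
        with pytest.raises(InfeasibleConfigError):
            GeneratorConfig(edge_density=0.0).validate()
        with pytest.raises(InfeasibleConfigError):
            GeneratorConfig(itype_weights={"interaction": 1.0}).validate()
        with pytest.raises(InfeasibleConfigError):
            GeneratorConfig(itype_weights={"regulation": -1.0}).validate()

    def test_fixtures_roundtrip_through_readers(self, tmp_path):
        cfg = GeneratorConfig(seed=9, **SMALL)
        write_fixtures(cfg, tmp_path)
        net, truth = generate_network(cfg)
        back = load_network(
            tmp_path / "nodes.tsv", tmp_path / "edges.tsv", tmp_path / "associations.tsv"
        )
        assert back.gene_symbols == net.gene_symbols
        assert sorted(
            (e.source, e.target, e.itype, e.directed) for e in back.edges
        ) == sorted((e.source, e.target, e.itype, e.directed) for e in net.edges)
        assert set(back.phenotype_ids) == set(net.phenotype_ids)


class TestGenerateArticleCounts:
    GENES = [f"g{i}" for i in range(200)]

    def test_null_effect_pvalues_are_valid(self):
        # discrete tails put mass at p = 1, so the null distribution is
        # super-uniform: P(p <= alpha) must not exceed alpha (validity),
        # checked by pooling over seeds on a grid of thresholds
        pooled = []
        for seed in range(5):
            cfg = GeneratorConfig(seed=seed)
            counts = generate_article_counts(
                self.GENES, GeneSet.from_iterable(self.GENES[:50]), cfg, effect=1.0
            )
            pooled.extend(r.p for r in cooccurrence_table(counts))
        pooled = np.asarray(pooled)
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            assert np.mean(pooled <= alpha) <= alpha + 2 * np.sqrt(
                alpha * (1 - alpha) / pooled.size
            )

    def test_large_effect_concentrates_smallest_pvalues(self):
        cfg = GeneratorConfig(seed=1)
        true = GeneSet.from_iterable(self.GENES[:50])
        counts = generate_article_counts(self.GENES, true, cfg, effect=20.0)
        table = cooccurrence_table(counts)
        top = [r.gene for r in table[:25]]
        assert sum(g in true for g in top) >= 20

    def test_empty_gene_list_gives_empty_table(self):
        counts = generate_article_counts([], GeneSet.from_iterable([]), GeneratorConfig())
        assert counts.rows == ()

    def test_infeasible_rates_rejected(self):
        with pytest.raises(InfeasibleConfigError):
            generate_article_counts(self.GENES, GeneSet.from_iterable([]),
                                    GeneratorConfig(), effect=0.0)


class TestGenerateMirnaTargets:
    def _ranking(self, n=334):
        return RankedGeneList(tuple((i + 1, f"C{i:03d}", float(n - i)) for i in range(n)))

    def test_planted_overlap_matches_closed_form(self):
        ranking = self._ranking()
        cfg = GeneratorConfig(seed=3)
        mirnas, tmap, omap = generate_mirna_targets(ranking, 5, 100, cfg, n_targets=69)
        rat, missing = targets_of_mirnas(mirnas, tmap)
        assert len(missing) == 4
        human = map_orthologs(rat, omap)
        assert len(human) == 69
        candidates = GeneSet.from_iterable(ranking.genes)
        report = validate_candidates(candidates, ranking, human, 20_000, [100])
        assert len(report.overlap_genes) == 5
        assert report.p_overall == pytest.approx(hypergeom_tail(5, 20_000, 69, 334))
        assert report.topk[0].m_observed == 5
        assert report.topk[0].p == pytest.approx(hypergeom_tail(5, 334, 100, 5))

    def test_zero_overlap_all_tests_one(self):
        ranking = self._ranking(50)
        cfg = GeneratorConfig(seed=3)
        mirnas, tmap, omap = generate_mirna_targets(ranking, 0, 10, cfg, n_targets=12)
        human = map_orthologs(targets_of_mirnas(mirnas, tmap)[0], omap)
        report = validate_candidates(
            GeneSet.from_iterable(ranking.genes), ranking, human, 20_000, [10]
        )
        assert report.p_overall == 1.0 and report.topk[0].p == 1.0

    def test_deterministic_tables(self):
        ranking = self._ranking(40)
        cfg = GeneratorConfig(seed=12)
        out1 = generate_mirna_targets(ranking, 3, 20, cfg, n_targets=10)
        out2 = generate_mirna_targets(ranking, 3, 20, cfg, n_targets=10)
        assert out1 == out2

    def test_infeasible_placement_rejected(self):
        with pytest.raises(InfeasibleConfigError):
            generate_mirna_targets(self._ranking(40), 30, 20, GeneratorConfig())
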