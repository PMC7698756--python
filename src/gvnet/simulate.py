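"""Seeded generators for synthetic associative networks, article-count
tables and miRNA-target tables with planted ground truth.

The generators emulate the statistical structure the pipeline assumes:

* a planted "GV core" of genes associated with both the hypoglycemia and
  hyperglycemia phenotypes (so phenotype intersection recovers it);
* planted upstream regulators, each with at least one directed regulatory
  edge into the core and no phenotype associations (so the length-4 path
  search recovers exactly them when noise is off);
* complication phenotype networks in which the core genes bridge two
  otherwise unconnected blocks, guaranteeing elevated betweenness of the
  core in expectation;
* article counts in which true GV genes have an elevated joint-mention
  probability;
* miRNA-target tables planting a configured candidate overlap at
  configured ranks.

Every artifact draws from its own pseudo-random stream derived from the
master seed by a stable label, so regenerating one artifact never
perturbs another.  All outputs are byte-identical across runs at a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .discovery import RankedGeneList
from .errors import InfeasibleConfigError
from .literature import ArticleCounts, write_article_counts
from .mirna import MirnaTargetMap, OrthologMap
from .network import (
    GENERIC_ITYPES,
    REGULATORY_ITYPES,
    AssociativeNetwork,
    GeneNode,
    GeneSet,
    InteractionEdge,
    PhenotypeAssociation,
    _canon,
    write_gene_set,
    write_network,
)

__all__ = [
    "GeneratorConfig",
    "generate_network",
    "generate_article_counts",
    "generate_mirna_targets",
    "write_fixtures",
]

HYPO, HYPER = "hypo", "hyper"

# stream labels (stable across releases; never reorder)
_STREAM_NETWORK = 1
_STREAM_COUNTS = 2
_STREAM_MIRNA = 3
_STREAM_GMT = 4


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study.

    Defaults mirror the real study's proportions: a 37-gene GV core (the
    published intersection size), a handful of upstream regulators, four
    complication phenotypes, and a sparse literature-mined background.
    """

    n_genes: int = 400
    core_size: int = 37
    n_regulators: int = 10
    n_complications: int = 4
    edge_density: float = 0.02
    assoc_noise: float = 0.05
    itype_weights: dict = field(
        default_factory=lambda: {
            "association": 2.0,
            "interaction": 2.0,
            "coexpression": 1.0,
            "regulation": 2.0,
            "upregulation": 1.0,
            "downregulation": 1.0,
            "catalysis": 0.5,
        }
    )
    seed: int = 0
    # complication wiring
    n_complication_genes: int = 40  # non-core members per complication
    p_block: float = 0.05           # intra-block edge probability
    bridge_noise: float = 0.0       # probability of a direct cross-block edge

    def validate(self) -> None:
        if self.core_size + self.n_regulators > self.n_genes:
            raise InfeasibleConfigError(
                "core_size + n_regulators must not exceed n_genes"
            )
        if not (0 < self.edge_density < 1):
            raise InfeasibleConfigError("edge_density must lie in (0, 1)")
        if not (0 <= self.assoc_noise <= 1):
            raise InfeasibleConfigError("assoc_noise must lie in [0, 1]")
        if any(w < 0 for w in self.itype_weights.values()):
            raise InfeasibleConfigError("itype weights must be non-negative")
        unknown = set(self.itype_weights) - (GENERIC_ITYPES | REGULATORY_ITYPES)
        if unknown:
            raise InfeasibleConfigError(f"unknown itypes in weights: {sorted(unknown)}")
        if not any(
            w > 0 for t, w in self.itype_weights.items() if t in REGULATORY_ITYPES
        ):
            raise InfeasibleConfigError(
                "at least one regulatory itype weight must be positive"
            )
        if self.core_size + self.n_complication_genes > self.n_genes:
            raise InfeasibleConfigError("complication membership exceeds gene pool")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _sample_itype(rng: np.random.Generator, weights: dict) -> str:
    types = sorted(t for t, w in weights.items() if w > 0)
    probs = np.array([weights[t] for t in types], dtype=float)
    return types[rng.choice(len(types), p=probs / probs.sum())]


def _sample_regulatory_itype(rng: np.random.Generator, weights: dict) -> str:
    reg = {t: w for t, w in weights.items() if t in REGULATORY_ITYPES and w > 0}
    return _sample_itype(rng, reg)


def generate_network(config: GeneratorConfig) -> tuple[AssociativeNetwork, dict]:
    """Generate an associative network with planted ground truth.

    Returns the network and a truth dict with keys ``core``,
    ``regulators``, ``complications`` (phenotype id -> member/block lists)
    and ``noise_associations``.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_NETWORK)

    symbols = [f"G{i:04d}" for i in range(config.n_genes)]
    core = symbols[: config.core_size]
    regulators = symbols[config.core_size : config.core_size + config.n_regulators]
    pool = symbols[config.core_size + config.n_regulators :]
    core_set = set(core)
    reg_set = set(regulators)

    net = AssociativeNetwork()
    for s in symbols:
        net.add_node(GeneNode(symbol=s))

    # (i) core genes associated with both phenotypes
    for pheno, name in ((HYPO, "hypoglycemia"), (HYPER, "hyperglycemia")):
        for g in core:
            net.add_association(PhenotypeAssociation(pheno, name, g))

    # single-phenotype association noise on background genes
    noise_assoc = []
    for g in pool:
        if rng.random() < config.assoc_noise:
            pheno = HYPO if rng.random() < 0.5 else HYPER
            name = "hypoglycemia" if pheno == HYPO else "hyperglycemia"
            net.add_association(PhenotypeAssociation(pheno, name, g))
            noise_assoc.append([g, pheno])

    def normalized_edge(u: str, v: str, itype: str) -> InteractionEdge:
        """Build a background/structural edge.

        Regulatory types are directed; a directed regulatory edge into a
        core gene from a gene that is neither core nor a planted regulator
        is reversed, so the path search's exact-recovery guarantee holds at
        any seed.
        """
        directed = itype in REGULATORY_ITYPES
        if directed and v in core_set and u not in core_set and u not in reg_set:
            u, v = v, u
        return InteractionEdge(source=u, target=v, itype=itype, directed=directed)

    # (ii) planted regulators: 1-3 directed regulatory edges into the core
    for r in regulators:
        n_out = int(rng.integers(1, 4))
        targets = rng.choice(config.core_size, size=n_out, replace=False)
        for t in targets:
            net.add_edge(
                InteractionEdge(
                    source=r,
                    target=core[int(t)],
                    itype=_sample_regulatory_itype(rng, config.itype_weights),
                    directed=True,
                    source_db="synthetic",
                )
            )

    # (iii) complication phenotypes: core bridges two blocks
    complications: dict[str, dict] = {}
    for ci in range(config.n_complications):
        pheno = f"comp{ci + 1}"
        members = [
            pool[int(i)]
            for i in rng.choice(len(pool), size=config.n_complication_genes, replace=False)
        ]
        half = len(members) // 2
        block_a, block_b = members[:half], members[half:]
        for g in core + members:
            net.add_association(PhenotypeAssociation(pheno, f"complication {ci + 1}", g))

        # random spanning tree over the core keeps it internally connected
        order = rng.permutation(config.core_size)
        for i in range(1, config.core_size):
            u = core[int(order[i])]
            v = core[int(order[int(rng.integers(0, i))])]
            net.add_edge(normalized_edge(u, v, _sample_itype(rng, config.itype_weights)))

        # every block gene hangs off two distinct core genes
        for g in block_a + block_b:
            anchors = rng.choice(config.core_size, size=min(2, config.core_size), replace=False)
            for a in anchors:
                net.add_edge(
                    normalized_edge(g, core[int(a)], _sample_itype(rng, config.itype_weights))
                )

        # sparse intra-block edges; cross-block only with bridge_noise
        for block in (block_a, block_b):
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    if rng.random() < config.p_block:
                        net.add_edge(
                            normalized_edge(
                                block[i], block[j], _sample_itype(rng, config.itype_weights)
                            )
                        )
        for u in block_a:
            for v in block_b:
                if rng.random() < config.bridge_noise:
                    net.add_edge(
                        normalized_edge(u, v, _sample_itype(rng, config.itype_weights))
                    )
        complications[pheno] = {
            "members": core + members,
            "block_a": block_a,
            "block_b": block_b,
        }

    # (iv) background edges by density
    n_pairs = config.n_genes * (config.n_genes - 1) // 2
    n_background = rng.binomial(n_pairs, config.edge_density)
    for _ in range(int(n_background)):
        u, v = rng.choice(config.n_genes, size=2, replace=False)
        net.add_edge(
            normalized_edge(
                symbols[int(u)], symbols[int(v)], _sample_itype(rng, config.itype_weights)
            )
        )

    truth = {
        "seed": config.seed,
        "core": core,
        "regulators": regulators,
        "phenotypes": [HYPO, HYPER],
        "complications": complications,
        "noise_associations": noise_assoc,
    }
    return net, truth


def generate_article_counts(
    genes: "list[str]",
    true_gv: GeneSet,
    config: GeneratorConfig,
    n_total: int = 2_000_000,
    k_gv: int = 4_000,
    effect: float = 5.0,
    mean_log_articles: float = 5.0,
    sigma_log_articles: float = 1.5,
) -> ArticleCounts:
    """Article-count table with elevated joint mentions for true GV genes.

    Per-gene article counts follow a long-tailed log-normal; joint counts
    are binomial with base rate K_gv/N_total, multiplied by ``effect`` for
    true GV genes.  ``effect`` = 1 reproduces the null (uniform p-values).
    """
    if effect <= 0 or k_gv > n_total:
        raise InfeasibleConfigError("infeasible article-count rates")
    rng = _rng(config.seed, _STREAM_COUNTS)
    base = k_gv / n_total
    truth_keys = true_gv.canon()
    rows = []
    for g in genes:
        n_gene = int(np.exp(rng.normal(mean_log_articles, sigma_log_articles)))
        n_gene = min(n_gene, n_total)
        rate = min(1.0, base * (effect if _canon(g) in truth_keys else 1.0))
        k_joint = int(rng.binomial(n_gene, rate))
        k_joint = min(k_joint, k_gv, n_gene)
        rows.append((g, n_gene, k_joint))
    return ArticleCounts(n_total=n_total, k_gv=k_gv, rows=tuple(rows))


def generate_mirna_targets(
    candidates: RankedGeneList,
    overlap_size: int,
    top_k_placement: int,
    config: GeneratorConfig,
    n_targets: int = 69,
    n_mirnas: int = 16,
    n_empty_mirnas: int = 4,
) -> tuple[list[str], MirnaTargetMap, OrthologMap]:
    """miRNA-target and ortholog tables planting a candidate overlap.

    Exactly ``overlap_size`` candidate genes, all ranked within the top
    ``top_k_placement``, appear among the ``n_targets`` rat target genes;
    the remainder are non-candidate padding.  A consistent rat-to-human
    ortholog map covers every target.  The returned miRNA list includes
    ``n_empty_mirnas`` identifiers absent from the target map.
    """
    if overlap_size > top_k_placement:
        raise InfeasibleConfigError("overlap_size exceeds top_k_placement")
    if top_k_placement > len(candidates):
        raise InfeasibleConfigError("top_k_placement exceeds the ranking length")
    if overlap_size > n_targets:
        raise InfeasibleConfigError("overlap_size exceeds n_targets")
    rng = _rng(config.seed, _STREAM_MIRNA)

    top_genes = [g for rank, g, _ in candidates.entries if rank <= top_k_placement]
    picked = [top_genes[int(i)] for i in rng.choice(len(top_genes), size=overlap_size, replace=False)]
    cand_keys = {_canon(g) for g in candidates.genes}
    padding = [f"PAD{i:03d}" for i in range(n_targets - overlap_size)]
    assert not any(_canon(p) in cand_keys for p in padding)
    human_targets = picked + padding

    # rat symbols: capitalized-lowercase convention
    rat_of = {h: h.capitalize() + "r" for h in human_targets}
    ortho_rows = tuple(
        (rat_of[h], "Rattus norvegicus", h) for h in sorted(human_targets)
    )

    mirnas = [f"rno-miR-{100 + i}" for i in range(n_mirnas)]
    empty = [f"rno-miR-{900 + i}" for i in range(n_empty_mirnas)]
    target_rows = []
    for i, h in enumerate(human_targets):
        m = mirnas[i % n_mirnas]
        target_rows.append((m, rat_of[h], "Rattus norvegicus"))
    # give some miRNAs extra shared targets so unions deduplicate
    for i in range(min(5, len(human_targets))):
        target_rows.append(
            (mirnas[(i + 1) % n_mirnas], rat_of[human_targets[i]], "Rattus norvegicus")
        )

    return (
        mirnas + empty,
        MirnaTargetMap.from_rows(target_rows),
        OrthologMap(ortho_rows),
    )


def generate_annotation(
    genes: "list[str]",
    core: "list[str]",
    config: GeneratorConfig,
    n_terms: int = 20,
) -> dict:
    """Synthetic GMT-style annotation: one term enriched in the planted
    core plus random terms, for exercising the enrichment stage."""
    rng = _rng(config.seed, _STREAM_GMT)
    annotation: dict = {}
    n_core_members = max(2, int(0.6 * len(core)))
    core_members = [core[int(i)] for i in rng.choice(len(core), size=n_core_members, replace=False)]
    extra = [genes[int(i)] for i in rng.choice(len(genes), size=5, replace=False)]
    annotation["T0000"] = (
        "planted core process",
        GeneSet.from_iterable(core_members + extra, "T0000"),
    )
    for t in range(1, n_terms):
        size = int(rng.integers(10, 51))
        members = [genes[int(i)] for i in rng.choice(len(genes), size=size, replace=False)]
        annotation[f"T{t:04d}"] = (
            f"random process {t}",
            GeneSet.from_iterable(members, f"T{t:04d}"),
        )
    return annotation


def write_fixtures(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Generate and write every fixture table plus a truth.json label file.

    Produces the network TSVs, GV core and regulator gene-set files, an
    article-count table, a synthetic term annotation (GMT), miRNA-target
    and ortholog tables consistent with the network's own candidate
    ranking, and a ready-to-run pipeline config; returns the truth dict.
    """
    from .discovery import find_candidates, prioritize_baseline
    from .mirna import MirnaTargetMap  # noqa: F401  (re-exported types)
    from .stats import write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth = generate_network(config)
    write_network(net, out / "nodes.tsv", out / "edges.tsv", out / "associations.tsv")
    core_set = GeneSet.from_iterable(truth["core"], "gv_core")
    write_gene_set(core_set, out / "gv_core.txt")
    write_gene_set(
        GeneSet.from_iterable(truth["regulators"], "regulators"), out / "regulators.txt"
    )

    genes = sorted(net.gene_symbols)
    # literature enrichment holds for every genuinely GV-involved gene:
    # the core and its planted upstream regulators
    true_gv = GeneSet.from_iterable(truth["core"] + truth["regulators"], "true_gv")
    counts = generate_article_counts(genes, true_gv, config)
    write_article_counts(counts, out / "counts.tsv")

    write_gmt(generate_annotation(genes, truth["core"], config), out / "terms.gmt")

    # miRNA tables consistent with the network's own candidate ranking
    candidates, _ = find_candidates(net, HYPO, HYPER, core_set)
    ranking = prioritize_baseline(candidates, core_set, net)
    overlap = min(5, len(candidates))
    placement = min(100, len(candidates))
    mirnas, tmap, omap = generate_mirna_targets(
        ranking, overlap, placement, config,
        n_targets=max(overlap, min(69, 2 * len(candidates))),
    )
    (out / "de_mirnas.txt").write_text("\n".join(mirnas) + "\n")
    _write_tsv(
        out / "mirna_targets.tsv",
        ["mirna_id", "target_gene", "species"],
        tmap.rows,
    )
    _write_tsv(
        out / "orthologs.tsv",
        ["source_gene", "source_taxon", "human_gene"],
        omap.rows,
    )

    # paths are relative to the fixture directory; PipelineConfig.from_yaml
    # resolves them against the YAML's location
    pipeline_cfg = {
        "nodes": "nodes.tsv",
        "edges": "edges.tsv",
        "associations": "associations.tsv",
        "phenotype_hypo": HYPO,
        "phenotype_hyper": HYPER,
        "complications": sorted(truth["complications"]),
        "gmt": "terms.gmt",
        "counts": "counts.tsv",
        "mirnas": "de_mirnas.txt",
        "mirna_targets": "mirna_targets.tsv",
        "orthologs": "orthologs.tsv",
        "population_size": 20000,
        "top_ks": sorted({min(50, len(candidates)), min(100, len(candidates))}),
        "seed": config.seed,
        "out_dir": "results",
    }
    import yaml

    (out / "pipeline.yaml").write_text(yaml.safe_dump(pipeline_cfg, sort_keys=True))
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2, sort_keys=True))
    return truth


def _write_tsv(path: Path, columns: "list[str]", rows) -> None:
    lines = ["\t".join(columns)] + ["\t".join(map(str, r)) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n")
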