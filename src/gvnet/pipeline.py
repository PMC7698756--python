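"""End-to-end pipeline: chain every analysis stage on fixture or user data.

The nine stages, in order: phenotype subnetworks, GV intersection,
connection ranking, per-complication centrality reports, candidate
discovery, prioritization, GO-style term enrichment, literature
co-occurrence statistics, and miRNA-target validation.  Each stage writes
one TSV; a machine-readable summary.json collects the headline numbers.
All randomness flows from the single declared seed, which is recorded in
the summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import centrality as cen
from . import discovery as disc
from . import literature as lit
from . import mirna as mir
from . import network as netmod
from . import stats as st
from .errors import GvnetError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All knobs of a full pipeline run."""

    nodes: str
    edges: str
    associations: str
    phenotype_hypo: str = "hypo"
    phenotype_hyper: str = "hyper"
    complications: list[str] = field(default_factory=list)
    gv_set: str | None = None          # path; default: computed intersection
    gmt: str | None = None
    counts: str | None = None
    mirnas: str | None = None
    mirna_targets: str | None = None
    orthologs: str | None = None
    external_ranking: str | None = None
    background_size: int | None = None  # default: loaded network size
    population_size: int = 20_000
    top_ks: list[int] = field(default_factory=lambda: [50, 100])
    fdr: float = 0.05
    centrality_test: str = "mannwhitney"
    seed: int = 0
    out_dir: str = "gvnet_out"

    def validate(self) -> None:
        if not (0 < self.fdr <= 1):
            raise GvnetError("fdr threshold must lie in (0, 1]")
        required = {"nodes": self.nodes, "edges": self.edges, "associations": self.associations}
        optional = {
            "gv_set": self.gv_set,
            "gmt": self.gmt,
            "counts": self.counts,
            "mirnas": self.mirnas,
            "mirna_targets": self.mirna_targets,
            "orthologs": self.orthologs,
            "external_ranking": self.external_ranking,
        }
        for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(path).exists():
                raise GvnetError(f"config file for {name!r} does not exist: {path}")

    _PATH_FIELDS = (
        "nodes", "edges", "associations", "gv_set", "gmt", "counts",
        "mirnas", "mirna_targets", "orthologs", "external_ranking", "out_dir",
    )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config; relative paths resolve against the YAML's directory."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise GvnetError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).resolve().parent
        for key in cls._PATH_FIELDS:
            value = raw.get(key)
            if value and not Path(value).is_absolute():
                raw[key] = str(base / value)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage(summary: dict, name: str, block: dict) -> None:
    # strip numpy scalar types so the summary is plain JSON everywhere
    block = json.loads(json.dumps(block, default=_json_default))
    summary[name] = block
    logger.info("stage %-16s %s", name, {k: v for k, v in block.items() if not isinstance(v, list)})


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the summary dict.

    Raises GvnetError with the stage name on any failure; stage outputs are
    flat TSV files so each downstream stage can be re-run in isolation.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    def fail(stage: str, exc: Exception):
        raise GvnetError(f"stage {stage!r} failed: {exc}") from exc

    # 1. phenotype subnetworks
    try:
        net = netmod.load_network(config.nodes, config.edges, config.associations)
        sub_hypo = netmod.phenotype_subnetwork(net, config.phenotype_hypo)
        sub_hyper = netmod.phenotype_subnetwork(net, config.phenotype_hyper)
        _stage(summary, "subnetworks", {
            "hypo_genes": sub_hypo.n_nodes(), "hypo_interactions": sub_hypo.n_edges(),
            "hyper_genes": sub_hyper.n_nodes(), "hyper_interactions": sub_hyper.n_edges(),
        })
    except Exception as exc:
        fail("subnetworks", exc)

    # 2. GV intersection
    try:
        if config.gv_set:
            gv = netmod.read_gene_set(config.gv_set, label="gv")
        else:
            gv = netmod.intersect_phenotypes(net, config.phenotype_hypo, config.phenotype_hyper)
        netmod.write_gene_set(gv, out / "gv_genes.txt")
        _stage(summary, "intersection", {"n_gv_genes": len(gv)})
    except Exception as exc:
        fail("intersection", exc)

    # 3. connection ranking inside the GV subnetwork
    try:
        gv_net = netmod.AssociativeNetwork()
        for g in gv:
            gv_net.add_node(net.resolve(g))
        keys = gv.canon()
        gv_net.edges = [
            e for e in net.edges
            if netmod._canon(e.source) in keys and netmod._canon(e.target) in keys
        ]
        ranking_df = netmod.connection_counts(gv_net)
        ranking_df.to_csv(out / "connection_counts.tsv", sep="\t", index=False)
        top = ranking_df.iloc[0]
        _stage(summary, "connection_ranking", {
            "top_gene": str(top["gene"]), "top_count": int(top["count"]),
            "n_rows": len(ranking_df),
        })
    except Exception as exc:
        fail("connection_ranking", exc)

    # 4. centrality reports for each complication
    try:
        background = config.background_size or net.n_nodes()
        reports = [
            cen.complication_report(net, pheno, gv, background) for pheno in config.complications
        ]
        rep_df = pd.DataFrame([r.as_dict() for r in reports])
        rep_df.to_csv(out / "centrality_reports.tsv", sep="\t", index=False)
        _stage(summary, "centrality", {
            "reports": [r.as_dict() for r in reports], "background_size": background,
        })
    except Exception as exc:
        fail("centrality", exc)

    # 5. candidate discovery
    try:
        candidates, paths = disc.find_candidates(
            net, config.phenotype_hypo, config.phenotype_hyper, gv
        )
        netmod.write_gene_set(candidates, out / "candidates.txt")
        pd.DataFrame(
            [
                (p.phenotype_a, p.gene2, p.gene3, p.gene4, p.phenotype_b,
                 p.edge23.itype, p.edge34.itype)
                for p in paths
            ],
            columns=["phenotype_a", "gene2", "gene3", "gene4", "phenotype_b",
                     "itype23", "itype34"],
        ).to_csv(out / "candidate_paths.tsv", sep="\t", index=False)
        _stage(summary, "candidates", {"n_candidates": len(candidates), "n_paths": len(paths)})
    except Exception as exc:
        fail("candidates", exc)

    # 6. prioritization
    try:
        if config.external_ranking:
            ranking = disc.load_ranking(config.external_ranking, candidates)
        else:
            ranking = disc.prioritize_baseline(candidates, gv, net)
        ranking.to_frame().to_csv(out / "ranked_candidates.tsv", sep="\t", index=False)
        _stage(summary, "prioritization", {
            "n_ranked": len(ranking), "best_gene": ranking.entries[0][1],
            "best_score": ranking.entries[0][2],
        })
    except Exception as exc:
        fail("prioritization", exc)

    # 7. term enrichment of the GV set
    try:
        if config.gmt:
            annotation = st.read_gmt(config.gmt)
            bg = netmod.GeneSet.from_iterable(net.gene_symbols, "background")
            results = st.term_enrichment(gv, annotation, bg)
            pd.DataFrame(
                [(r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p, r.p_adj, r.p_adj < config.fdr)
                 for r in results],
                columns=["term_id", "term_name", "k", "K", "n", "N", "p", "p_adj", "significant"],
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            n_sig = sum(r.p_adj < config.fdr for r in results)
            _stage(summary, "enrichment", {"n_terms_tested": len(results), "n_significant": n_sig})
        else:
            _stage(summary, "enrichment", {"skipped": "no GMT annotation provided"})
    except Exception as exc:
        fail("enrichment", exc)

    # 8. literature co-occurrence
    try:
        if config.counts:
            counts = lit.read_article_counts(config.counts)
            table = lit.cooccurrence_table(counts)
            pd.DataFrame(
                [(r.gene, r.n_gene, r.k_joint, r.p, r.p_adj) for r in table],
                columns=["gene", "n_gene", "k_joint", "p", "p_adj"],
            ).to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
            have = {netmod._canon(r.gene) for r in table}
            covered = [g for g in ranking.genes if netmod._canon(g) in have]
            block = {"n_genes_tested": len(table)}
            if len(covered) == len(ranking):
                rho, p = lit.rank_probability_correlation(ranking, table)
                block.update({"spearman_rho": rho, "spearman_p": p})
            else:
                block["spearman"] = "skipped: counts do not cover the ranking"
            _stage(summary, "literature", block)
        else:
            _stage(summary, "literature", {"skipped": "no article-count table provided"})
    except Exception as exc:
        fail("literature", exc)

    # 9. miRNA-target validation
    try:
        if config.mirnas and config.mirna_targets and config.orthologs:
            mirnas = [
                line.strip() for line in Path(config.mirnas).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            ]
            tmap = mir.read_mirna_targets(config.mirna_targets)
            omap = mir.read_orthologs(config.orthologs)
            rat_targets, no_target = mir.targets_of_mirnas(mirnas, tmap)
            human_targets = mir.map_orthologs(rat_targets, omap)
            report = mir.validate_candidates(
                candidates, ranking, human_targets, config.population_size, config.top_ks
            )
            block = report.as_dict()
            block["n_mirnas_without_targets"] = len(no_target)
            _stage(summary, "mirna_validation", block)
        else:
            _stage(summary, "mirna_validation", {"skipped": "miRNA tables not provided"})
    except Exception as exc:
        fail("mirna_validation", exc)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default))
    return summary
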