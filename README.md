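# gvnet

Network analysis of **glucose variability (GV)** — the swings between
hyperglycemia and hypoglycemia that accompany diabetes and promote its
complications. Because no molecular data measure GV directly, the package
operationalizes GV genes as the genes associated with *both* hyperglycemia
and hypoglycemia in a literature-mined associative gene network, then asks
three questions a systems biologist would ask of that gene set:

1. **Are GV genes central to diabetes-complication networks?**
   Betweenness centrality of each gene in the complication subnetwork,
   a hypergeometric test for overrepresentation of GV genes among the
   network's participants, and a one-sided Mann–Whitney test for elevation
   of their centrality.
2. **Which genes regulate GV without being directly linked to it?**
   A typed, directed length-4 path search
   `phenotype ← GV gene ← candidate → GV gene → phenotype`: the candidate
   must regulate phenotype-linked intermediaries through directed,
   non-generic interactions (generic types — association, coexpression,
   expression, interaction, involvement — never count as regulation) and
   must itself have no direct association with either phenotype.
3. **Do independent data support the candidates?** Literature
   co-occurrence statistics (hypergeometric tails over article counts, BH
   FDR, Spearman correlation of prioritization rank against co-occurrence
   probability) and enrichment of the candidate list for targets of
   differentially expressed miRNAs, mapped from rat to human orthologs.

Every overrepresentation statistic in the pipeline is the upper tail of a
hypergeometric distribution: with a universe of `N` items of which `K` are
marked and a sample of `n`, the probability of observing an overlap of at
least `k` is

```
P(X ≥ k) = Σ_{j≥k} C(K, j) · C(N−K, n−j) / C(N, n).
```

The package is aimed at researchers reproducing or extending this style of
text-mined network analysis: all inputs are plain TSV/GMT tables, a seeded
synthetic-data generator plants recoverable ground truth for every stage,
and each statistical kernel is exposed as a plain function.

## Worked example

Generate a synthetic study (37-gene GV core, 10 planted upstream
regulators, 4 complication networks where the core bridges two blocks) and
run the whole pipeline:

```bash
gvnet simulate --out-dir demo --seed 7
gvnet run-all --config demo/pipeline.yaml
```

The summary (`demo/results/summary.json`) reports, among others:

```
intersection        {"n_gv_genes": 37}
candidates          {"n_candidates": 10, "n_paths": 38}
centrality (comp1)  {"n_participants": 77, "n_gv_genes": 37,
                     "mean_centrality_all": 48.5, "mean_centrality_gv": 84.9,
                     "p_overrepresentation": 5.3e-31,
                     "p_centrality_difference": 8.3e-13}
mirna_validation    {"overlap": 5, "p_overall": 1.5e-13}
```

Reading these numbers: the intersection of the hypo- and hyperglycemia
subnetworks recovers exactly the 37 planted core genes; the path search
recovers exactly the 10 planted regulators (via 38 witnessing paths); in
the first complication network the planted bridge wiring gives the GV
genes nearly double the average betweenness of the network at large
(84.9 vs 48.5, Mann–Whitney p ≈ 8×10⁻¹³); and the 5 candidate genes
planted as miRNA targets make the candidate–target overlap wildly
non-random against a 20,000-gene universe.

Each stage is also a standalone subcommand (`gvnet intersect`,
`gvnet candidates`, `gvnet centrality-report`, `gvnet enrich`,
`gvnet litco`, `gvnet mirna-validate`, …) operating on the same TSV
formats; see `gvnet --help`.

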