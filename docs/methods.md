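# Methods

## The data model

An *associative gene network* is a set of gene/protein nodes, a multiset
of typed gene–gene interaction records, and a separate table of
phenotype–gene associations. Three conventions matter throughout:

- **Multi-edges are records, not redundancy.** Text-mined interaction
  databases report one row per extraction (type, direction, source
  database, PMIDs); two rows between the same pair are independent
  evidence. Connection counts therefore count records — a hub inside a
  37-gene subnetwork can legitimately have 59 connections.
- **Generic vs regulatory types.** The controlled vocabulary splits into
  five generic types (`association`, `coexpression`, `expression`,
  `interaction`, `involvement`), always stored undirected, and seven
  regulatory/biochemical types (`regulation`, `up-`/`downregulation`,
  `catalysis`, `transport`, `cleavage`, `degradation`) that may carry a
  direction. Everything that asks "does A regulate B?" ignores generic
  types entirely.
- **Symbols are matched case-insensitively, stored case-preserved**,
  because literature-derived sources mix `Ins`/`INS`/`ins`. Phenotype
  associations live outside the gene–gene edge multiset so graph
  algorithms stay purely molecular.

Self-loops are rejected at load: the networks describe inter-molecular
relations, and a self-loop is almost always an extraction artifact.

## Centrality analysis

Betweenness is computed on the **simple undirected graph** obtained by
collapsing multi-edges and dropping direction. The mixture of directed and
undirected edge types in these networks makes any directed reading
arbitrary; collapsing is the conservative choice. Values are
**unnormalized** Brandes betweenness (raw shortest-path counts, endpoints
excluded, fractional credit across equal-length geodesics, each unordered
pair counted once), which is the scale on which such network reports print
values in the hundreds or thousands.

Two statistics summarize a complication network against a GV gene set:

- *Overrepresentation*: upper-tail hypergeometric probability of the
  observed GV-gene count among the network's participants. The background
  universe defaults to the loaded network's gene count and is
  configurable — the "right" universe (the whole knowledge base the
  network was extracted from) is usually not available.
- *Centrality elevation*: one-sided Mann–Whitney U, testing whether GV
  genes' betweenness values are stochastically greater than those of the
  remaining participants. The rank basis is deliberate: betweenness is
  heavy-tailed, so a t-test would be dominated by the largest hub. For
  combined sample sizes ≤ 12 the p-value is permutation-exact (enumeration
  of all subset assignments of the pooled values, tie-safe); above that, a
  normal approximation with tie correction. Since both interpretations of
  "number of interactions" are defensible, the report emits both the
  record count and the collapsed pair count.

## Candidate discovery

A candidate is the middle gene (slot 3) of a 5-slot chain
`phenotype_A — g2 — c — g4 — phenotype_B` in which:

- `g2` and `g4` are drawn from a supplied intermediary set (the GV genes)
  and are associated with phenotype A resp. B;
- both inner edges are **directed out of the candidate** (`c→g2`, `c→g4`)
  and carry a non-generic type — the candidate regulates the
  intermediaries, not vice versa;
- the phenotype–gene links at the two ends accept any association;
- `c` itself has **no direct association with either phenotype** (that
  exclusion is the point: candidates are indirectly implicated genes).

Because every GV gene is associated with both phenotypes, `g2 = g4` is
allowed by default; `require_distinct_intermediaries` enables the stricter
reading. Intermediary genes themselves are excluded from the candidate
slot by default (they are phenotype-associated anyway whenever the
intermediaries are the GV genes); `allow_intermediary_candidates` lifts
the explicit exclusion for non-associated intermediary sets. All
witnessing paths are returned, deduplicated on the full
(gene2, gene3, gene4, edge, edge) tuple.

`regulated_genes` applies the same edge semantics to a one-hop question:
genes in scope with at least one incoming directed non-generic edge from a
regulator.

### Prioritization

External multi-evidence prioritizers are web services with opaque feature
fusion; the package instead ships a transparent guilt-by-association
baseline: `score(c)` = fraction of training genes adjacent to `c` by any
edge record. It is deterministic (ties break alphabetically), and any
externally produced ranking can be supplied as a TSV and validated against
the candidate set, keeping the downstream statistics identical.

## Enrichment and validation statistics

All overrepresentation tests are upper-tail hypergeometric probabilities,
evaluated by `scipy.stats.hypergeom.sf` (log-space internals keep
literature-scale populations of 10⁶⁺ articles stable). Multiple testing
uses Benjamini–Hochberg step-up FDR. Term enrichment intersects every term
with the background before testing and by default excludes zero-overlap
terms from both the test and the BH family, mirroring the convention of
reporting only represented terms; a flag reverses this.

The **top-k membership test** treats a ranking of `n` candidates as the
population, the top `k` positions as marked, and the validated genes as
the draw: `P(X ≥ m)` is the chance that at least `m` of them land that
high by luck. At the published scale (334 candidates, 5 validated genes,
all in the top 100, 3 in the top 50; 69 targets in a 20,000-gene universe)
the three statistics round to 0.002, 0.03 and 0.006 at one significant
digit.

The universe for the overall candidate–target overlap test is **not
derivable from the data**; the default of 20,000 (approximate human
protein-coding gene count) is a declared assumption, exposed as
`--population-size`.

**Literature co-occurrence**: for each gene, `P(X ≥ k_joint)` with the
corpus as population, GV-mentioning articles as marked, and the gene's
articles as the draw. A gene with no articles scores p = 1 (absence of
mentions is vacuous, not evidence). The Spearman correlation between
prioritization rank (1 = best) and the *raw* co-occurrence probability
validates a ranking: positive rho means better-ranked genes have stronger
literature support. Raw rather than FDR-adjusted probabilities are
correlated (adjustment is monotone within a family but flattens ties);
`use_adjusted` switches. Rank direction is easy to silently invert, hence
the explicit convention. Significance uses the large-sample t
approximation for n > 10 and exact permutation enumeration below
(vectorised; 10! permutations take under a second). The 13 GV query
phrases used to define the corpus's marked set ship as the documented
constant `GV_QUERY_TERMS`.

**miRNA validation** chains three steps: union of target genes over the
differentially expressed miRNAs (miRNAs absent from the target map are
reported, not errors), ortholog translation with silent-but-logged
dropping of unmapped genes, and the overall + top-k tests above.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
not the biology. Planted structure and what it guarantees:

- **GV core** (default 37 genes, the published intersection size):
  associated with both `hypo` and `hyper`; phenotype intersection recovers
  it exactly at any noise level, because association noise adds
  *single*-phenotype associations only (probability `assoc_noise` = 0.05
  per background gene).
- **Regulators** (default 10): 1–3 directed regulatory edges into the
  core, no phenotype associations. The path search recovers exactly this
  set at `assoc_noise = 0`: any background edge that would fake the
  pattern (directed regulatory into a core gene from an unassociated
  non-regulator) is reversed at generation, making the guarantee hold for
  every seed, not just in expectation.
- **Complication networks** (default 4 × 40 non-core members plus the
  core): each complication's non-core members split into two blocks wired
  only *through* the core (each block gene hangs off two core genes; the
  core carries an internal spanning tree; intra-block edges appear with
  probability 0.05, direct cross-block edges with probability
  `bridge_noise` = 0). Every cross-block geodesic passes through core
  genes, which elevates their betweenness by construction.
- **Article counts**: per-gene counts are log-normal
  (`exp(N(5, 1.5))`, a long-tailed literature distribution with median
  ≈ 150 articles) against a corpus of 2,000,000 articles of which 4,000
  mention GV; joint mentions are binomial at the base rate times
  `effect` = 5 for truly GV-involved genes. The fivefold enrichment is
  the smallest round factor that reproduces a rank–probability dependence
  of the magnitude the analysis is designed to detect (rho ≈ 0.3 at
  n = 300); at `effect` = 1 the p-values are valid (super-uniform — the
  discrete tails put an atom at p = 1, so they are *not* uniform).
- **miRNA tables**: exactly `overlap_size` candidates planted as targets
  within the top `top_k_placement` ranks, padded with non-candidate
  targets, plus a consistent rat→human ortholog map and a configurable
  number of miRNAs absent from the target map.

Each artifact draws from its own PRNG stream derived from the master seed
by a stable label, so regenerating one artifact never perturbs another;
all outputs are byte-identical at a fixed seed.

What the generator does **not** emulate: real symbol vocabularies,
scale-free degree structure, correlated extraction errors, literature
growth dynamics, or miRNA seed-match biology. Passing recovery tests shows
the pipeline implements its definitions correctly under the planted
statistical structure — not that the definitions find true biology in
real networks.

## Numerical and degenerate-input choices

- Hypergeometric tails return exactly 1 at k = 0; inconsistent counts
  (k > min(K, n), K > N, n > N) raise a dedicated error.
- Ties: connection counts and rankings break ties by symbol ascending;
  Mann–Whitney assigns half-wins; Spearman uses average ranks.
- A GV set disjoint from a complication network yields a defined report
  (0 GV genes, both p-values 1) rather than an error; an empty phenotype
  intersection warns but returns the empty set.
- The exact/asymptotic switch for the Mann–Whitney test sits at combined
  n = 12, where the two branches agree within 0.02 on tie-free data.
- BH-adjusted p-values are capped at 1 and never fall below raw p.

## Problem sizes

Default simulated studies use 400 genes, which makes every pipeline stage
(including betweenness on all four 77-node complication subnetworks and
the 400-gene co-occurrence table) complete in seconds while keeping all
planted-recovery guarantees; the oracle tests run on graphs of ≤ 12 nodes
(exact enumeration) and typed networks of ≤ 50 nodes (path enumeration),
where brute force is itself exact.

## Known limitations

- The published absolute network sizes and centrality tables derive from a
  proprietary text-mining knowledge base and live literature counts;
  without those inputs the package validates its statistics against
  enumeration oracles and planted synthetic structure instead.
- Centrality ignores edge direction and multiplicity; directed or
  evidence-weighted variants are out of scope.
- The enrichment module does no GO-graph propagation; terms are flat gene
  sets.
- Entity normalization (protein vs gene, synonyms) is assumed done
  upstream; matching is by case-insensitive symbol only.
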