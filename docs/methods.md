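# Methods

## Model and assumptions

The package treats disease-module discovery as evidence integration over a
fixed interactome, not as subgraph search: the module is *defined* as the
set of proteins supported by at least two of four independent evidence
streams, and the network only supplies its induced edges. This mirrors the
interactome-medicine view that disease proteins cluster in a connected
neighborhood of the PPIN. Assumptions worth making explicit:

* The interactome is undirected and unweighted; evidence class (binary Y2H
  vs. co-complex) is carried on records but pooled by default, since curated
  physical-interaction sources mix both. A `binary_only` switch restricts
  assembly to binary records.
* Seed genes are taken as ground-truth disease anchors. Seed selection is
  deliberately sharp: GWAS *p* strictly below 5×10⁻⁸, or an OMIM entry with
  a molecular-association flag. OMIM rows without the flag never qualify.
* LD is estimated from phased haplotypes only (no genotype EM phase
  inference); fine-mapping treats the gene body as the locus (a `flank`
  option pads it symmetrically).
* The coexpression criterion ("mutual top-1% rank") is defined relative to
  whatever expression matrix is supplied. Against a single matrix the ranks
  are an analogue — not a replica — of ranks from large precomputed
  coexpression compendia.

## Thresholds and parameters

All thresholds live in `PipelineConfig`, are echoed into every report, and
are frozen by unit tests with their exact comparison semantics:

| parameter | default | semantics |
|---|---|---|
| `seed_p_threshold` | 5e-8 | strict `<` |
| `finemap_p_max` | 1e-3 | inclusive `<=` |
| `proxy_r2` | 0.8 | inclusive, proxy window 500 kb per side |
| `min_interactors` | 3 | distinct seeds, per gene (and per compartment term) |
| `min_coexpressed_seeds` / `min_shared_seeds` | 3 | distinct seeds |
| `top_fraction` | 0.01 | top list size `ceil(f*(G-1))`, boundary ties included |
| `gps_min_differential` | 1.0 | inclusive `>=` on score − cutoff |
| `networkin_min_score` | 2.0 | strict `>` |
| `enrichment_alpha` | 0.05 | on BH-adjusted p |
| tiers | high ≥ 3, moderate = 2 | of 4 streams |
| `n_reiterations` | 10 000 | randomization draws |

The proxy r² threshold, the 500 kb window, the enrichment alpha and the
overlap-test universe size (20 000, protein-coding-genome scale) are
community conventions exposed in config rather than quantities with a single
defensible value; reports carry them so results are interpretable.

## Statistics

* **Enrichment / overlap**: upper-tail hypergeometric probability
  P(X ≥ k) via `scipy.stats.hypergeom.sf`, validated in tests against
  direct combinatorial summation to 1e-12. BH adjustment via statsmodels
  `fdr_bh`, validated against hand-evaluated step-up cases. Terms are used
  as given — no GO-DAG ancestor propagation; the annotation universe
  defaults to all annotated genes.
* **LD**: D = p_AB − p_A p_B from haplotype frequencies; r² and D′ with the
  standard D_max convention and D′ = 0 at D = 0. Monomorphic SNPs are an
  error (named in the message); allele relabeling invariance is tested.
  `ld_blocks` is a greedy all-pairs D′ ≥ 0.98 partition — a documented
  simplified surrogate for the Gabriel confidence-interval method, used for
  descriptive block structure only (fine-mapping never depends on it).
* **Randomization test**: uniform k-subsets without replacement from the
  network's sorted node list, statistic ∈ {induced_edges, expansion_nodes,
  expansion_edges} computed on a boolean adjacency matrix; all three are
  reported, `induced_edges` is the headline statistic. The empirical p uses
  the add-one (Davison–Hinkley) estimator, so p ≥ 1/(N+1) and a claim like
  "p < 0.0049" is bounded by the draw count. Tests verify agreement with
  exhaustive subset enumeration within 3σ and calibration (fraction of
  uniform null modules with p ≤ 0.05 ≈ 0.05).
* **Centrality**: networkx betweenness (unnormalized by default; both
  variants exposed since hub-ranking tools differ), validated against an
  independent all-simple-paths enumeration oracle on small graphs. Hub
  ranking breaks ties by the co-metric, then lexicographically, so output is
  total and reproducible.

## Reproducibility

One top-level seed drives everything. Per-stage RNG streams are derived via
`SeedSequence(seed, spawn_key=crc32(stage_name))`, so a stage can be rerun
in isolation and still match a full run. All set-valued outputs are emitted
in sorted order; reports contain no timestamps. Identical config + seed
yields byte-identical edge lists, null distributions and reports (tested).

## The synthetic scenario

The generator plants every signal the pipeline is supposed to find, at
desk-scale magnitudes comparable to the motivating study (600 genes, 180
seeds, 90-gene module):

* **Network**: Barabási–Albert background (m = 2) for a heavy-tailed degree
  distribution; the module wired internally at density 0.08; every member
  wired to 3–5 "anchor" seeds; two module kinases upgraded to global hubs;
  a sprinkle of self-pairs, duplicate orientations and exclusion-list
  partners that the assembly stage must clean.
* **Associations**: seeds draw p from 10^U(−20, −7.3) or carry OMIM tags;
  30 module genes get sub-threshold signals in (10⁻⁶, 10⁻³]; background
  genes draw null p-values from U(0.05, 1).
* **Haplotypes**: 40 LD blocks of 8 SNPs (2000 haplotypes), each block a
  founder 0/1 assignment copied with flip rate ε = (1 − r²_target^¼)/2 so
  within-block r² ≈ 0.9 while blocks are independent. Signal-block index
  SNPs sit *outside* the planted gene body, so fine-mapping must traverse
  LD proxies; null blocks overlap control loci.
* **Expression**: planted coexpression groups of 3 candidates + 3 seeds
  sharing a latent factor (ρ = 0.9), emitted on a positive log-normal-like
  scale. Group size is deliberately one less than the default top-1% list
  (⌈0.01·599⌉ = 6), the largest clique whose members can all be mutually
  top-ranked — larger planted groups would compete for top-list slots and
  make mutual rank an unreliable read-out of a planted signal.
* **Auxiliary**: one planted compartment term containing exactly the anchor
  seeds (strongly enriched among seeds; every gene also gets 1–3 decoy
  terms); one regulator set per coexpression group plus decoy sets with < 3
  seeds; category-1 flags on 15 fine-mapped module genes and noise
  categories elsewhere; kinase rows mixing confirmable above-threshold,
  below-threshold and off-network predictions.

Ground truth exports per-stream expected gene sets, so each evidence module
is testable in isolation.

**What passing tests do and do not show.** The generator plants clean,
separable signals: module wiring guarantees the proximity and colocalization
streams, LD blocks are internally exchangeable, and coexpression groups are
disjoint. Real data have correlated pathologies the scenario does not
emulate — ascertainment bias in interaction databases, population structure
in LD panels, batch effects in expression, annotation incompleteness.
Recovery of the planted module (precision/recall ≥ 0.9 across seeds)
validates the *machinery*, not the biological error rate on real inputs.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive throughout (the loci reader documents its
divergence from 0-based half-open BED via the `start_1based` header).
Constant-expression genes are dropped from correlation with a logged
warning; index SNPs absent from the panel are skipped with a summary
warning; an empty interaction file parses to an empty record list; an empty
module skips the randomization test. Correlation defaults to Pearson on
log1p values (Spearman selectable; recorded in report metadata). Ortholog
mapping under `best_score` breaks score ties lexicographically.

## Problem sizes

Default test-suite runs use the scaled-down scenario (160 genes, 48 seeds,
26-gene module, 500 haplotypes) with a proportionally larger `top_fraction`
(0.04) so planted coexpression groups still fit one top list; the
acceptance analyses use the full default scenario with 10 000 randomization
draws. Both complete in seconds on one CPU.

## Known limitations

* The colocalization stream takes the seed set present in the interaction
  records; seeds absent from the network cannot contribute interactors.
* No optimization-based module search (DIAMOnD, Steiner trees) — module
  membership is purely evidence-defined, by design.
* No live database clients; all external resources are consumed as tables.
* `ld_blocks` is descriptive, not a calibrated Gabriel implementation.
* Betweenness normalization choice of the original hub-ranking tooling is
  unknowable from published descriptions; both raw and normalized values
  are exposed and the default (raw) is stated in the report.
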