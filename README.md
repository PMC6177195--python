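# ppimod — disease-module discovery in protein interaction networks

`ppimod` implements a candidate-gene / disease-module analysis of the kind
used to place a complex-trait risk architecture (here modeled on type 2
diabetes) onto a physical protein–protein interaction network (PPIN). It is
aimed at systems-biology researchers who have (i) an interaction table
assembled from curated databases, (ii) a gene↔trait association table
(GWAS + OMIM), and (iii) supporting molecular data — compartment
annotations, phased haplotypes, an expression matrix, regulator target sets
and kinase–substrate predictions — and want a tested, reproducible path from
those tables to a statistically validated disease module.

## Method

1. **Interactome assembly.** Interaction records (TSV or SIF) are
   normalized to HUGO-style symbols; nonspecific partners (chaperones,
   ribosomal `RPL*` proteins, `UBC`/`CUL` ubiquitylation machinery, …) are
   removed, then self-loops and duplicate edges, giving a simple undirected
   graph *G*. Hubs are ranked by betweenness and degree ("connectivity").
2. **Seed selection.** A gene is a seed (disease-associated gene, DAG) iff
   it has a GWAS signal with *p* < 5×10⁻⁸ (strict) or an OMIM entry flagged
   for a known molecular association. The *proto-module* is the subgraph
   induced by seed–seed edges alone.
3. **Four evidence streams** score every non-seed protein of *G*:
   * **PPIN proximity** — ≥ 3 distinct seed interactors;
   * **Colocalization** — ≥ 3 interacting seeds annotated to a cellular
     compartment enriched among the seeds (upper-tail hypergeometric test,
     Benjamini–Hochberg FDR < 0.05);
   * **Fine-mapping** — an LD proxy (*r*² ≥ 0.8 within 500 kb, computed from
     phased haplotypes: D = p_AB − p_A·p_B, r² = D²/(p_A q_A p_B q_B),
     D′ = |D|/D_max) of an association signal with *p* ≤ 10⁻³ falls inside
     the gene body;
   * **Regulation** — a category-1 regulatory variant, or mutual top-1%
     coexpression rank with ≥ 3 seeds combined with a shared TF/miRNA
     target set (≥ 3 seeds in the same set).
4. **Module extraction.** Candidates supported by ≥ 3 streams are
   high-confidence, exactly 2 moderate. The disease module is the subgraph
   of *G* induced by high+moderate candidates; it is expanded to first
   neighbors, and its internal edge count is tested against 10 000 uniform
   random same-size node draws, with the add-one empirical p-value
   p = (1 + #{null ≥ observed}) / (1 + N). Seed over-representation among
   network proteins uses the upper-tail hypergeometric test.
5. **Kinase confirmation.** Kinase–substrate predictions are kept at GPS
   differential score ≥ 1.0 (score − cutoff, inclusive) or NetworKIN score
   > 2.0 (strict) and confirmed when the pair is also a network edge.

A synthetic-data generator (`ppimod.synthetic_data`) produces a complete,
self-consistent input bundle — scale-free background network, planted dense
module wired to seeds, block-structured haplotypes with sub-threshold proxy
signals, latent-factor coexpression groups, planted regulator sets and mixed
kinase scores — together with per-stream ground truth, so every stage of the
pipeline is verifiable without downloads.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic scenario (600 genes, 180 seeds, planted 90-gene module):

```bash
python analysis/01_simulate.py 1      # write results/scenario/
python analysis/02_network_hubs.py
python analysis/03_protomodule.py
python analysis/04_evidence_streams.py
python analysis/05_module.py
python analysis/06_kinase.py
```

which prints (seed 1):

```
interactome: 600 nodes, 2168 edges (from 2176 records)
180 seeds selected; proto-module of 144 nodes / 158 edges
stream ppin      : 117 candidates
stream go        : 94 candidates
stream gwas      : 30 candidates
stream regulation: 58 candidates
top seed compartment: GO:0005768 (k=40/180, BH p=8.86e-22)
evidence tiers: {'high': 69, 'moderate': 25, 'weak': 27}
module: 94 nodes / 414 edges (connected=True, 0 isolated)
expansion: 463 nodes covering 77% of nodes and 83% of interactions
randomization (induced_edges): observed=414 p=9.999e-05 over 10000 draws
planted-module recovery: precision=0.957 recall=1.000
48 of 94 module substrates have >= 1 kinase interaction confirmed in the network
```

Reading: of the 600 proteins, the evidence tiers recover a 94-node module
containing all 90 planted members (recall 1.0) plus 4 background proteins
that accumulated ≥ 2 evidence streams by chance (precision 0.957). Its 414
internal interactions are far denser than any of 10 000 random 94-node
draws (empirical p ≈ 10⁻⁴, the add-one floor), and roughly half of the
module substrates have a score-filtered kinase prediction confirmed by a
physical edge.

The same pipeline runs on real tables: point a YAML config (see
`results/pipeline_config.yaml` after step 01 for a template) at your own
files and use the `ppimod` CLI (`ppimod simulate|graph|seeds|evidence-*|
module|randomize|kinase|run-all`).

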