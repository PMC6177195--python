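"""Self-consistent synthetic input bundle with a planted disease module.

The generator emulates the structure of the real study inputs at desk scale:
a scale-free background interactome (preferential attachment) with a planted
dense module whose members each touch at least three seed genes; genome-wide
significant GWAS/OMIM seed associations; sub-threshold association signals
sitting in LD blocks that overlap planted module gene loci; a latent-factor
expression matrix giving planted mutual-rank coexpression groups; shared
TF/miRNA target sets; regulatory-variant category flags; and kinase-substrate
predictions with mixed above/below-threshold scores.

Everything is a pure function of (config, rng_seed); ground truth (planted
membership per evidence stream) is exported so each pipeline stage can be
validated in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .evidence_finemap import GeneLocus, HaplotypePanel
from .graph_core import InteractionRecord
from .module_discovery import stage_rng

_SOURCES = ("BIOGRID", "HPRD", "INTACT", "REACTOME", "DIP")


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic scenario. Defaults mirror the magnitudes of the
    study (hundreds of genes, ~180 seeds, a ~90-gene module)."""

    n_genes: int = 600
    n_seeds: int = 180
    module_size: int = 90
    module_edge_density: float = 0.08
    background_attachment_parameter: int = 2
    # evidence-stream planting
    n_anchor_seeds: int = 40          # compartment-annotated seeds the module wires to
    min_seed_links: int = 3           # every module member touches >= this many anchors
    max_seed_links: int = 5
    seed_seed_edge_prob: float = 0.003
    n_gwas_planted: int = 30          # module genes with sub-threshold proxy signals
    n_regulome_planted: int = 15      # subset of the above with category-1 flags
    n_coexpr_groups: int = 13
    coexpr_group_candidates: int = 3
    coexpr_group_seeds: int = 3
    n_kinases: int = 2
    # expression
    n_samples: int = 200
    module_correlation: float = 0.9   # latent-factor rho within a coexpression group
    top_fraction: float = 0.01
    # haplotypes
    n_haplotypes: int = 2000
    n_ld_blocks: int = 40             # n_gwas_planted signal blocks + the rest null
    snps_per_block: int = 8
    block_r2: float = 0.9
    signal_p_range: tuple[float, float] = (1e-6, 1e-3)
    # annotation noise
    n_background_terms: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes - self.n_seeds:
            raise ValueError("module_size exceeds available non-seed genes")
        if not (0 <= self.module_correlation < 1):
            raise ValueError("module_correlation must be in [0,1)")
        if not (0 < self.block_r2 <= 1):
            raise ValueError("block_r2 must be in (0,1]")
        if not (0 < self.module_edge_density <= 1):
            raise ValueError("module_edge_density must be a probability")
        if self.n_gwas_planted > self.module_size:
            raise ValueError("n_gwas_planted exceeds module_size")
        if self.n_ld_blocks < self.n_gwas_planted:
            raise ValueError("need at least one LD block per planted signal")
        n_coexpr = self.n_coexpr_groups * self.coexpr_group_candidates
        if n_coexpr > self.module_size:
            raise ValueError("coexpression groups exceed module size")
        group = self.coexpr_group_candidates + self.coexpr_group_seeds
        top_k = int(np.ceil(self.top_fraction * (self.n_genes - 1)))
        if group - 1 > top_k:
            raise ValueError(
                f"coexpression group size {group} cannot fit a mutual top list of "
                f"{top_k}; raise top_fraction or shrink groups"
            )


def small_config(rng_seed: int = 0) -> ScenarioConfig:
    """A scaled-down scenario for fast tests (same structure, smaller sizes)."""
    return ScenarioConfig(
        n_genes=160,
        n_seeds=48,
        module_size=26,
        n_anchor_seeds=14,
        n_gwas_planted=10,
        n_regulome_planted=5,
        n_coexpr_groups=4,
        n_samples=120,
        top_fraction=0.04,
        n_haplotypes=500,
        n_ld_blocks=14,
        n_background_terms=10,
        rng_seed=rng_seed,
    )


@dataclass
class GroundTruth:
    """Planted membership, per evidence stream, for validating the pipeline."""

    module: list[str]
    seeds: list[str]
    anchor_seeds: list[str]
    kinases: list[str]
    stream_ppin: list[str]
    stream_go: list[str]
    stream_gwas: list[str]
    stream_coexpression: list[str]
    coexpr_groups: list[dict]
    kinase_confirmed: list[list[str]]
    planted_term: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ScenarioBundle:
    """In-memory scenario: all pipeline inputs plus ground truth."""

    cfg: ScenarioConfig
    records: list[InteractionRecord]
    associations: list[dict]            # rows of the association TSV
    loci: list[GeneLocus]
    panel: HaplotypePanel
    expression_genes: list[str]
    expression: np.ndarray              # genes x samples
    sample_ids: list[str]
    compartments: dict[str, list[str]]  # term -> genes
    tft_sets: dict[str, list[str]]
    mirna_sets: dict[str, list[str]]
    regulome_flags: dict[str, str]
    kinase_rows: list[dict]
    exclusions: list[str]
    truth: GroundTruth


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def generate_ppin(cfg: ScenarioConfig) -> tuple[list[InteractionRecord], dict]:
    """Scale-free background + planted module wiring.

    The background is a preferential-attachment graph (heavy-tailed degrees,
    a few central hubs). The planted module is internally wired at
    ``module_edge_density`` and every member is wired to ``min_seed_links``..
    ``max_seed_links`` anchor seeds; seeds are sparsely wired to each other so
    that a proto-module exists; planted kinases are high-degree hubs.
    """
    rng = stage_rng(cfg.rng_seed, "ppin")
    names = _gene_names(cfg.n_genes)
    order = [names[i] for i in rng.permutation(cfg.n_genes)]
    seeds = sorted(order[: cfg.n_seeds])
    module = sorted(order[cfg.n_seeds : cfg.n_seeds + cfg.module_size])
    anchor_seeds = sorted(rng.choice(seeds, size=cfg.n_anchor_seeds, replace=False))

    bg = nx.barabasi_albert_graph(
        cfg.n_genes,
        cfg.background_attachment_parameter,
        seed=int(rng.integers(2**31)),
    )
    relabel = {i: names[j] for i, j in enumerate(rng.permutation(cfg.n_genes))}
    g = nx.relabel_nodes(bg, relabel)

    # module internal density
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            if rng.random() < cfg.module_edge_density:
                g.add_edge(a, b)
    # each member anchored to >= min_seed_links compartment seeds
    for m in module:
        n_links = int(rng.integers(cfg.min_seed_links, cfg.max_seed_links + 1))
        for s in rng.choice(anchor_seeds, size=n_links, replace=False):
            g.add_edge(m, s)
    # sparse seed-seed wiring -> proto-module with disconnected seeds
    for i, a in enumerate(seeds):
        for b in seeds[i + 1 :]:
            if rng.random() < cfg.seed_seed_edge_prob:
                g.add_edge(a, b)
    # planted kinase hubs inside the module
    kinases = list(module[: cfg.n_kinases])
    hub_fracs = [0.3, 0.12, 0.08][: cfg.n_kinases]
    for kin, frac in zip(kinases, hub_fracs):
        others = [n for n in names if n != kin]
        for t in rng.choice(others, size=int(frac * cfg.n_genes), replace=False):
            g.add_edge(kin, t)

    records = [
        InteractionRecord.make(
            a,
            b,
            source_db=_SOURCES[int(rng.integers(len(_SOURCES)))],
            evidence_class="binary" if rng.random() < 0.6 else "complex",
        )
        for a, b in sorted(tuple(sorted(e)) for e in g.edges())
    ]
    # raw-table noise the pipeline must clean: self-pairs, duplicate
    # orientations, and nonspecific partners on the exclusion list
    dup = [records[int(i)] for i in rng.choice(len(records), size=5, replace=False)]
    records += [InteractionRecord.make(r.gene_b, r.gene_a, r.source_db) for r in dup]
    records += [InteractionRecord.make(n, n) for n in rng.choice(names, 3, replace=False)]
    excl_partners = ["RPL3", "RPL7A", "UBC", "CUL1", "HSPA8"]
    for p in excl_partners:
        for t in rng.choice(names, size=3, replace=False):
            records.append(InteractionRecord.make(p, t))

    truth = {
        "seeds": seeds,
        "module": module,
        "anchor_seeds": anchor_seeds,
        "kinases": kinases,
        "graph": g,
        "exclusions": ["RPL*", "UBC", "CUL1", "HSPA8"],
    }
    return records, truth


def generate_associations(
    cfg: ScenarioConfig,
    genes: list[str],
    seeds: list[str],
    gwas_planted: list[str],
    signal_snps: dict[str, tuple[str, str, int]],
) -> list[dict]:
    """Association rows: seeds below genome-wide significance or OMIM-tagged;
    planted module genes with sub-threshold signals at panel SNPs; background
    genes with null p-values."""
    rng = stage_rng(cfg.rng_seed, "associations")
    traits = ("t2d", "glycemic", "obesity", "insulin")
    rows: list[dict] = []

    def trait() -> str:
        return traits[int(rng.integers(len(traits)))]

    for i, s in enumerate(seeds):
        kind = rng.random()
        if kind < 0.7:  # GWAS-only seed
            p = 10 ** rng.uniform(-20, np.log10(4.9e-8))
            rows.append(
                dict(snp_id=f"rsS{i:04d}", chrom="chr20", pos=10_000 + 500 * i,
                     gene=s, trait=trait(), p_value=f"{p:.3e}", source="gwas",
                     omim_tag="")
            )
        elif kind < 0.9:  # OMIM-only seed
            rows.append(
                dict(snp_id="", chrom="", pos="", gene=s, trait=trait(),
                     p_value="", source="omim", omim_tag="true")
            )
        else:  # both
            p = 10 ** rng.uniform(-20, np.log10(4.9e-8))
            rows.append(
                dict(snp_id=f"rsS{i:04d}", chrom="chr20", pos=10_000 + 500 * i,
                     gene=s, trait=trait(), p_value=f"{p:.3e}", source="gwas",
                     omim_tag="")
            )
            rows.append(
                dict(snp_id="", chrom="", pos="", gene=s, trait=trait(),
                     p_value="", source="omim", omim_tag="true")
            )

    lo, hi = cfg.signal_p_range
    for gene in gwas_planted:
        snp_id, chrom, pos = signal_snps[gene]
        p = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
        rows.append(
            dict(snp_id=snp_id, chrom=chrom, pos=pos, gene=gene, trait=trait(),
                 p_value=f"{p:.3e}", source="gwas", omim_tag="")
        )

    planted = set(seeds) | set(gwas_planted)
    background = [gene for gene in genes if gene not in planted]
    for i, gene in enumerate(background):
        if rng.random() < 0.5:
            rows.append(
                dict(snp_id=f"rsB{i:04d}", chrom="chr21", pos=5_000 + 700 * i,
                     gene=gene, trait="other",
                     p_value=f"{rng.uniform(0.05, 1.0):.3e}", source="gwas",
                     omim_tag="")
            )
    # OMIM rows without the molecular tag: retained, never seed-qualifying
    for gene in background[:3]:
        rows.append(
            dict(snp_id="", chrom="", pos="", gene=gene, trait="other",
                 p_value="", source="omim", omim_tag="false")
        )
    return rows


def generate_haplotypes(
    cfg: ScenarioConfig, genes: list[str], gwas_planted: list[str]
) -> tuple[HaplotypePanel, list[GeneLocus], dict[str, tuple[str, str, int]]]:
    """Block-structured panel plus gene loci.

    Each LD block carries ``snps_per_block`` SNPs generated by copying a
    founder 0/1 assignment per haplotype with a small flip rate, so that
    within-block pairwise r^2 ~= block_r2 while blocks are independent. The
    first ``n_gwas_planted`` blocks are signal blocks: the index SNP (first
    SNP, carrying the sub-threshold association p-value) lies OUTSIDE the
    planted gene's locus, which overlaps the tail SNPs of the block — the
    gene is only reachable through LD proxies. Null blocks overlap background
    gene loci and carry no signal.
    """
    rng = stage_rng(cfg.rng_seed, "haplotypes")
    eps = (1 - cfg.block_r2 ** 0.25) / 2
    chrom = "chr10"
    block_span = 1_000 * (cfg.snps_per_block - 1)
    spacing = 100_000

    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    cols: list[np.ndarray] = []
    loci: list[GeneLocus] = []
    signal_snps: dict[str, tuple[str, str, int]] = {}

    non_module_pool = [g for g in genes if g not in set(gwas_planted)]
    null_block_genes = list(
        rng.choice(non_module_pool, size=cfg.n_ld_blocks - cfg.n_gwas_planted,
                   replace=False)
    )

    for b in range(cfg.n_ld_blocks):
        start = 1_000_000 + b * (block_span + spacing)
        founder = (rng.random(cfg.n_haplotypes) < 0.5).astype(np.int8)
        for s in range(cfg.snps_per_block):
            flips = rng.random(cfg.n_haplotypes) < eps
            col = founder ^ flips.astype(np.int8)
            sid = f"rs{b:03d}_{s}"
            snp_ids.append(sid)
            chroms.append(chrom)
            positions.append(start + 1_000 * s)
            cols.append(col)
        half = cfg.snps_per_block // 2
        locus_start = start + 1_000 * half - 200
        locus_end = start + block_span + 200
        if b < cfg.n_gwas_planted:
            gene = gwas_planted[b]
            signal_snps[gene] = (f"rs{b:03d}_0", chrom, start)
        else:
            gene = null_block_genes[b - cfg.n_gwas_planted]
        loci.append(GeneLocus(gene, chrom, locus_start, locus_end))

    # loci for every remaining gene, far from the panel
    covered = {l.gene for l in loci}
    offset = 1_000_000
    for gene in genes:
        if gene in covered:
            continue
        loci.append(GeneLocus(gene, "chr2", offset, offset + 20_000))
        offset += 60_000

    panel = HaplotypePanel(
        snp_ids=snp_ids,
        chroms=chroms,
        positions=np.array(positions),
        alleles=np.column_stack(cols),
    )
    return panel, loci, signal_snps


def generate_expression(
    cfg: ScenarioConfig,
    genes: list[str],
    coexpr_groups: list[dict],
) -> tuple[np.ndarray, list[str]]:
    """Latent-factor expression: each planted coexpression group shares one
    factor with loading sqrt(rho); everything else is independent noise.
    Values are emitted on a positive, roughly log-normal scale."""
    rng = stage_rng(cfg.rng_seed, "expression")
    gindex = {g: i for i, g in enumerate(genes)}
    z = rng.standard_normal((len(genes), cfg.n_samples))
    rho = cfg.module_correlation
    for grp in coexpr_groups:
        factor = rng.standard_normal(cfg.n_samples)
        for gene in grp["candidates"] + grp["seeds"]:
            i = gindex[gene]
            z[i] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * rng.standard_normal(
                cfg.n_samples
            )
    values = np.exp(z + 5.0)
    samples = [f"SAMPLE{j:03d}" for j in range(1, cfg.n_samples + 1)]
    return values, samples


def generate_auxiliary(
    cfg: ScenarioConfig,
    genes: list[str],
    seeds: list[str],
    module: list[str],
    anchor_seeds: list[str],
    gwas_planted: list[str],
    coexpr_groups: list[dict],
    kinases: list[str],
    graph: nx.Graph,
) -> dict:
    """Compartment GMT, TF/miRNA target sets, regulatory flags and kinase
    prediction rows, with planted positives and realistic decoys."""
    rng = stage_rng(cfg.rng_seed, "auxiliary")

    # compartments: one planted endosome-like term = the anchor seeds; every
    # gene also carries 1-3 random background terms
    planted_term = "GO:0005768"
    compartments: dict[str, list[str]] = {planted_term: sorted(anchor_seeds)}
    bg_terms = [f"GO:19{i:05d}" for i in range(cfg.n_background_terms)]
    term_members: dict[str, set[str]] = {t: set() for t in bg_terms}
    for gene in genes:
        for t in rng.choice(bg_terms, size=int(rng.integers(1, 4)), replace=False):
            term_members[t].add(gene)
    for t in bg_terms:
        if term_members[t]:
            compartments[t] = sorted(term_members[t])

    # TF / miRNA target sets: each coexpression group gets one regulator set
    # containing its candidates + seeds (+ random padding); decoy sets have
    # fewer than three seeds
    tft_sets: dict[str, list[str]] = {}
    mirna_sets: dict[str, list[str]] = {}
    for gi, grp in enumerate(coexpr_groups):
        members = set(grp["candidates"]) | set(grp["seeds"])
        members |= set(rng.choice(genes, size=5, replace=False))
        target = tft_sets if gi % 3 != 2 else mirna_sets
        name = f"{'TFT' if target is tft_sets else 'MIR'}_M{gi:02d}"
        target[name] = sorted(members)
        grp["regulator_set"] = name
    non_seed = [g for g in genes if g not in set(seeds)]
    for d in range(4):
        decoy = set(rng.choice(non_seed, size=8, replace=False))
        decoy |= set(rng.choice(seeds, size=2, replace=False))  # only 2 seeds
        tft_sets[f"TFT_DECOY{d}"] = sorted(decoy)

    # regulatory flags: category 1 for the planted regulome genes (subset of
    # the fine-mapping stream), noise categories elsewhere
    regulome_planted = gwas_planted[: cfg.n_regulome_planted]
    cat1 = ("1a", "1b", "1c", "1d", "1e", "1f")
    noise_cats = ("2a", "2b", "3a", "4", "5", "6", "7")
    flags: dict[str, str] = {}
    for gene in regulome_planted:
        flags[gene] = cat1[int(rng.integers(len(cat1)))]
    for gene in rng.choice([g for g in genes if g not in flags], 50, replace=False):
        flags[gene] = noise_cats[int(rng.integers(len(noise_cats)))]

    # kinase predictions: confirmable above-threshold rows where a planted
    # kinase-substrate edge exists, plus below-threshold and off-network decoys
    kin_rows: list[dict] = []
    confirmed: list[list[str]] = []
    residues = ("Y", "S", "T")

    def site() -> str:
        return f"{residues[int(rng.integers(3))]}{int(rng.integers(1, 900))}"

    for sub in module:
        for kin in kinases:
            if kin == sub or not graph.has_edge(kin, sub):
                continue
            if rng.random() < 0.5:
                cutoff = rng.uniform(1.0, 3.0)
                kin_rows.append(
                    dict(substrate=sub, site=site(), kinase=kin, source="gps",
                         gps_score=f"{cutoff + rng.uniform(1.0, 3.0):.3f}",
                         gps_cutoff=f"{cutoff:.3f}", networkin_score="")
                )
            else:
                kin_rows.append(
                    dict(substrate=sub, site=site(), kinase=kin, source="networkin",
                         gps_score="", gps_cutoff="",
                         networkin_score=f"{rng.uniform(2.01, 6.0):.3f}")
                )
            confirmed.append([kin, sub])
            break  # one confirmable row per substrate is enough
    # below-threshold rows (must be filtered out)
    for sub in rng.choice(module, size=min(20, len(module)), replace=False):
        kin = kinases[int(rng.integers(len(kinases)))]
        if rng.random() < 0.5:
            cutoff = rng.uniform(1.0, 3.0)
            kin_rows.append(
                dict(substrate=sub, site=site(), kinase=kin, source="gps",
                     gps_score=f"{cutoff + rng.uniform(0.0, 0.99):.3f}",
                     gps_cutoff=f"{cutoff:.3f}", networkin_score="")
            )
        else:
            kin_rows.append(
                dict(substrate=sub, site=site(), kinase=kin, source="networkin",
                     gps_score="", gps_cutoff="",
                     networkin_score=f"{rng.uniform(0.1, 2.0):.3f}")
            )
    # above-threshold rows whose kinase-substrate pair is NOT a network edge
    for sub in rng.choice(non_seed, size=10, replace=False):
        kin_rows.append(
            dict(substrate=sub, site=site(), kinase="MAPK99", source="networkin",
                 gps_score="", gps_cutoff="", networkin_score="3.000")
        )

    return dict(
        compartments=compartments,
        planted_term=planted_term,
        tft_sets=tft_sets,
        mirna_sets=mirna_sets,
        flags=flags,
        kinase_rows=kin_rows,
        kinase_confirmed=confirmed,
        regulome_planted=regulome_planted,
    )


def generate_bundle(cfg: ScenarioConfig) -> ScenarioBundle:
    """Generate the full scenario in memory (pure function of cfg)."""
    rng = stage_rng(cfg.rng_seed, "scenario")
    records, net = generate_ppin(cfg)
    genes = _gene_names(cfg.n_genes)
    seeds, module = net["seeds"], net["module"]

    gwas_planted = sorted(rng.choice(module, size=cfg.n_gwas_planted, replace=False))
    panel, loci, signal_snps = generate_haplotypes(cfg, genes, gwas_planted)
    associations = generate_associations(cfg, genes, seeds, gwas_planted, signal_snps)

    coexpr_pool = [m for m in module if m not in set(gwas_planted)]
    n_cand = cfg.n_coexpr_groups * cfg.coexpr_group_candidates
    if len(coexpr_pool) < n_cand:  # overlap with the gwas stream if module is small
        coexpr_pool = list(module)
    cand_pick = list(rng.choice(coexpr_pool, size=n_cand, replace=False))
    seed_pick = list(
        rng.choice(seeds, size=cfg.n_coexpr_groups * cfg.coexpr_group_seeds,
                   replace=False)
    )
    coexpr_groups = []
    for i in range(cfg.n_coexpr_groups):
        coexpr_groups.append(
            dict(
                candidates=sorted(
                    cand_pick[i * cfg.coexpr_group_candidates : (i + 1) * cfg.coexpr_group_candidates]
                ),
                seeds=sorted(
                    seed_pick[i * cfg.coexpr_group_seeds : (i + 1) * cfg.coexpr_group_seeds]
                ),
            )
        )

    expression, samples = generate_expression(cfg, genes, coexpr_groups)
    aux = generate_auxiliary(
        cfg, genes, seeds, module, net["anchor_seeds"], gwas_planted,
        coexpr_groups, net["kinases"], net["graph"],
    )

    coexpr_stream = sorted({g for grp in coexpr_groups for g in grp["candidates"]})
    truth = GroundTruth(
        module=module,
        seeds=seeds,
        anchor_seeds=net["anchor_seeds"],
        kinases=net["kinases"],
        stream_ppin=module,          # every member is wired to >= 3 (anchor) seeds
        stream_go=module,            # ... annotated to the planted enriched term
        stream_gwas=gwas_planted,
        stream_coexpression=sorted(
            set(coexpr_stream) | set(aux["regulome_planted"])
        ),
        coexpr_groups=coexpr_groups,
        kinase_confirmed=aux["kinase_confirmed"],
        planted_term=aux["planted_term"],
    )
    return ScenarioBundle(
        cfg=cfg,
        records=records,
        associations=associations,
        loci=loci,
        panel=panel,
        expression_genes=genes,
        expression=expression,
        sample_ids=samples,
        compartments=aux["compartments"],
        tft_sets=aux["tft_sets"],
        mirna_sets=aux["mirna_sets"],
        regulome_flags=aux["flags"],
        kinase_rows=aux["kinase_rows"],
        exclusions=net["exclusions"],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# disk emission


def _write_gmt(sets: dict[str, list[str]], path: Path, desc: str) -> None:
    with path.open("w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, desc, *sorted(sets[name])]) + "\n")


def generate_scenario(
    cfg: ScenarioConfig, outdir: str | Path, force: bool = False
) -> dict[str, Path]:
    """Write every input file the pipeline reads, plus ground truth and a
    checksum manifest. Refuses a non-empty output directory without force."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(cfg)
    paths: dict[str, Path] = {}

    def emit(name: str, filename: str, text: str) -> None:
        p = outdir / filename
        p.write_text(text)
        paths[name] = p

    lines = ["gene_a\tgene_b\tsource_db\tevidence_class"]
    lines += [
        f"{r.gene_a}\t{r.gene_b}\t{r.source_db}\t{r.evidence_class}"
        for r in bundle.records
    ]
    emit("interactions", "interactions.tsv", "\n".join(lines) + "\n")

    cols = ["snp_id", "chrom", "pos", "gene", "trait", "p_value", "source", "omim_tag"]
    lines = ["\t".join(cols)]
    lines += ["\t".join(str(row[c]) for c in cols) for row in bundle.associations]
    emit("associations", "associations.tsv", "\n".join(lines) + "\n")

    lines = ["chrom\tstart_1based\tend\tgene"]
    lines += [f"{l.chrom}\t{l.start}\t{l.end}\t{l.gene}" for l in bundle.loci]
    emit("loci", "loci.tsv", "\n".join(lines) + "\n")

    panel = bundle.panel
    lines = ["\t".join(panel.snp_ids)]
    lines += ["\t".join(map(str, row)) for row in panel.alleles]
    emit("haplotypes", "haplotypes.tsv", "\n".join(lines) + "\n")
    lines = ["snp_id\tchrom\tpos"]
    lines += [
        f"{s}\t{c}\t{p}"
        for s, c, p in zip(panel.snp_ids, panel.chroms, panel.positions)
    ]
    emit("snp_map", "snp_map.tsv", "\n".join(lines) + "\n")

    lines = ["gene\t" + "\t".join(bundle.sample_ids)]
    for gene, row in zip(bundle.expression_genes, bundle.expression):
        lines.append(gene + "\t" + "\t".join(f"{v:.4f}" for v in row))
    emit("expression", "expression.tsv", "\n".join(lines) + "\n")

    _write_gmt(bundle.compartments, outdir / "compartments.gmt", "cellular_component")
    paths["compartments"] = outdir / "compartments.gmt"
    _write_gmt(bundle.tft_sets, outdir / "tft.gmt", "tf_targets")
    paths["tft"] = outdir / "tft.gmt"
    _write_gmt(bundle.mirna_sets, outdir / "mirna.gmt", "mirna_targets")
    paths["mirna"] = outdir / "mirna.gmt"

    lines = ["gene\tcategory"]
    lines += [f"{g}\t{c}" for g, c in sorted(bundle.regulome_flags.items())]
    emit("regulome_flags", "regulome_flags.tsv", "\n".join(lines) + "\n")

    cols = ["substrate", "site", "kinase", "source", "gps_score", "gps_cutoff",
            "networkin_score"]
    lines = ["\t".join(cols)]
    lines += ["\t".join(str(r[c]) for c in cols) for r in bundle.kinase_rows]
    emit("kinase_predictions", "kinase_predictions.tsv", "\n".join(lines) + "\n")

    emit("exclusions", "exclusions.txt",
         "# nonspecific interactors\n" + "\n".join(bundle.exclusions) + "\n")

    bundle.truth.to_json(outdir / "ground_truth.json")
    paths["ground_truth"] = outdir / "ground_truth.json"

    manifest = {
        "config": asdict(bundle.cfg),
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(paths.values())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = outdir / "manifest.json"
    return paths


def recovery_scores(recovered: set[str], planted: set[str]) -> dict[str, float]:
    """Precision/recall of a recovered gene set against planted truth."""
    tp = len(recovered & planted)
    precision = tp / len(recovered) if recovered else 0.0
    recall = tp / len(planted) if planted else 0.0
    return {"precision": precision, "recall": recall, "n_recovered": len(recovered),
            "n_planted": len(planted), "n_true_positive": tp}
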