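"""End-to-end pipeline: inputs -> networks -> evidence streams -> disease module.

Stages are lazy cached properties of :class:`Pipeline`, so a single stage can
be run in isolation (the CLI subcommands do exactly that) while ``run`` executes
everything and writes the TSV artifacts plus a machine-readable JSON report.
Every numeric threshold is carried in :class:`PipelineConfig` and echoed into
the report; the report contains no timestamps so identical config + seed give
byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import (
    evidence_finemap,
    evidence_ppin_go,
    evidence_regulation,
    graph_core,
    io,
    kinase_substrate,
    module_discovery,
    seed_protomodule,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All file paths and numeric thresholds of one pipeline run."""

    # inputs
    interactions: str = ""
    interactions_dialect: str = "tsv"
    associations: str = ""
    exclusions: Optional[str] = None
    compartments: Optional[str] = None
    loci: Optional[str] = None
    haplotypes: Optional[str] = None        # TSV matrix (with snp_map) or VCF
    snp_map: Optional[str] = None
    expression: Optional[str] = None
    tft: Optional[str] = None
    mirna: Optional[str] = None
    regulome_flags: Optional[str] = None
    kinase_predictions: Optional[str] = None
    kinase_aliases: dict[str, str] = field(default_factory=dict)
    # thresholds (defaults as used throughout the analysis)
    seed_p_threshold: float = 5e-8          # strict <
    finemap_p_max: float = 1e-3             # inclusive <=
    proxy_r2: float = 0.8
    proxy_window: int = 500_000
    min_interactors: int = 3
    min_coexpressed_seeds: int = 3
    min_shared_seeds: int = 3
    top_fraction: float = 0.01
    correlation_method: str = "pearson"
    gps_min_differential: float = 1.0       # inclusive >=
    networkin_min_score: float = 2.0        # strict >
    enrichment_alpha: float = 0.05
    binary_only: bool = False
    # module / randomization
    module_tiers: tuple[str, ...] = ("high", "moderate")
    statistic: str = "induced_edges"
    n_reiterations: int = 10_000
    overlap_universe_size: int = 20_000     # protein-coding genome scale
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_tiers"] = list(self.module_tiers)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.module_tiers, list):
            cfg.module_tiers = tuple(cfg.module_tiers)
        return cfg

    @classmethod
    def for_scenario(cls, scenario_dir: str | Path, **overrides) -> "PipelineConfig":
        """Point every input path at a generated scenario bundle.

        Scenario-dependent analysis parameters recorded in the bundle's
        manifest (the mutual-rank top fraction) are adopted so the analysis
        matches the conditions the data were generated under.
        """
        d = Path(scenario_dir)
        base = dict(
            interactions=str(d / "interactions.tsv"),
            associations=str(d / "associations.tsv"),
            exclusions=str(d / "exclusions.txt"),
            compartments=str(d / "compartments.gmt"),
            loci=str(d / "loci.tsv"),
            haplotypes=str(d / "haplotypes.tsv"),
            snp_map=str(d / "snp_map.tsv"),
            expression=str(d / "expression.tsv"),
            tft=str(d / "tft.gmt"),
            mirna=str(d / "mirna.gmt"),
            regulome_flags=str(d / "regulome_flags.tsv"),
            kinase_predictions=str(d / "kinase_predictions.tsv"),
        )
        manifest = d / "manifest.json"
        if manifest.exists():
            scenario_cfg = json.loads(manifest.read_text()).get("config", {})
            if "top_fraction" in scenario_cfg:
                base["top_fraction"] = scenario_cfg["top_fraction"]
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        """Check that every referenced input exists before any compute."""
        missing = []
        for name in ("interactions", "associations", "exclusions", "compartments",
                     "loci", "haplotypes", "snp_map", "expression", "tft", "mirna",
                     "regulome_flags", "kinase_predictions"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                missing.append(f"{name}: {value}")
        if not self.interactions:
            missing.append("interactions: (unset)")
        if not self.associations:
            missing.append("associations: (unset)")
        if missing:
            raise FileNotFoundError("missing pipeline inputs: " + "; ".join(missing))
        if self.statistic not in ("induced_edges", "expansion_edges", "expansion_nodes"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


class Pipeline:
    """Lazy stage graph over one validated configuration."""

    def __init__(self, cfg: PipelineConfig):
        cfg.validate()
        self.cfg = cfg
        self.warnings: list[str] = []

    # -- network ------------------------------------------------------------

    @cached_property
    def records(self) -> list[graph_core.InteractionRecord]:
        recs = graph_core.read_interaction_table(
            self.cfg.interactions, dialect=self.cfg.interactions_dialect  # type: ignore[arg-type]
        )
        if self.cfg.exclusions:
            excl = graph_core.ExclusionList.from_file(self.cfg.exclusions)
            n0 = len(recs)
            recs = graph_core.filter_nonspecific(recs, excl)
            if n0 != len(recs):
                logger.info("excluded %d nonspecific records", n0 - len(recs))
        return recs

    @cached_property
    def graph(self):
        return graph_core.build_graph(self.records, binary_only=self.cfg.binary_only)

    @cached_property
    def hub_table(self) -> pd.DataFrame:
        return graph_core.rank_hubs(self.graph, metric="betweenness")

    # -- seeds --------------------------------------------------------------

    @cached_property
    def associations(self):
        return seed_protomodule.read_association_table(self.cfg.associations)

    @cached_property
    def seeds(self) -> seed_protomodule.SeedSet:
        return seed_protomodule.select_dags(
            self.associations, p_threshold=self.cfg.seed_p_threshold
        )

    @cached_property
    def protomodule(self):
        g, stats = seed_protomodule.build_protomodule(self.seeds, self.records)
        stats["n_peripheral"] = seed_protomodule.count_peripheral(g)
        stats["degree_distribution"] = seed_protomodule.degree_distribution(g)
        return g, stats

    @cached_property
    def candidate_universe(self) -> set[str]:
        """Non-seed proteins of the interactome (the candidate search space)."""
        return set(self.graph.nodes) - self.seeds.genes

    # -- evidence streams ---------------------------------------------------

    @cached_property
    def stream_ppin(self) -> set[str]:
        return evidence_ppin_go.ppin_proximity_candidates(
            self.records, self.candidate_universe, self.seeds,
            min_interactors=self.cfg.min_interactors,
        )

    @cached_property
    def compartment_annotation(self):
        return io.read_compartments(self.cfg.compartments)

    @cached_property
    def seed_enrichment(self) -> pd.DataFrame:
        ann = self.compartment_annotation
        query = self.seeds.genes & ann.annotated_genes
        return evidence_ppin_go.compartment_enrichment(query, ann)

    @cached_property
    def stream_go(self) -> set[str]:
        if not self.cfg.compartments:
            return set()
        terms = evidence_ppin_go.enriched_terms(
            self.seed_enrichment, alpha=self.cfg.enrichment_alpha
        )
        return evidence_ppin_go.colocalization_candidates(
            self.candidate_universe, self.seeds, self.compartment_annotation,
            self.records, terms, min_seed_interactors=self.cfg.min_interactors,
        )

    @cached_property
    def haplotype_panel(self):
        path = Path(self.cfg.haplotypes)
        if path.suffix.lower() == ".vcf":
            panel, _rejected = evidence_finemap.read_haplotype_vcf(path)
            return panel
        return evidence_finemap.read_haplotype_tsv(path, self.cfg.snp_map)

    @cached_property
    def finemap_genes(self) -> set[str]:
        """Fine-mapping candidates over ALL loci (before universe restriction)."""
        loci = evidence_finemap.read_loci_table(self.cfg.loci)
        return evidence_finemap.finemap_candidates(
            loci, self.associations, self.haplotype_panel,
            p_max=self.cfg.finemap_p_max, r2_threshold=self.cfg.proxy_r2,
            window=self.cfg.proxy_window,
        )

    @cached_property
    def stream_gwas(self) -> set[str]:
        if not (self.cfg.loci and self.cfg.haplotypes):
            return set()
        return self.finemap_genes & self.candidate_universe

    @cached_property
    def stream_regulation(self) -> set[str]:
        if not self.cfg.expression:
            return set()
        flags = (
            evidence_regulation.read_flag_table(self.cfg.regulome_flags)
            if self.cfg.regulome_flags else {}
        )
        pool1 = evidence_regulation.regulome_pool(self.stream_gwas, flags)
        expr = evidence_regulation.ExpressionMatrix.from_tsv(self.cfg.expression)
        coexpr = evidence_regulation.coexpressed_with_seeds(
            expr, self.candidate_universe, self.seeds,
            min_seeds=self.cfg.min_coexpressed_seeds,
            top_fraction=self.cfg.top_fraction,
            method=self.cfg.correlation_method,  # type: ignore[arg-type]
        )
        tft = mirna = set()
        if self.cfg.tft:
            tft = evidence_regulation.shared_regulator_candidates(
                io.read_gene_sets(self.cfg.tft, "tft"),
                self.candidate_universe, self.seeds, self.cfg.min_shared_seeds,
            )
        if self.cfg.mirna:
            mirna = evidence_regulation.shared_regulator_candidates(
                io.read_gene_sets(self.cfg.mirna, "mirna"),
                self.candidate_universe, self.seeds, self.cfg.min_shared_seeds,
            )
        return evidence_regulation.regulation_candidates(pool1, coexpr, tft, mirna)

    # -- module -------------------------------------------------------------

    @cached_property
    def evidence(self) -> pd.DataFrame:
        return module_discovery.combine_evidence(
            self.stream_ppin, self.stream_go, self.stream_gwas,
            self.stream_regulation, self.candidate_universe,
        )

    @cached_property
    def module_genes(self) -> set[str]:
        return module_discovery.genes_in_tiers(self.evidence, self.cfg.module_tiers)

    @cached_property
    def module(self) -> module_discovery.ModuleResult:
        result = module_discovery.extract_module(self.graph, self.module_genes)
        sub, stats = module_discovery.expand_first_neighbors(
            self.graph, result.module_nodes
        )
        result.expansion_nodes = set(sub.nodes)
        result.expansion_edges = {tuple(sorted(e)) for e in sub.edges()}
        result.coverage_node_fraction = stats["coverage_node_fraction"]
        result.coverage_edge_fraction = stats["coverage_edge_fraction"]
        return result

    @cached_property
    def randomization(self) -> dict:
        result = self.module
        k = len(result.module_nodes)
        observed = {
            "induced_edges": len(result.module_edges),
            "expansion_nodes": len(result.expansion_nodes),
            "expansion_edges": len(result.expansion_edges),
        }
        out: dict = {"k": k, "observed": observed, "p": {}, "null": {}}
        if k == 0:
            self.warnings.append("empty module: randomization test skipped")
            return out
        for stat in ("induced_edges", "expansion_nodes", "expansion_edges"):
            p, null = module_discovery.randomization_test(
                self.graph, k, observed[stat], statistic=stat,  # type: ignore[arg-type]
                n_reiterations=self.cfg.n_reiterations, rng_seed=self.cfg.rng_seed,
            )
            out["p"][stat] = p
            out["null"][stat] = null
        out["p_empirical"] = out["p"][self.cfg.statistic]
        return out

    @cached_property
    def seed_overlap_p(self) -> float:
        """Over-representation of seeds among interactome proteins."""
        return module_discovery.overlap_enrichment(
            set(self.graph.nodes), self.seeds.genes, self.cfg.overlap_universe_size
        )

    @cached_property
    def kinase(self) -> dict:
        if not self.cfg.kinase_predictions:
            return {}
        recs = kinase_substrate.read_prediction_table(self.cfg.kinase_predictions)
        if self.cfg.kinase_aliases:
            recs = kinase_substrate.apply_kinase_aliases(recs, self.cfg.kinase_aliases)
        recs = kinase_substrate.filter_gps(recs, self.cfg.gps_min_differential)
        recs = kinase_substrate.filter_networkin(recs, self.cfg.networkin_min_score)
        confirmed, n_confirmed = kinase_substrate.confirmed_in_network(
            recs, self.graph, self.module_genes
        )
        return {
            "n_filtered_predictions": len(recs),
            "confirmed": confirmed,
            "n_substrates_confirmed": n_confirmed,
        }

    # -- reporting ----------------------------------------------------------

    def report(self) -> dict:
        proto_g, proto_stats = self.protomodule
        module = self.module
        rand = self.randomization
        report = {
            "config": self.cfg.to_dict(),
            "network": {
                "n_records": len(self.records),
                "n_nodes": self.graph.number_of_nodes(),
                "n_edges": self.graph.number_of_edges(),
                "top_hubs": self.hub_table.head(10)["gene"].tolist(),
            },
            "seeds": {
                "n_seeds": len(self.seeds),
                "protomodule": {
                    k: v for k, v in proto_stats.items() if k != "degree_distribution"
                },
                "peripheral_fraction": (
                    proto_stats["n_peripheral"] / proto_stats["n_connected_nodes"]
                    if proto_stats["n_connected_nodes"] else 0.0
                ),
            },
            "evidence": {
                "n_candidate_universe": len(self.candidate_universe),
                "n_ppin": len(self.stream_ppin),
                "n_go": len(self.stream_go),
                "n_gwas": len(self.stream_gwas),
                "n_coexpression": len(self.stream_regulation),
                "tier_counts": self.evidence["tier"].value_counts().to_dict(),
                "n_supported": int((self.evidence["n_streams"] > 0).sum()),
            },
            "module": {
                "tiers": list(self.cfg.module_tiers),
                "n_nodes": len(module.module_nodes),
                "n_edges": len(module.module_edges),
                "connected": module.connected,
                "n_isolated": len(module.isolated_genes),
                "n_missing": len(module.missing_genes),
                "expansion_nodes": len(module.expansion_nodes),
                "expansion_edges": len(module.expansion_edges),
                "coverage_node_fraction": module.coverage_node_fraction,
                "coverage_edge_fraction": module.coverage_edge_fraction,
            },
            "randomization": {
                "statistic": self.cfg.statistic,
                "n_reiterations": self.cfg.n_reiterations,
                "rng_seed": self.cfg.rng_seed,
                "observed": rand["observed"],
                "p_values": rand["p"],
                "p_empirical": rand.get("p_empirical"),
            },
            "seed_overlap": {
                "universe_size": self.cfg.overlap_universe_size,
                "n_network": self.graph.number_of_nodes(),
                "n_seeds": len(self.seeds),
                "n_overlap": len(set(self.graph.nodes) & self.seeds.genes),
                "p_hypergeometric": self.seed_overlap_p,
            },
            "warnings": list(self.warnings),
        }
        if self.kinase:
            report["kinase"] = {
                "n_filtered_predictions": self.kinase["n_filtered_predictions"],
                "n_substrates_confirmed": self.kinase["n_substrates_confirmed"],
            }
        return report

    def run(self, outdir: str | Path) -> dict:
        """Execute every stage and write artifacts + report.json under outdir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        graph_core.write_edge_tsv(self.graph, outdir / "network_edges.tsv")
        self.hub_table.to_csv(outdir / "hub_ranking.tsv", sep="\t", index=False)
        proto_g, _ = self.protomodule
        graph_core.write_edge_tsv(proto_g, outdir / "protomodule_edges.tsv")
        self.evidence.to_csv(outdir / "evidence_vectors.tsv", sep="\t", index=False)
        if self.cfg.compartments:
            self.seed_enrichment.to_csv(
                outdir / "seed_enrichment.tsv", sep="\t", index=False
            )

        module = self.module
        with (outdir / "module_edges.tsv").open("w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in sorted(module.module_edges):
                fh.write(f"{a}\t{b}\n")
        rand = self.randomization
        if rand["null"]:
            null_df = pd.DataFrame(
                {stat: rand["null"][stat] for stat in sorted(rand["null"])}
            )
            null_df.to_csv(outdir / "null_distributions.tsv", sep="\t", index=False)
        if self.kinase:
            kinase_substrate.confirmed_table(self.kinase["confirmed"]).to_csv(
                outdir / "kinase_confirmed.tsv", sep="\t", index=False
            )

        report = self.report()
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=str)
        )
        return report


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    return Pipeline(cfg).run(outdir)
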