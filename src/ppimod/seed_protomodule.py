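"""Seed-gene selection and the seed-induced proto-module network.

Seeds ("DAGs", disease-associated genes) are genes carrying a genome-wide
significant GWAS signal (p < 5e-8, strict) or an OMIM entry flagged for a
known molecular association. The proto-module is the network induced by
seed-seed interactions only; seeds without any seed partner are counted as
disconnected, not drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import networkx as nx
import pandas as pd

from .graph_core import InteractionRecord, build_graph, normalize_symbol

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8

Trait = Literal["t2d", "glycemic", "obesity", "insulin", "other"]


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP/gene/trait association row (GWAS or OMIM)."""

    gene: str
    source: Literal["gwas", "omim"]
    snp_id: str = ""
    chrom: str = ""
    pos: int = 0
    trait: Trait = "other"
    p_value: Optional[float] = None
    omim_molecular_tag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        if self.source == "gwas":
            if self.p_value is None or not (0 < self.p_value <= 1):
                raise ValueError(
                    f"gwas row for {self.gene} needs a p_value in (0,1], got {self.p_value}"
                )


@dataclass
class SeedSet:
    """Selected seed genes with per-gene provenance (best p, source)."""

    genes: set[str] = field(default_factory=set)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))


def read_association_table(path: str | Path) -> list[AssociationRecord]:
    """Read the association TSV (snp_id, chrom, pos, gene, trait, p_value, source, omim_tag)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        p = row.get("p_value", "")
        records.append(
            AssociationRecord(
                gene=row["gene"],
                source=row["source"],  # type: ignore[arg-type]
                snp_id=row.get("snp_id", ""),
                chrom=row.get("chrom", ""),
                pos=int(row["pos"]) if row.get("pos", "") else 0,
                trait=row.get("trait", "other") or "other",  # type: ignore[arg-type]
                p_value=float(p) if p not in ("", "NA") else None,
                omim_molecular_tag=str(row.get("omim_tag", "")).lower()
                in ("1", "true", "yes"),
            )
        )
    return records


def select_dags(
    assoc: Iterable[AssociationRecord], p_threshold: float = GENOME_WIDE_P
) -> SeedSet:
    """Select seed genes: any GWAS row with p strictly below threshold, or any
    OMIM row with the molecular-association tag.

    Provenance keeps the minimum GWAS p per gene and whether an OMIM tag
    contributed.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0,1)")
    assoc = list(assoc)
    if not assoc:
        logger.warning("select_dags: empty association table")
        return SeedSet()
    seeds = SeedSet()
    for rec in assoc:
        qualifies = False
        if rec.source == "gwas" and rec.p_value is not None and rec.p_value < p_threshold:
            qualifies = True
        if rec.source == "omim" and rec.omim_molecular_tag:
            qualifies = True
        if not qualifies:
            continue
        seeds.genes.add(rec.gene)
        prov = seeds.provenance.setdefault(
            rec.gene, {"best_p": None, "sources": set()}
        )
        prov["sources"].add(rec.source)
        if rec.p_value is not None:
            prov["best_p"] = (
                rec.p_value
                if prov["best_p"] is None
                else min(prov["best_p"], rec.p_value)
            )
    return seeds


def build_protomodule(
    seeds: SeedSet, records: Iterable[InteractionRecord]
) -> tuple[nx.Graph, dict]:
    """Induce the seed-seed interaction network and drop isolated seeds.

    Only records with BOTH endpoints in the seed set contribute. Stats report
    connected node count, edge count, input seed count and the number of
    seeds left without any seed partner.
    """
    seed_records = [
        r for r in records if r.gene_a in seeds.genes and r.gene_b in seeds.genes
    ]
    g = build_graph(seed_records)
    # build_graph already omits degree-0 nodes (nodes come from edges only)
    stats = {
        "n_input_seeds": len(seeds),
        "n_connected_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_disconnected": len(seeds) - g.number_of_nodes(),
    }
    return g, stats


def count_peripheral(g: nx.Graph) -> int:
    """Number of peripheral (degree-1) nodes."""
    return sum(1 for _, d in g.degree() if d == 1)


def degree_distribution(g: nx.Graph) -> dict[int, int]:
    """Histogram degree -> node count; counts sum to the node count."""
    hist: dict[int, int] = {}
    for _, d in g.degree():
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))
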