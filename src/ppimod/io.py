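"""Readers for gene-set (GMT) inputs shared by several evidence streams."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

from gseapy.parser import read_gmt as _read_gmt

from .evidence_ppin_go import CompartmentAnnotation
from .evidence_regulation import GeneSetCollection
from .graph_core import normalize_symbol


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT file -> set name -> member gene symbols (normalized)."""
    raw = _read_gmt(str(path))
    return {name: [normalize_symbol(g) for g in genes] for name, genes in raw.items()}


def read_compartments(path: str | Path) -> CompartmentAnnotation:
    """Compartment annotations from GMT (term per row) or a 2-column TSV
    (gene, term). GMT is detected by >= 3 columns in the first row."""
    path = Path(path)
    first = path.read_text().splitlines()[0].split("\t")
    ann = CompartmentAnnotation()
    if len(first) >= 3 or path.suffix.lower() == ".gmt":
        for term, genes in read_gmt(path).items():
            ann.term_names[term] = term
            for g in genes:
                ann.gene_terms.setdefault(g, set()).add(term)
    else:
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, term = line.split("\t")[:2]
            ann.gene_terms.setdefault(normalize_symbol(gene), set()).add(term)
            ann.term_names.setdefault(term, term)
    return ann


def read_gene_sets(path: str | Path, kind: Literal["tft", "mirna"]) -> GeneSetCollection:
    return GeneSetCollection(
        sets={name: set(genes) for name, genes in read_gmt(path).items()},
        kind=kind,
    )
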