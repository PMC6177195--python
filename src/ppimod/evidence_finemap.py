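"""Evidence stream 3: linkage-disequilibrium statistics from phased haplotypes
and proxy-SNP fine-mapping of genes onto disease-associated loci.

LD is computed directly from phased haplotype frequencies:

    D  = pAB - pA*pB
    r2 = D^2 / (pA(1-pA) pB(1-pB))
    D' = |D| / Dmax

where ``Dmax = min(pA(1-pB), (1-pA)pB)`` for D > 0 and
``min(pA pB, (1-pA)(1-pB))`` for D < 0 (D' = 0 when D = 0). A gene is a
fine-mapping candidate when any proxy SNP (r2 above threshold, within a
position window) of any index association signal (p <= p_max) falls inside
the gene's locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph_core import normalize_symbol
from .seed_protomodule import AssociationRecord

logger = logging.getLogger(__name__)

FINEMAP_P_MAX = 1e-3
PROXY_R2 = 0.8
PROXY_WINDOW = 500_000  # bases each side of the index SNP


@dataclass(frozen=True)
class LDResult:
    snp_i: str
    snp_j: str
    r2: float
    d_prime: float


@dataclass(frozen=True)
class GeneLocus:
    """Gene body coordinates, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.gene}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes: (2*samples) x SNPs matrix of 0/1 alleles."""

    snp_ids: list[str]
    chroms: list[str]
    positions: np.ndarray  # 1-based, int64
    alleles: np.ndarray  # (n_haplotypes, n_snps) of {0,1}
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError("duplicate snp_ids in panel")
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.snp_ids):
            raise ValueError("alleles matrix shape does not match snp_ids")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        for chrom in set(self.chroms):
            pos = self.positions[[c == chrom for c in self.chroms]]
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.alleles[:, self._index[snp_id]]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def _ld_from_columns(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(r2, d_prime) from two 0/1 haplotype columns."""
    pA = float(a.mean())
    pB = float(b.mean())
    pAB = float((a & b).mean())
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return r2, 0.0
    return r2, abs(D) / dmax


def ld_statistics(panel: HaplotypePanel, snp_i: str, snp_j: str) -> LDResult:
    """Pairwise r2 and D' between two same-chromosome polymorphic SNPs."""
    for s in (snp_i, snp_j):
        if s not in panel:
            raise KeyError(f"SNP {s} not in panel")
        col = panel.column(s)
        if col.min() == col.max():
            raise ValueError(f"SNP {s} is monomorphic")
    ci = panel.chroms[panel._index[snp_i]]
    cj = panel.chroms[panel._index[snp_j]]
    if ci != cj:
        raise ValueError(f"SNPs {snp_i} ({ci}) and {snp_j} ({cj}) on different chromosomes")
    r2, dp = _ld_from_columns(panel.column(snp_i), panel.column(snp_j))
    return LDResult(snp_i, snp_j, r2, dp)


def proxy_snps(
    panel: HaplotypePanel,
    index_snps: Sequence[str],
    r2_threshold: float = PROXY_R2,
    window: int = PROXY_WINDOW,
) -> dict[str, set[str]]:
    """Same-chromosome SNPs within ``window`` bases and r2 >= threshold of each
    index SNP. The index SNP is always its own proxy; index SNPs absent from
    the panel are skipped with a warning."""
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0,1]")
    out: dict[str, set[str]] = {}
    skipped = []
    for idx in index_snps:
        if idx not in panel:
            skipped.append(idx)
            continue
        i = panel._index[idx]
        proxies = {idx}
        icol = panel.column(idx)
        polymorphic_index = icol.min() != icol.max()
        for j, sid in enumerate(panel.snp_ids):
            if j == i or panel.chroms[j] != panel.chroms[i]:
                continue
            if abs(int(panel.positions[j]) - int(panel.positions[i])) > window:
                continue
            jcol = panel.alleles[:, j]
            if not polymorphic_index or jcol.min() == jcol.max():
                continue
            r2, _ = _ld_from_columns(icol, jcol)
            if r2 >= r2_threshold:
                proxies.add(sid)
        out[idx] = proxies
    if skipped:
        logger.warning(
            "proxy_snps: %d index SNP(s) absent from panel (e.g. %s)",
            len(skipped),
            skipped[:3],
        )
    return out


def finemap_candidates(
    loci: Iterable[GeneLocus],
    assoc: Iterable[AssociationRecord],
    panel: HaplotypePanel,
    p_max: float = FINEMAP_P_MAX,
    r2_threshold: float = PROXY_R2,
    window: int = PROXY_WINDOW,
) -> set[str]:
    """Genes whose locus contains a proxy of any association signal with
    p <= p_max (inclusive). Genome-wide significant signals are included since
    their p-values satisfy the threshold."""
    index_records = [
        r for r in assoc if r.p_value is not None and r.p_value <= p_max and r.snp_id
    ]
    proxies = proxy_snps(
        panel, [r.snp_id for r in index_records], r2_threshold, window
    )
    # proxy SNP id -> genomic coordinates from the panel
    hits: set[tuple[str, int]] = set()
    for snp_set in proxies.values():
        for sid in snp_set:
            j = panel._index[sid]
            hits.add((panel.chroms[j], int(panel.positions[j])))
    kept = set()
    for locus in loci:
        if any(locus.contains(chrom, pos) for chrom, pos in hits):
            kept.add(locus.gene)
    return kept


def ld_blocks(
    panel: HaplotypePanel, strong_dprime: float = 0.98
) -> list[tuple[int, int]]:
    """Greedy LD-block partition (simplified surrogate for the Gabriel
    confidence-interval method).

    Walking each chromosome in position order, a block is extended while the
    candidate SNP has pairwise D' >= ``strong_dprime`` with EVERY SNP already
    in the block. Returns maximal non-overlapping half-open column-index
    intervals (start, end) with end - start >= 2; monomorphic SNPs break
    blocks.
    """
    blocks: list[tuple[int, int]] = []
    n = panel.n_snps
    j = 0
    while j < n:
        chrom = panel.chroms[j]
        start = j
        members = [j]
        col_start = panel.alleles[:, j]
        if col_start.min() == col_start.max():
            j += 1
            continue
        k = j + 1
        while k < n and panel.chroms[k] == chrom:
            ck = panel.alleles[:, k]
            if ck.min() == ck.max():
                break
            ok = all(
                _ld_from_columns(panel.alleles[:, m], ck)[1] >= strong_dprime
                for m in members
            )
            if not ok:
                break
            members.append(k)
            k += 1
        if len(members) >= 2:
            blocks.append((start, k))
        j = k if k > j + 1 else j + 1
    return blocks


# ---------------------------------------------------------------------------
# IO


def read_loci_table(path: str | Path) -> list[GeneLocus]:
    """BED-like TSV read as 1-BASED INCLUSIVE coordinates (header keyword
    ``start_1based`` flags the divergence from 0-based half-open BED).

    Columns: chrom, start_1based, end, gene.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start_1based", "end", "gene"}
    if not required <= set(df.columns):
        raise ValueError(f"loci table needs columns {sorted(required)}")
    return [
        GeneLocus(normalize_symbol(r.gene), str(r.chrom), int(r.start_1based), int(r.end))
        for r in df.itertuples()
    ]


def read_haplotype_tsv(matrix_path: str | Path, snp_map_path: str | Path) -> HaplotypePanel:
    """Plain-text haplotype matrix (rows = haplotypes, columns = SNP ids) with
    a sidecar SNP map TSV (snp_id, chrom, pos)."""
    mat = pd.read_csv(matrix_path, sep="\t")
    snp_map = pd.read_csv(snp_map_path, sep="\t", dtype={"chrom": str})
    ids = list(mat.columns)
    mapped = snp_map.set_index("snp_id")
    missing = [s for s in ids if s not in mapped.index]
    if missing:
        raise ValueError(f"SNP map missing entries for {missing[:5]}")
    return HaplotypePanel(
        snp_ids=ids,
        chroms=[str(mapped.loc[s, "chrom"]) for s in ids],
        positions=np.array([int(mapped.loc[s, "pos"]) for s in ids]),
        alleles=mat.to_numpy(dtype=np.int8),
    )


def read_haplotype_vcf(path: str | Path) -> tuple[HaplotypePanel, int]:
    """Read phased biallelic records from a plain uncompressed VCF.

    Only the subset of VCF needed for a haplotype panel is handled: one ALT
    allele, phased GT as the first FORMAT field. Returns the panel and the
    count of rejected (non-biallelic) records.
    """
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    columns: list[list[int]] = []
    rejected = 0
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        chrom, pos, sid, _ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
        if "," in alt or alt in (".", ""):
            rejected += 1
            continue
        alleles: list[int] = []
        for sample in parts[9:]:
            gt = sample.split(":", 1)[0]
            if "|" not in gt:
                raise ValueError(f"unphased genotype {gt!r} for SNP {sid}")
            alleles.extend(int(a) for a in gt.split("|"))
        snp_ids.append(sid)
        chroms.append(chrom)
        positions.append(pos)
        columns.append(alleles)
    panel = HaplotypePanel(
        snp_ids=snp_ids,
        chroms=chroms,
        positions=np.array(positions),
        alleles=np.array(columns, dtype=np.int8).T,
    )
    if rejected:
        logger.warning("read_haplotype_vcf: rejected %d non-biallelic records", rejected)
    return panel, rejected
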