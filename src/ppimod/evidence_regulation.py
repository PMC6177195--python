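"""Evidence stream 4: regulatory-variant pool and coexpression / shared-regulator pool.

Pool 1 holds candidates whose locus carries a regulatory variant with a
category-1 flag (high-confidence eQTL + binding evidence). Pool 2 holds
candidates that are mutually ranked in the top fraction of coexpressed
partners with at least ``min_seeds`` seed genes AND share a transcription
factor / miRNA target set with at least ``min_shared_seeds`` seeds. The
stream's result is the nonredundant union of the two pools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .graph_core import normalize_symbol
from .seed_protomodule import SeedSet

logger = logging.getLogger(__name__)

REGULOME_CATEGORIES = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c", "3a", "3b", "4", "5", "6", "7",
)


@dataclass
class GeneSetCollection:
    """Named regulator target sets (TFT or miRNA)."""

    sets: dict[str, set[str]]
    kind: Literal["tft", "mirna"] = "tft"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values backed by a DataFrame."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.shape[1] < 3:
            raise ValueError("need >= 3 samples for correlation")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = [normalize_symbol(g) for g in df.index]
        return cls(df)


def read_flag_table(path: str | Path) -> dict[str, str]:
    """TSV (gene, category) -> gene -> regulatory category label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {normalize_symbol(g): str(c) for g, c in zip(df["gene"], df["category"])}


def regulome_pool(candidates: set[str], flags: dict[str, str]) -> set[str]:
    """Candidates whose best regulatory category is category 1 (1a..1f)."""
    bad = sorted(
        f"{g}: {c}" for g, c in flags.items() if c not in REGULOME_CATEGORIES
    )
    if bad:
        raise ValueError(f"unknown regulatory categories: {bad[:5]}")
    return {g for g in candidates if flags.get(g, "").startswith("1")}


def _correlation_matrix(
    expr: ExpressionMatrix,
    method: Literal["pearson", "spearman"] = "pearson",
    log_transform: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Gene-gene correlation over samples; constant genes are dropped with a
    warning (their correlation is undefined)."""
    x = expr.values.to_numpy(dtype=float)
    if log_transform:
        x = np.log1p(x)
    genes = expr.genes
    keep = x.std(axis=1) > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("excluding %d constant-expression gene(s): %s",
                       len(dropped), dropped[:5])
        x = x[keep]
        genes = [g for g, k in zip(genes, keep) if k]
    if method == "spearman":
        x = np.apply_along_axis(lambda row: pd.Series(row).rank().to_numpy(), 1, x)
    corr = np.corrcoef(x)
    return corr, genes


def mutual_rank_pairs(
    expr: ExpressionMatrix,
    a_set: set[str],
    b_set: set[str],
    top_fraction: float = 0.01,
    method: Literal["pearson", "spearman"] = "pearson",
    log_transform: bool = True,
) -> set[tuple[str, str]]:
    """Pairs (a, b) with a in a_set, b in b_set, each inside the other's top
    ``ceil(top_fraction * (G-1))`` coexpression partners.

    Ranking is by descending correlation against ALL other genes in the
    matrix; boundary ties are all included. Output pairs are ordered (a, b)
    with a != b; symmetric membership is guaranteed by the mutuality rule.
    """
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0,1)")
    corr, genes = _correlation_matrix(expr, method, log_transform)
    gindex = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    if G < 2:
        return set()
    top_k = math.ceil(top_fraction * (G - 1))

    # per-gene correlation cutoff: value of the top_k-th best partner; ties at
    # the boundary are included
    np.fill_diagonal(corr, -np.inf)
    partner_sorted = np.sort(corr, axis=1)[:, ::-1]
    cutoffs = partner_sorted[:, top_k - 1]

    pairs: set[tuple[str, str]] = set()
    for a in sorted(a_set & gindex.keys()):
        i = gindex[a]
        for b in sorted(b_set & gindex.keys()):
            if a == b:
                continue
            j = gindex[b]
            if corr[i, j] >= cutoffs[i] and corr[j, i] >= cutoffs[j]:
                pairs.add((a, b))
    return pairs


def coexpressed_with_seeds(
    expr: ExpressionMatrix,
    candidates: set[str],
    seeds: SeedSet,
    min_seeds: int = 3,
    top_fraction: float = 0.01,
    method: Literal["pearson", "spearman"] = "pearson",
) -> set[str]:
    """Candidates forming mutual top-fraction coexpression pairs with at least
    ``min_seeds`` distinct seeds present in the matrix."""
    present = seeds.genes & set(expr.genes)
    absent = len(seeds.genes) - len(present)
    if absent:
        logger.info("coexpressed_with_seeds: %d seed(s) absent from matrix", absent)
    pairs = mutual_rank_pairs(expr, candidates, present, top_fraction, method)
    counts: dict[str, int] = {}
    for a, _b in pairs:
        counts[a] = counts.get(a, 0) + 1
    return {g for g, c in counts.items() if c >= min_seeds}


def shared_regulator_candidates(
    collection: GeneSetCollection,
    candidates: set[str],
    seeds: SeedSet,
    min_shared_seeds: int = 3,
) -> set[str]:
    """Candidates sharing a single regulator target set with >= min_shared_seeds seeds."""
    kept: set[str] = set()
    for members in collection.sets.values():
        if len(members & seeds.genes) >= min_shared_seeds:
            kept |= members & candidates
    return kept


def regulation_candidates(
    pool1: set[str], coexpr: set[str], tft: set[str], mirna: set[str]
) -> set[str]:
    """Nonredundant union: regulatory-variant pool plus coexpressed candidates
    that also share a TF and/or miRNA target set."""
    pool2 = coexpr & (tft | mirna)
    return pool1 | pool2
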