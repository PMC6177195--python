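"""Evidence streams 1 and 2: topological proximity to seeds, and
compartment-restricted colocalization via hypergeometric enrichment with
Benjamini-Hochberg correction.

A candidate qualifies by proximity if it physically interacts with at least
``min_interactors`` distinct seeds; it qualifies by colocalization if, for
some cellular compartment significantly enriched among the seeds, it
interacts with at least that many seeds annotated to that compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graph_core import InteractionRecord
from .seed_protomodule import SeedSet

logger = logging.getLogger(__name__)


@dataclass
class CompartmentAnnotation:
    """gene -> set of compartment term ids, with optional term labels."""

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, terms in self.gene_terms.items() if term in terms}

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.gene_terms.values():
            out |= terms
        return out

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.gene_terms)


def _seed_neighbor_counts(
    records: Iterable[InteractionRecord], seed_genes: set[str]
) -> dict[str, set[str]]:
    """For every gene appearing in the records, the distinct seeds it touches."""
    neighbors: dict[str, set[str]] = {}
    for r in records:
        if r.gene_a == r.gene_b:
            continue
        if r.gene_b in seed_genes:
            neighbors.setdefault(r.gene_a, set()).add(r.gene_b)
        if r.gene_a in seed_genes:
            neighbors.setdefault(r.gene_b, set()).add(r.gene_a)
    return neighbors


def ppin_proximity_candidates(
    records: Iterable[InteractionRecord],
    query_genes: set[str],
    seeds: SeedSet,
    min_interactors: int = 3,
) -> set[str]:
    """Genes from ``query_genes`` interacting with >= min_interactors distinct seeds."""
    if min_interactors < 1:
        raise ValueError("min_interactors must be >= 1")
    neighbors = _seed_neighbor_counts(records, seeds.genes)
    return {
        g
        for g in query_genes
        if len(neighbors.get(g, ())) >= min_interactors
    }


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= n <= N) or not (0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = list(p_values)
    if not p:
        return []
    if any(not (0 < x <= 1) for x in p):
        raise ValueError("p-values must be in (0,1]")
    return list(multipletests(p, method="fdr_bh")[1])


def compartment_enrichment(
    query: set[str],
    ann: CompartmentAnnotation,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each compartment term in the query.

    The universe defaults to all annotated genes in ``ann``. One row per term
    with at least one annotated query gene; BH correction across all tested
    terms; sorted by adjusted p ascending (ties by term id).

    Columns: term, name, k, n, K, N, p_raw, p_adj.
    """
    if universe is None:
        universe = ann.annotated_genes
    if not universe:
        raise ValueError("empty annotation universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for term in sorted(ann.terms):
        members = ann.genes_for_term(term) & universe
        k = len(members & query)
        if k < 1:
            continue
        K = len(members)
        rows.append(
            {
                "term": term,
                "name": ann.term_names.get(term, term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_raw": hypergeometric_upper_tail(k, n, K, N),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "name", "k", "n", "K", "N", "p_raw"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p_raw"].tolist())
        df = df.sort_values(["p_adj", "p_raw", "term"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        df["p_adj"] = []
    return df


def enriched_terms(enrichment: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Term ids with BH-adjusted p below alpha."""
    if not len(enrichment):
        return []
    return enrichment.loc[enrichment["p_adj"] < alpha, "term"].tolist()


def colocalization_candidates(
    candidates: set[str],
    seeds: SeedSet,
    ann: CompartmentAnnotation,
    records: Iterable[InteractionRecord],
    enriched: Sequence[str],
    min_seed_interactors: int = 3,
) -> set[str]:
    """Candidates with >= min_seed_interactors interacting seeds annotated to
    some single enriched compartment term (union over terms, deduplicated)."""
    neighbors = _seed_neighbor_counts(list(records), seeds.genes)
    kept: set[str] = set()
    for term in enriched:
        term_seeds = ann.genes_for_term(term) & seeds.genes
        if not term_seeds:
            continue
        for g in candidates:
            if len(neighbors.get(g, set()) & term_seeds) >= min_seed_interactors:
                kept.add(g)
    return kept
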