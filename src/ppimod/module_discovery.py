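"""Evidence tiering, module extraction, first-neighbor expansion and the
node-randomization significance test.

A gene's confidence tier counts how many of the four independent evidence
streams (seed proximity in the interactome, compartment colocalization,
fine-mapping, expression regulation) support it: high (>= 3), moderate (2),
weak (1). The disease module is the subgraph of the interactome induced by
the supported genes; its robustness is assessed by drawing uniform random
node subsets of the same size and comparing a subgraph statistic, with the
add-one empirical p-value estimator (p is never exactly zero).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .evidence_ppin_go import hypergeometric_upper_tail

Tier = Literal["high", "moderate", "weak", "none"]
Statistic = Literal["induced_edges", "expansion_edges", "expansion_nodes"]

STREAMS = ("ppin", "go", "gwas", "coexpression")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG stream derived from one top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(stage.encode()),))
    )


def tier_of(n_streams: int) -> Tier:
    if n_streams >= 3:
        return "high"
    return {2: "moderate", 1: "weak", 0: "none"}[n_streams]


def combine_evidence(
    ppin: set[str],
    go: set[str],
    gwas: set[str],
    coexpr: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """One evidence vector per universe gene, lexicographic order.

    Columns: gene, ppin, go, gwas, coexpression (bool), n_streams, tier.
    """
    streams = {"ppin": ppin, "go": go, "gwas": gwas, "coexpression": coexpr}
    for name, s in streams.items():
        if not s <= universe:
            raise ValueError(f"{name} evidence set is not a subset of the universe")
    rows = []
    for gene in sorted(universe):
        flags = {name: gene in s for name, s in streams.items()}
        n = sum(flags.values())
        rows.append({"gene": gene, **flags, "n_streams": n, "tier": tier_of(n)})
    return pd.DataFrame(rows, columns=["gene", *STREAMS, "n_streams", "tier"])


def genes_in_tiers(evidence: pd.DataFrame, tiers: Sequence[Tier] = ("high", "moderate")) -> set[str]:
    return set(evidence.loc[evidence["tier"].isin(tiers), "gene"])


@dataclass
class ModuleResult:
    """Extracted module, its expansion and randomization-test outcome."""

    module_nodes: set[str]
    module_edges: set[tuple[str, str]]
    connected: bool
    isolated_genes: set[str] = field(default_factory=set)
    missing_genes: set[str] = field(default_factory=set)
    expansion_nodes: set[str] = field(default_factory=set)
    expansion_edges: set[tuple[str, str]] = field(default_factory=set)
    coverage_node_fraction: float = 0.0
    coverage_edge_fraction: float = 0.0
    p_empirical: float | None = None
    n_reiterations: int = 0
    rng_seed: int | None = None
    null_statistics: np.ndarray | None = None


def extract_module(iren: nx.Graph, module_genes: set[str]) -> ModuleResult:
    """Induce the subgraph of the interactome on the supported genes.

    Isolated (degree-0) genes are reported separately and excluded from the
    connected-module node set; ``connected`` states whether the non-isolated
    part forms a single connected component.
    """
    present = set(module_genes) & set(iren.nodes)
    sub = iren.subgraph(present)
    isolated = {n for n in present if sub.degree(n) == 0}
    core = present - isolated
    core_sub = iren.subgraph(core)
    connected = bool(core) and nx.is_connected(core_sub)
    return ModuleResult(
        module_nodes=core,
        module_edges={tuple(sorted(e)) for e in core_sub.edges()},
        connected=connected,
        isolated_genes=isolated,
        missing_genes=set(module_genes) - present,
    )


def expand_first_neighbors(
    iren: nx.Graph, module_nodes: set[str]
) -> tuple[nx.Graph, dict]:
    """Augment the module with all direct neighbors and induce the subgraph.

    Coverage fractions are measured against the full interactome.
    """
    if not module_nodes <= set(iren.nodes):
        raise ValueError("module nodes must belong to the interactome")
    expanded = set(module_nodes)
    for n in module_nodes:
        expanded.update(iren.neighbors(n))
    sub = iren.subgraph(expanded)
    stats = {
        "n_nodes": sub.number_of_nodes(),
        "n_edges": sub.number_of_edges(),
        "coverage_node_fraction": sub.number_of_nodes() / iren.number_of_nodes(),
        "coverage_edge_fraction": sub.number_of_edges() / iren.number_of_edges(),
    }
    return sub, stats


def _adjacency(iren: nx.Graph) -> tuple[np.ndarray, list[str]]:
    nodes = sorted(iren.nodes)
    a = nx.to_numpy_array(iren, nodelist=nodes, dtype=bool)
    return a, nodes


def subset_statistic(adj: np.ndarray, idx: np.ndarray, statistic: Statistic) -> int:
    """Statistic of a node subset over a boolean adjacency matrix."""
    if statistic == "induced_edges":
        return int(adj[np.ix_(idx, idx)].sum() // 2)
    mask = np.zeros(adj.shape[0], dtype=bool)
    mask[idx] = True
    neighbor = adj[idx].any(axis=0)
    expanded = mask | neighbor
    if statistic == "expansion_nodes":
        return int(expanded.sum())
    if statistic == "expansion_edges":
        sub = adj[np.ix_(np.flatnonzero(expanded), np.flatnonzero(expanded))]
        return int(sub.sum() // 2)
    raise ValueError(f"unknown statistic {statistic!r}")


def randomization_test(
    iren: nx.Graph,
    k: int,
    observed: int,
    statistic: Statistic = "induced_edges",
    n_reiterations: int = 10_000,
    rng_seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Empirical p-value of an observed subgraph statistic under uniform
    random k-node subsets of the interactome.

    p = (1 + #{draws with statistic >= observed}) / (1 + n_reiterations)
    (add-one estimator). Reproducible bit-for-bit for a given seed and
    canonical (sorted-node) adjacency.
    """
    n = iren.number_of_nodes()
    if not (0 < k <= n):
        raise ValueError(f"k={k} out of range for a {n}-node graph")
    if n_reiterations < 1:
        raise ValueError("n_reiterations must be >= 1")
    adj, _nodes = _adjacency(iren)
    rng = stage_rng(rng_seed, "randomization_test")
    null = np.empty(n_reiterations, dtype=np.int64)
    for i in range(n_reiterations):
        idx = rng.choice(n, size=k, replace=False)
        null[i] = subset_statistic(adj, idx, statistic)
    p = (1 + int((null >= observed).sum())) / (1 + n_reiterations)
    return p, null


def overlap_enrichment(set_a: set[str], set_b: set[str], universe_size: int) -> float:
    """Upper-tail hypergeometric probability of the observed overlap between
    two gene sets drawn from a universe of the given size."""
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("set sizes exceed universe size")
    return hypergeometric_upper_tail(
        k=len(set_a & set_b), n=len(set_a), K=len(set_b), N=universe_size
    )
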