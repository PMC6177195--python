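"""Interaction-table parsing, filtering, graph assembly and hub ranking.

The interactome is represented as a simple undirected :class:`networkx.Graph`
over normalized gene symbols. Raw interaction records may contain self-pairs,
duplicates (in either orientation) and mixed-case identifiers; ``build_graph``
canonicalizes all of that. Hub ranking mirrors the betweenness/degree
("connectivity") centrality ranking used in interactome studies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

EvidenceClass = Literal["binary", "complex", "unknown"]


def normalize_symbol(raw: str) -> str:
    """Normalize a gene identifier to a canonical HUGO-style symbol.

    Uppercases, trims, and collapses internal whitespace. Idempotent.
    Raises ``ValueError`` on empty input.
    """
    sym = _WS.sub(" ", str(raw).strip()).upper()
    if not sym:
        raise ValueError("empty gene symbol")
    return sym


@dataclass(frozen=True)
class InteractionRecord:
    """One raw protein-protein interaction (self-pairs permitted here)."""

    gene_a: str
    gene_b: str
    source_db: str = ""
    evidence_class: EvidenceClass = "unknown"

    @classmethod
    def make(
        cls,
        gene_a: str,
        gene_b: str,
        source_db: str = "",
        evidence_class: str = "unknown",
    ) -> "InteractionRecord":
        if evidence_class not in ("binary", "complex", "unknown"):
            evidence_class = "unknown"
        return cls(
            normalize_symbol(gene_a),
            normalize_symbol(gene_b),
            str(source_db),
            evidence_class,  # type: ignore[arg-type]
        )


@dataclass
class ExclusionList:
    """Symbols removed for nonspecific interactions (chaperones, RPL*, UBC...).

    ``exact_symbols`` match whole symbols; ``prefix_rules`` match symbol
    prefixes. Matching is case-insensitive because symbols are normalized.
    """

    exact_symbols: set[str] = field(default_factory=set)
    prefix_rules: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.exact_symbols = {normalize_symbol(s) for s in self.exact_symbols}
        self.prefix_rules = {normalize_symbol(p) for p in self.prefix_rules}

    def matches(self, symbol: str) -> bool:
        sym = normalize_symbol(symbol)
        if sym in self.exact_symbols:
            return True
        return any(sym.startswith(p) for p in self.prefix_rules)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExclusionList":
        """Read one symbol or ``PREFIX*`` per line; ``#`` starts a comment."""
        exact: set[str] = set()
        prefixes: set[str] = set()
        for line in Path(path).read_text().splitlines():
            entry = line.split("#", 1)[0].strip()
            if not entry:
                continue
            if entry.endswith("*"):
                prefixes.add(entry[:-1])
            else:
                exact.add(entry)
        return cls(exact_symbols=exact, prefix_rules=prefixes)


def read_interaction_table(
    path: str | Path, dialect: Literal["tsv", "sif"] = "tsv"
) -> list[InteractionRecord]:
    """Read interaction records from a TSV edge table or a SIF file.

    TSV rows are ``gene_a<TAB>gene_b[<TAB>source_db[<TAB>evidence_class]]``
    with an optional header (detected by a first cell named ``gene_a``).
    SIF rows are ``source relation target [target ...]``; one record is
    emitted per (source, target) pair. Row order is preserved.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    lines = path.read_text().splitlines()
    if not lines:
        logger.warning("empty interaction file: %s", path)
        return records
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if dialect == "tsv":
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and parts[0].strip().lower() in ("gene_a", "genea", "source"):
                continue
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}: malformed TSV row at line {lineno}: {line!r}")
            records.append(
                InteractionRecord.make(
                    parts[0],
                    parts[1],
                    parts[2].strip() if len(parts) > 2 else "",
                    parts[3].strip() if len(parts) > 3 else "unknown",
                )
            )
        elif dialect == "sif":
            parts = line.split()
            if len(parts) == 1:
                raise ValueError(f"{path}: malformed SIF row at line {lineno}: {line!r}")
            source, _relation, targets = parts[0], parts[1], parts[2:]
            if not targets:
                raise ValueError(f"{path}: SIF row without targets at line {lineno}")
            for t in targets:
                records.append(InteractionRecord.make(source, t, source_db="sif"))
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown dialect {dialect!r}")
    return records


def map_orthologs(
    ids: Sequence[str],
    ortholog_map: dict[str, list[tuple[str, float]]],
    policy: Literal["best_score", "all"] = "best_score",
) -> tuple[list[str], dict]:
    """Map source protein ids to human gene symbols via an ortholog table.

    ``best_score`` keeps one symbol per id (highest confidence score,
    lexicographically smallest symbol on ties); ``all`` keeps every target.
    Unmapped ids are dropped and counted in the returned report.
    """
    mapped: list[str] = []
    unmapped = 0
    for pid in ids:
        targets = ortholog_map.get(pid)
        if not targets:
            unmapped += 1
            continue
        normalized = [(normalize_symbol(sym), float(score)) for sym, score in targets]
        if policy == "best_score":
            best = min(normalized, key=lambda t: (-t[1], t[0]))
            mapped.append(best[0])
        else:
            mapped.extend(sorted(sym for sym, _ in normalized))
    return mapped, {"n_input": len(ids), "n_mapped": len(mapped), "n_unmapped": unmapped}


def filter_nonspecific(
    records: Iterable[InteractionRecord], excl: ExclusionList
) -> list[InteractionRecord]:
    """Drop records where either endpoint matches the exclusion list."""
    return [
        r
        for r in records
        if not (excl.matches(r.gene_a) or excl.matches(r.gene_b))
    ]


def build_graph(
    records: Iterable[InteractionRecord],
    binary_only: bool = False,
) -> nx.Graph:
    """Assemble a simple undirected graph from interaction records.

    Self-pairs are dropped; duplicate edges (in either orientation) collapse.
    Nodes are only the endpoints of surviving edges, so the result is
    independent of record order. With ``binary_only`` every record whose
    evidence class is not ``binary`` is ignored.
    """
    g = nx.Graph()
    for r in records:
        if binary_only and r.evidence_class != "binary":
            continue
        a, b = normalize_symbol(r.gene_a), normalize_symbol(r.gene_b)
        if a == b:
            continue
        g.add_edge(a, b)
    return g


def graph_from_pairs(pairs: Iterable[tuple[str, str]]) -> nx.Graph:
    """Convenience: build a graph from bare (gene, gene) pairs."""
    return build_graph([InteractionRecord.make(a, b) for a, b in pairs])


def canonical_edges(g: nx.Graph) -> list[tuple[str, str]]:
    """Edges as sorted pairs in lexicographic order (reproducible emission)."""
    return sorted(tuple(sorted(e)) for e in g.edges())


def write_edge_tsv(g: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in canonical_edges(g):
            fh.write(f"{a}\t{b}\n")


def betweenness_centrality(g: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness per node.

    Unnormalized values are the sum over unordered node pairs of the fraction
    of shortest paths passing through the node; pairs in different components
    contribute zero.
    """
    return nx.betweenness_centrality(g, normalized=normalized)


def rank_hubs(
    g: nx.Graph,
    metric: Literal["betweenness", "degree"] = "degree",
    normalized_betweenness: bool = False,
) -> pd.DataFrame:
    """Rank nodes by a centrality metric.

    Sorted by the chosen metric descending; ties broken by the other metric
    descending, then lexicographically by symbol. Returns a DataFrame with
    columns gene, betweenness, degree, rank (1 = top).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot rank hubs of an empty graph")
    btw = betweenness_centrality(g, normalized=normalized_betweenness)
    rows = [
        {"gene": n, "betweenness": btw[n], "degree": g.degree(n)} for n in g.nodes()
    ]
    df = pd.DataFrame(rows)
    if metric == "degree":
        keys = ["degree", "betweenness", "gene"]
    elif metric == "betweenness":
        keys = ["betweenness", "degree", "gene"]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    df = df.sort_values(
        keys, ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df
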