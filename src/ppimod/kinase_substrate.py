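"""Kinase-substrate prediction filtering and network confirmation.

Predictions from motif-based tools come with tool-specific scores: GPS rows
carry a score and a cutoff (kept when score - cutoff >= 1.0, inclusive) and
NetworKIN rows carry a single score (kept when strictly > 2.0). A filtered
prediction is "confirmed" when the kinase-substrate pair is also a physical
edge of the interactome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

import networkx as nx
import pandas as pd

from .graph_core import normalize_symbol

GPS_MIN_DIFFERENTIAL = 1.0
NETWORKIN_MIN_SCORE = 2.0

_SITE = re.compile(r"^[A-Z]\d+$")


@dataclass(frozen=True)
class KinasePredictionRecord:
    substrate: str
    site: str  # residue letter + 1-based position, e.g. Y83
    kinase: str
    source: Literal["gps", "networkin", "phosphosite"]
    gps_score: Optional[float] = None
    gps_cutoff: Optional[float] = None
    networkin_score: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrate", normalize_symbol(self.substrate))
        object.__setattr__(self, "kinase", normalize_symbol(self.kinase))
        if not _SITE.match(self.site) or int(self.site[1:]) < 1:
            raise ValueError(f"bad site {self.site!r} for {self.substrate}")


def read_prediction_table(path: str | Path) -> list[KinasePredictionRecord]:
    """TSV with header: substrate, site, kinase, source, gps_score, gps_cutoff, networkin_score."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples():
        out.append(
            KinasePredictionRecord(
                substrate=r.substrate,
                site=r.site,
                kinase=r.kinase,
                source=r.source,  # type: ignore[arg-type]
                gps_score=float(r.gps_score) if r.gps_score else None,
                gps_cutoff=float(r.gps_cutoff) if r.gps_cutoff else None,
                networkin_score=float(r.networkin_score) if r.networkin_score else None,
            )
        )
    return out


def filter_gps(
    records: Iterable[KinasePredictionRecord],
    min_differential: float = GPS_MIN_DIFFERENTIAL,
) -> list[KinasePredictionRecord]:
    """Keep GPS rows with differential score (score - cutoff) >= min_differential,
    inclusive; rows from other sources pass through untouched."""
    records = list(records)
    bad = [
        r
        for r in records
        if r.source == "gps" and (r.gps_score is None or r.gps_cutoff is None)
    ]
    if bad:
        raise ValueError(
            f"GPS rows missing score/cutoff: {[(r.substrate, r.site, r.kinase) for r in bad[:5]]}"
        )
    return [
        r
        for r in records
        if r.source != "gps" or (r.gps_score - r.gps_cutoff >= min_differential)
    ]


def filter_networkin(
    records: Iterable[KinasePredictionRecord],
    min_score: float = NETWORKIN_MIN_SCORE,
) -> list[KinasePredictionRecord]:
    """Keep NetworKIN rows with score strictly greater than min_score; rows
    from other sources pass through untouched."""
    records = list(records)
    bad = [r for r in records if r.source == "networkin" and r.networkin_score is None]
    if bad:
        raise ValueError(
            f"NetworKIN rows missing score: {[(r.substrate, r.site, r.kinase) for r in bad[:5]]}"
        )
    return [
        r
        for r in records
        if r.source != "networkin" or r.networkin_score > min_score
    ]


def apply_kinase_aliases(
    records: Iterable[KinasePredictionRecord], aliases: dict[str, str]
) -> list[KinasePredictionRecord]:
    """Map kinase family labels to gene symbols (e.g. AMPKA1 -> PRKAA1) before
    network lookup."""
    norm = {normalize_symbol(k): normalize_symbol(v) for k, v in aliases.items()}
    return [
        KinasePredictionRecord(
            substrate=r.substrate,
            site=r.site,
            kinase=norm.get(r.kinase, r.kinase),
            source=r.source,
            gps_score=r.gps_score,
            gps_cutoff=r.gps_cutoff,
            networkin_score=r.networkin_score,
        )
        for r in records
    ]


def confirmed_in_network(
    records: Iterable[KinasePredictionRecord],
    g: nx.Graph,
    substrates_of_interest: set[str],
) -> tuple[dict[str, set[str]], int]:
    """Kinase-substrate pairs confirmed as physical interactome edges.

    Returns (substrate -> set of confirmed kinases) and the number of
    substrates of interest (that are interactome nodes) with at least one
    confirmation. Records should already be threshold-filtered.
    """
    confirmed: dict[str, set[str]] = {}
    for r in records:
        if g.has_edge(r.kinase, r.substrate):
            confirmed.setdefault(r.substrate, set()).add(r.kinase)
    eligible = substrates_of_interest & set(g.nodes)
    n_confirmed = sum(1 for s in eligible if confirmed.get(s))
    return confirmed, n_confirmed


def confirmed_table(confirmed: dict[str, set[str]]) -> pd.DataFrame:
    rows = [
        {"substrate": s, "kinase": k}
        for s in sorted(confirmed)
        for k in sorted(confirmed[s])
    ]
    return pd.DataFrame(rows, columns=["substrate", "kinase"])
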