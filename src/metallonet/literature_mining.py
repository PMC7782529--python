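"""Protein–disease association scoring from an abstract corpus.

Association is measured by pointwise mutual information over document
co-occurrence: for a protein x and the disease term y,

    PMI(x, y) = log2( n_xy · N / (n_x · n_y) )

with N total documents and n_x, n_y, n_xy document counts (one count per
document regardless of repeat mentions).  Protein symbols match as exact
uppercase tokens — gene symbols collide with English words too often for
case-insensitive matching — while disease terms match case-insensitively as
phrases.  Proteins are called disease-associated when they co-occur with the
disease in at least ``min_docs`` abstracts (default 3) with positive PMI.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .hub_detection import Hub

TOKEN_RE = re.compile(r"[A-Za-z0-9'-]+")


@dataclass(frozen=True)
class CoOccurrence:
    symbol: str
    n_total: int      # N: total documents
    n_x: int          # docs mentioning the protein
    n_y: int          # docs mentioning the disease term
    n_xy: int         # docs mentioning both

    def __post_init__(self) -> None:
        if not 0 <= self.n_xy <= min(self.n_x, self.n_y):
            raise ValueError("co-occurrence counts inconsistent")
        if max(self.n_x, self.n_y) > self.n_total:
            raise ValueError("marginal count exceeds corpus size")


class UndefinedPMI(ValueError):
    """PMI is undefined (no co-occurring document) — distinct from a low score."""


def pmi(c: CoOccurrence) -> float:
    if c.n_xy == 0:
        raise UndefinedPMI(f"{c.symbol}: no co-occurring document")
    return math.log2(c.n_xy * c.n_total / (c.n_x * c.n_y))


def _doc_tokens(text: str) -> set[str]:
    return set(TOKEN_RE.findall(text))


def count_cooccurrence(corpus: Mapping[str, str], symbols: Iterable[str],
                       disease_terms: Iterable[str] = ("Parkinson's disease",),
                       ) -> list[CoOccurrence]:
    """Document co-occurrence counts of each symbol with any disease term."""
    if not corpus:
        raise ValueError("empty corpus")
    symbols = sorted({s.strip().upper() for s in symbols})
    terms = [t.lower() for t in disease_terms]
    n_total = len(corpus)
    n_x = {s: 0 for s in symbols}
    n_xy = {s: 0 for s in symbols}
    n_y = 0
    for text in corpus.values():
        tokens = _doc_tokens(text)
        lower = text.lower()
        has_disease = any(t in lower for t in terms)
        if has_disease:
            n_y += 1
        for s in symbols:
            if s in tokens:
                n_x[s] += 1
                if has_disease:
                    n_xy[s] += 1
    return [CoOccurrence(symbol=s, n_total=n_total, n_x=n_x[s], n_y=n_y,
                         n_xy=n_xy[s]) for s in symbols]


def select_pd_proteins(stats: list[CoOccurrence], min_docs: int = 3,
                       min_pmi: float = 0.0) -> set[str]:
    """Proteins with >= min_docs co-occurring abstracts and PMI above min_pmi."""
    out = set()
    for c in stats:
        if c.n_xy >= min_docs and c.n_xy > 0 and pmi(c) > min_pmi:
            out.add(c.symbol)
    return out


@dataclass
class AnnotatedHub:
    hub: Hub
    pd_members: set[str] = field(default_factory=set)

    @property
    def retained(self) -> bool:
        return bool(self.pd_members)


def annotate_hubs(hubs: list[Hub], pd_proteins: set[str],
                  ) -> tuple[list[AnnotatedHub], list[Hub]]:
    """Tag each hub with its disease-associated members; a hub is retained
    iff it contains at least one."""
    annotated = []
    retained = []
    for h in hubs:
        inter = h.members & pd_proteins
        h.pd_members = inter
        annotated.append(AnnotatedHub(hub=h, pd_members=inter))
        if inter:
            retained.append(h)
    return annotated, retained


def cooccurrence_table(stats: list[CoOccurrence], min_docs: int = 3,
                       min_pmi: float = 0.0) -> list[dict]:
    """Rows for the mining output TSV (symbol, counts, PMI, selected flag)."""
    selected = select_pd_proteins(stats, min_docs=min_docs, min_pmi=min_pmi)
    rows = []
    for c in stats:
        rows.append({
            "symbol": c.symbol, "n_x": c.n_x, "n_y": c.n_y,
            "n_xy": c.n_xy, "N": c.n_total,
            "pmi": pmi(c) if c.n_xy > 0 else float("nan"),
            "selected": c.symbol in selected,
        })
    return rows
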