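"""Pathway enrichment: Fisher's exact test with Benjamini-Hochberg FDR.

Tests whether a query gene set (e.g. genes of the altered subsystems)
overlaps a pathway's gene set more than expected by chance, against a
background universe that defaults to the genes of the metabolic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "fisher_enrichment",
    "bh_adjust",
    "read_gmt",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the background universe they live in."""

    sets: Dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"gene set {name!r} has {len(stray)} genes outside the universe"
                )

    @classmethod
    def from_dict(cls, sets: Dict[str, Iterable[str]], universe: Iterable[str]) -> "GeneSetCollection":
        return cls(
            sets={name: frozenset(genes) for name, genes in sets.items()},
            universe=frozenset(universe),
        )


@dataclass(frozen=True)
class EnrichmentRow:
    pathway: str
    a: int  # query ∩ set
    b: int  # query \ set
    c: int  # set \ query
    d: int  # neither
    odds_ratio: float
    p_value: float
    q_value: float


def fisher_enrichment(query: Iterable[str], collection: GeneSetCollection) -> List[EnrichmentRow]:
    """Two-sided Fisher exact test of the query against every pathway.

    Query genes outside the universe are dropped with a warning.  The
    displayed odds ratio uses the Haldane +0.5 correction (never the
    p-value).  Rows are sorted by p, ties by pathway name.
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty background universe")
    q = set(query)
    stray = q - universe
    if stray:
        logger.warning("%d query genes outside the universe dropped", len(stray))
        q &= universe
    n = len(universe)
    raw: List[tuple] = []
    for name, genes in collection.sets.items():
        a = len(q & genes)
        b = len(q) - a
        c = len(genes) - a
        d = n - a - b - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)) if a else 0.0
        raw.append((name, a, b, c, d, oddsr, float(p)))
    qvals = bh_adjust([row[6] for row in raw])
    rows = [
        EnrichmentRow(name, a, b, c, d, oddsr, p, qv)
        for (name, a, b, c, d, oddsr, p), qv in zip(raw, qvals)
    ]
    rows.sort(key=lambda r: (r.p_value, r.pathway))
    return rows


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def read_gmt(path) -> Dict[str, Set[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
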