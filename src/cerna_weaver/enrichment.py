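"""Hypergeometric term enrichment with kappa-based term-similarity network.

Each term is scored by the upper-tail hypergeometric probability of its
overlap with the query list against a background universe, BH-adjusted
across terms. A term is significant when raw P < 0.05, the overlap count is
at least 3, and the enrichment factor (observed/expected hit ratio) exceeds
1.5 — all configurable. Significant terms are connected into a similarity
network by Cohen's kappa of their membership indicator vectors over the
background (edges above kappa 0.3 by default), the documented convention
behind "similarity" in Metascape-style term networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentThresholds:
    max_p: float = 0.05
    min_count: int = 3
    min_enrichment_factor: float = 1.5


@dataclass
class TermSet:
    term_id: str
    term_name: str
    member_gene_ids: frozenset

    def __post_init__(self) -> None:
        if not self.member_gene_ids:
            raise ValueError(f"term {self.term_id} has empty membership")
        self.member_gene_ids = frozenset(self.member_gene_ids)


@dataclass
class EnrichedTerm:
    term_id: str
    term_name: str
    count: int
    list_size: int
    term_size: int
    background_size: int
    enrichment_factor: float
    p_value: float
    p_adjusted: float
    passes: bool


def hypergeom_p(count: int, list_size: int, term_size: int, background_size: int) -> float:
    """Upper-tail P(X >= count), X ~ Hypergeom(background, term, list)."""
    if not (0 <= count <= list_size <= background_size):
        raise ValueError("require 0 <= count <= list_size <= background_size")
    if not (0 <= term_size <= background_size):
        raise ValueError("term_size must lie within the background")
    if count > term_size:
        raise ValueError("count cannot exceed term_size")
    return float(stats.hypergeom.sf(count - 1, background_size, term_size, list_size))


def enrichment_factor(
    count: int, list_size: int, term_size: int, background_size: int
) -> float:
    """(count/list_size) / (term_size/background_size): observed over expected."""
    if list_size <= 0 or term_size <= 0 or background_size <= 0:
        raise ValueError("sizes must be positive")
    return (count / list_size) / (term_size / background_size)


def enrich(
    gene_list,
    term_collection: list[TermSet],
    background,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
) -> list[EnrichedTerm]:
    """Score every term against the query list; sorted by (P, term_id).

    Query genes absent from the background are dropped (logged). All terms
    are BH-adjusted together; membership outside the background is ignored.
    """
    background = frozenset(background)
    query = frozenset(gene_list)
    dropped = query - background
    if dropped:
        logger.info("dropping %d query genes absent from background", len(dropped))
    query &= background
    n_bg = len(background)
    n_list = len(query)

    raw = []
    for term in term_collection:
        members = term.member_gene_ids & background
        if not members:
            continue
        count = len(query & members)
        p = hypergeom_p(count, n_list, len(members), n_bg) if n_list else 1.0
        ef = enrichment_factor(count, n_list, len(members), n_bg) if n_list else 0.0
        raw.append((term, count, len(members), p, ef))

    p_adj = bh_adjust([r[3] for r in raw]) if raw else np.array([])
    results = [
        EnrichedTerm(
            term_id=term.term_id,
            term_name=term.term_name,
            count=count,
            list_size=n_list,
            term_size=term_size,
            background_size=n_bg,
            enrichment_factor=ef,
            p_value=p,
            p_adjusted=float(adj),
            passes=bool(
                p < thresholds.max_p
                and count >= thresholds.min_count
                and ef > thresholds.min_enrichment_factor
            ),
        )
        for (term, count, term_size, p, ef), adj in zip(raw, p_adj)
    ]
    results.sort(key=lambda t: (t.p_value, t.term_id))
    return results


def cohen_kappa(members_a: frozenset, members_b: frozenset, background) -> float:
    """Chance-corrected agreement of two membership indicators over the
    background: kappa = (p_o - p_e) / (1 - p_e)."""
    background = frozenset(background)
    a = members_a & background
    b = members_b & background
    n = len(background)
    if n == 0:
        raise ValueError("empty background")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    p_o = (both + neither) / n
    p_e = (len(a) * len(b) + (n - len(a)) * (n - len(b))) / (n * n)
    if p_e == 1.0:
        return 1.0  # identical constant indicators agree perfectly
    return (p_o - p_e) / (1.0 - p_e)


def term_similarity_network(
    enriched_terms: list[EnrichedTerm],
    term_collection: list[TermSet],
    background,
    kappa_min: float = 0.3,
) -> nx.Graph:
    """Graph of passing terms; edge iff membership kappa > ``kappa_min``."""
    by_id = {t.term_id: t for t in term_collection}
    passing = [t for t in enriched_terms if t.passes]
    g = nx.Graph()
    for t in passing:
        g.add_node(
            t.term_id,
            term_name=t.term_name,
            count=int(t.count),
            p_value=float(t.p_value),
            neg_log10_p=float(-np.log10(max(t.p_value, 1e-300))),
        )
    background = frozenset(background)
    for i, ta in enumerate(passing):
        for tb in passing[i + 1 :]:
            kappa = cohen_kappa(
                by_id[ta.term_id].member_gene_ids,
                by_id[tb.term_id].member_gene_ids,
                background,
            )
            if kappa > kappa_min:
                g.add_edge(ta.term_id, tb.term_id, kappa=float(kappa))
    return g


def enrich_lists(
    gene_lists: dict[str, list],
    term_collection: list[TermSet],
    background,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
) -> tuple[dict[str, list[EnrichedTerm]], pd.DataFrame]:
    """Enrich several lists and build a term x list heatmap of -log10 P.

    The heatmap covers terms passing in at least one list; cells hold
    -log10 raw P (0 where the term was not scored for that list).
    """
    results = {
        name: enrich(genes, term_collection, background, thresholds)
        for name, genes in gene_lists.items()
    }
    keep = sorted(
        {t.term_id for res in results.values() for t in res if t.passes}
    )
    heat = pd.DataFrame(0.0, index=keep, columns=list(gene_lists))
    for name, res in results.items():
        for t in res:
            if t.term_id in heat.index:
                heat.loc[t.term_id, name] = -np.log10(max(t.p_value, 1e-300))
    return results, heat


def enrichment_table(terms: list[EnrichedTerm]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [t.term_id for t in terms],
            "term_name": [t.term_name for t in terms],
            "count": [t.count for t in terms],
            "list_size": [t.list_size for t in terms],
            "term_size": [t.term_size for t in terms],
            "background_size": [t.background_size for t in terms],
            "enrichment_factor": [t.enrichment_factor for t in terms],
            "p_value": [t.p_value for t in terms],
            "p_adjusted": [t.p_adjusted for t in terms],
            "passes": [t.passes for t in terms],
        }
    )


def read_gmt(path: str | Path) -> list[TermSet]:
    """Standard GMT: term_id <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    terms = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term_id, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term_id in seen:
                raise ValueError(f"duplicate term id {term_id!r}")
            seen.add(term_id)
            terms.append(TermSet(term_id, name, frozenset(genes)))
    return terms


def write_gmt(terms: list[TermSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            genes = "\t".join(sorted(t.member_gene_ids))
            fh.write(f"{t.term_id}\t{t.term_name}\t{genes}\n")
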