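"""ceRNA network assembly from DE sets, seed sites, and expression coupling.

A candidate triplet (circRNA, miRNA, mRNA) requires all three members to be
differentially expressed and both arms (circRNA-miRNA, miRNA-mRNA) to carry
at least one seed site. Triplets are then scored on expression across the
compared samples:

* ``cor_xy`` — Pearson correlation of circRNA and mRNA (log2(x+1) of
  normalized values); a sponge pair should co-vary positively.
* ``S`` — sensitivity correlation: ``cor_xy`` minus the partial correlation
  of circRNA and mRNA given the shared miRNA. S is large exactly when the
  miRNA accounts for the circRNA-mRNA co-variation, the signature of
  miRNA-mediated coupling.

Valid triplets (cor_xy and S above their thresholds) are assembled into a
graph bipartite between miRNAs and {circRNAs, mRNAs}, exportable as GraphML
(Cytoscape-ready) and edge-list TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import DERecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TripletThresholds:
    """Validity cutoffs for scored triplets (effect-size based; with n=6
    samples correlation P-values are uninformative and are not computed)."""

    cor_min: float = 0.7
    s_min: float = 0.3


@dataclass
class CeRNATriplet:
    """A scored (circRNA, miRNA, mRNA) sponge candidate."""

    circ_id: str
    mir_id: str
    mrna_id: str
    cor_xy: float
    cor_cm: float
    cor_tm: float
    s_value: float
    n_sites_circ: int
    n_sites_mrna: int
    valid: bool


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ZeroDivisionError("zero variance in one of the vectors")
    return float((xc @ yc) / denom)


def relationship_s(cor_xy: float, cor_cm: float, cor_tm: float) -> float:
    """Sensitivity correlation S = cor_xy - partial(cor_xy | miRNA).

    The partial correlation of circRNA and mRNA given the miRNA is
    ``(cor_xy - cor_cm*cor_tm) / sqrt((1-cor_cm^2)(1-cor_tm^2))``. S
    measures how much of the raw coupling the shared miRNA explains.
    """
    for v in (cor_xy, cor_cm, cor_tm):
        if not -1.0 <= v <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    if abs(cor_cm) == 1.0 or abs(cor_tm) == 1.0:
        raise ZeroDivisionError("partial correlation undefined at |cor| = 1")
    partial = (cor_xy - cor_cm * cor_tm) / np.sqrt(
        (1.0 - cor_cm**2) * (1.0 - cor_tm**2)
    )
    return float(cor_xy - partial)


def _passing_ids(records: list[DERecord]) -> dict[str, DERecord]:
    return {r.feature_id: r for r in records if r.passes_filter}


def candidate_pairs(
    de_circ: list[DERecord],
    de_mir: list[DERecord],
    de_mrna: list[DERecord],
    sites_circ,
    sites_mrna,
    require_opposite_direction: bool = False,
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], int]]:
    """Seed-site-backed pairs among DE features.

    Returns ``(circ_mir_pairs, mir_mrna_pairs)`` mapping each pair to its
    number of supporting sites (distinct start positions). The optional
    direction constraint (miRNA regulated opposite to both partners) defaults
    off — the study's printed pairings include same-direction partners.
    """
    circ_de = _passing_ids(de_circ)
    mir_de = _passing_ids(de_mir)
    mrna_de = _passing_ids(de_mrna)
    if not circ_de or not mir_de or not mrna_de:
        logger.warning(
            "empty DE set (circ=%d, mir=%d, mrna=%d passing); no pairs",
            len(circ_de), len(mir_de), len(mrna_de),
        )

    def collect(sites, target_de) -> dict[tuple[str, str], int]:
        starts: dict[tuple[str, str], set[int]] = {}
        for s in sites:
            if s.target_id in target_de and s.mir_id in mir_de:
                starts.setdefault((s.target_id, s.mir_id), set()).add(s.start)
        pairs = {k: len(v) for k, v in starts.items()}
        if require_opposite_direction:
            pairs = {
                (tid, mid): n
                for (tid, mid), n in pairs.items()
                if target_de[tid].direction != mir_de[mid].direction
            }
        return pairs

    return collect(sites_circ, circ_de), collect(sites_mrna, mrna_de)


def shared_mirnas(circ_pairs, mrna_pairs) -> set[str]:
    """miRNAs appearing in at least one pair of each kind."""
    return {m for _, m in circ_pairs} & {m for _, m in mrna_pairs}


def score_triplets(
    circ_pairs: dict[tuple[str, str], int],
    mrna_pairs: dict[tuple[str, str], int],
    expr_circ: pd.DataFrame,
    expr_mir: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    thresholds: TripletThresholds = TripletThresholds(),
    pseudocounts: dict | None = None,
) -> list[CeRNATriplet]:
    """Score every triplet through a shared miRNA on log2(x + pseudocount)
    expression.

    Expression frames are normalized values over the compared samples (same
    columns in all three). ``pseudocounts`` maps class names ('circ', 'mir',
    'mrna') to the pseudocount added before the log — ideally the class-unit
    equivalent of one read (the log-CPM prior-count convention), so the
    regularization does not depend on the arbitrary scale of the unit;
    defaults to 1.0 per class. A scalar or per-feature Series is accepted.
    Triplets with a zero-variance member are dropped with a logged reason.
    """
    mirs = shared_mirnas(circ_pairs, mrna_pairs)
    pc = {"circ": 1.0, "mir": 1.0, "mrna": 1.0}
    if pseudocounts:
        pc.update(pseudocounts)
    lc = np.log2(expr_circ.add(pc["circ"], axis=0))
    lm = np.log2(expr_mir.add(pc["mir"], axis=0))
    lt = np.log2(expr_mrna.add(pc["mrna"], axis=0))
    triplets: list[CeRNATriplet] = []
    for mir in sorted(mirs):
        circs = sorted(c for (c, m) in circ_pairs if m == mir)
        mrnas = sorted(t for (t, m) in mrna_pairs if m == mir)
        for circ in circs:
            for mrna in mrnas:
                try:
                    cor_xy = pearson(lc.loc[circ], lt.loc[mrna])
                    cor_cm = pearson(lc.loc[circ], lm.loc[mir])
                    cor_tm = pearson(lt.loc[mrna], lm.loc[mir])
                    s_val = relationship_s(cor_xy, cor_cm, cor_tm)
                except ZeroDivisionError as exc:
                    logger.info(
                        "dropping triplet (%s, %s, %s): %s", circ, mir, mrna, exc
                    )
                    continue
                triplets.append(
                    CeRNATriplet(
                        circ_id=circ,
                        mir_id=mir,
                        mrna_id=mrna,
                        cor_xy=cor_xy,
                        cor_cm=cor_cm,
                        cor_tm=cor_tm,
                        s_value=s_val,
                        n_sites_circ=circ_pairs[(circ, mir)],
                        n_sites_mrna=mrna_pairs[(mrna, mir)],
                        valid=bool(
                            cor_xy >= thresholds.cor_min and s_val >= thresholds.s_min
                        ),
                    )
                )
    triplets.sort(key=lambda t: (t.circ_id, t.mir_id, t.mrna_id))
    return triplets


@dataclass
class CeRNANetwork:
    """Assembled network over valid triplets, bipartite miRNA vs targets."""

    graph: nx.Graph
    triplets: list[CeRNATriplet] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_class(self, node_class: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("node_class") == node_class
        )

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "edge_type": d["edge_type"],
                    "n_sites": d["n_sites"],
                    "triplet_ids": d["triplet_ids"],
                }
            )
        return pd.DataFrame(rows, columns=["source", "target", "edge_type", "n_sites", "triplet_ids"])

    def triplet_table(self) -> pd.DataFrame:
        return triplet_table(self.triplets)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))

    def write_edges(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)


def triplet_table(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [t.circ_id for t in triplets],
            "mir_id": [t.mir_id for t in triplets],
            "mrna_id": [t.mrna_id for t in triplets],
            "cor_xy": [t.cor_xy for t in triplets],
            "cor_cm": [t.cor_cm for t in triplets],
            "cor_tm": [t.cor_tm for t in triplets],
            "S": [t.s_value for t in triplets],
            "n_sites_circ": [t.n_sites_circ for t in triplets],
            "n_sites_mrna": [t.n_sites_mrna for t in triplets],
            "valid": [t.valid for t in triplets],
        }
    )


def _triplet_id(t: CeRNATriplet) -> str:
    return f"{t.circ_id}|{t.mir_id}|{t.mrna_id}"


def assemble(
    triplets: list[CeRNATriplet],
    de_direction: dict[str, str] | None = None,
    de_log2fc: dict[str, float] | None = None,
) -> CeRNANetwork:
    """Build the network over valid triplets only, deterministically ordered.

    ``de_direction``/``de_log2fc`` optionally annotate nodes with their DE
    call (feature_id -> value) for Cytoscape-style rendering.
    """
    valid = [t for t in triplets if t.valid]
    g = nx.Graph()
    de_direction = de_direction or {}
    de_log2fc = de_log2fc or {}

    def add_node(node_id: str, node_class: str) -> None:
        attrs = {"node_class": node_class}
        if node_id in de_direction:
            attrs["direction"] = de_direction[node_id]
        if node_id in de_log2fc:
            attrs["log2_fold_change"] = float(de_log2fc[node_id])
        g.add_node(node_id, **attrs)

    edges: dict[tuple[str, str], dict] = {}
    for t in sorted(valid, key=lambda t: (t.circ_id, t.mir_id, t.mrna_id)):
        add_node(t.circ_id, "circRNA")
        add_node(t.mir_id, "miRNA")
        add_node(t.mrna_id, "mRNA")
        for key, etype, nsites in (
            ((t.circ_id, t.mir_id), "circRNA-miRNA", t.n_sites_circ),
            ((t.mir_id, t.mrna_id), "miRNA-mRNA", t.n_sites_mrna),
        ):
            d = edges.setdefault(key, {"edge_type": etype, "n_sites": nsites, "ids": []})
            d["ids"].append(_triplet_id(t))
    for (u, v), d in sorted(edges.items()):
        g.add_edge(
            u,
            v,
            edge_type=d["edge_type"],
            n_sites=int(d["n_sites"]),
            triplet_ids=";".join(sorted(set(d["ids"]))),
        )
    return CeRNANetwork(graph=g, triplets=valid)
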