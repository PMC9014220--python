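"""Published circRNA-miRNA pairing tables, packaged as typed fixtures.

Two printed tables from the source study are shipped verbatim: the DE
circRNAs in the control-condition ceRNA network (6 rows) and in the
anesthesia/surgery-condition network (13 rows), each with log2 fold change,
raw P, regulation direction, and the miRNAs predicted to bind by seed
matching. They serve as exact, desk-scale inputs for the pairing logic: the
printed statistics are taken as given, not recomputed. A checksum guards the
packaged rows against accidental edits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import networkx as nx

from .diffexpr import DEThresholds


@dataclass(frozen=True)
class CircTableRow:
    circ_id: str
    log2_fold_change: float
    p_value: float
    direction: str
    mirnas: tuple

    @property
    def mirna_set(self) -> frozenset:
        return frozenset(self.mirnas)


_CONTROL_ROWS = (
    ("mm9_circ_001571", 1.55, 0.0197, "up", ("mmu-miR-296-5p",)),
    ("mm9_circ_002005", 1.27, 0.0010, "up", ("mmu-miR-298-5p",)),
    ("mm9_circ_002179", 1.25, 0.0024, "up", ("mmu-miR-7056-5p",)),
    ("mm9_circ_002489", -1.11, 0.0196, "down", ("mmu-miR-296-3p",)),
    ("mm9_circ_000550", -1.66, 0.0025, "down", ("mmu-miR-6938-3p",)),
    (
        "mm9_circ_003736",
        -2.71,
        6.88e-27,
        "down",
        (
            "mmu-miR-298-5p",
            "mmu-miR-615-3p",
            "mmu-miR-6938-3p",
            "mmu-miR-7056-5p",
        ),
    ),
)

# the printed surgery-condition table; the circ_003736 row's miRNA list is
# missing a comma in print and is stored here as the intended three miRNAs
_SURGERY_ROWS = (
    ("mm9_circ_006949", 1.08, 0.0449, "up", ("mmu-miR-615-3p",)),
    ("mm9_circ_007155", 1.24, 0.0497, "up", ("mmu-miR-296-5p",)),
    ("mm9_circ_010522", 1.30, 0.0466, "up", ("mmu-miR-298-5p",)),
    ("mm9_circ_013251", 1.28, 0.0489, "up", ("mmu-miR-1966-3p",)),
    ("mm9_circ_014796", 1.19, 0.0350, "up", ("mmu-miR-298-5p",)),
    ("mm9_circ_016411", 1.21, 0.0216, "up", ("mmu-miR-615-3p",)),
    ("mm9_circ_018802", 1.24, 0.0459, "up", ("mmu-miR-1264-5p",)),
    ("mm9_circ_009789", 1.98, 0.0003, "up", ("mmu-miR-298-5p",)),
    ("mm9_circ_008009", 1.48, 0.0316, "up", ("mmu-miR-298-5p",)),
    ("mm9_circ_004229", 1.52, 0.0109, "up", ("mmu-miR-298-3p", "mmu-miR-298-5p")),
    ("mm9_circ_007503", 1.31, 0.0042, "up", ("mmu-miR-298-5p", "mmu-miR-615-3p")),
    ("mm9_circ_011555", 1.50, 0.0149, "up", ("mmu-miR-122-5p", "mmu-miR-615-3p")),
    (
        "mm9_circ_003736",
        -2.46,
        2.93e-18,
        "down",
        ("mmu-miR-18a-3p", "mmu-miR-298-5p", "mmu-miR-615-3p"),
    ),
)

_CONTROL_SHA256 = "57dedc495f774071c0cc77054d9bad9f597be5433eed255da38f698e0278d65e"
_SURGERY_SHA256 = "9ed183c33090b028c3577d651b62d000f63644ae5e54aa4b7fdb995bf3a444fe"


def _checksum(rows) -> str:
    canon = repr(rows).encode()
    return hashlib.sha256(canon).hexdigest()


def _load(rows, expected: str) -> list[CircTableRow]:
    digest = _checksum(rows)
    if digest != expected:
        raise RuntimeError(
            f"packaged fixture checksum mismatch ({digest}); the table was edited"
        )
    return [CircTableRow(*row) for row in rows]


def load_control_table() -> list[CircTableRow]:
    """DE circRNAs in the control-condition network (6 rows)."""
    return _load(_CONTROL_ROWS, _CONTROL_SHA256)


def load_surgery_table() -> list[CircTableRow]:
    """DE circRNAs in the anesthesia/surgery-condition network (13 rows)."""
    return _load(_SURGERY_ROWS, _SURGERY_SHA256)


def fixture_network(
    rows: list[CircTableRow], thresholds: DEThresholds = DEThresholds()
) -> nx.Graph:
    """Bipartite circRNA-miRNA graph from a printed table.

    Applies the DE filter (|log2FC| and raw P) to each row, then adds one
    edge per listed miRNA — the study's pairing logic with the printed
    statistics taken as the DE call.
    """
    g = nx.Graph()
    for row in rows:
        if abs(row.log2_fold_change) < thresholds.min_abs_log2fc:
            continue
        if row.p_value > thresholds.max_p:
            continue
        g.add_node(
            row.circ_id,
            node_class="circRNA",
            direction=row.direction,
            log2_fold_change=row.log2_fold_change,
        )
        for mir in row.mirnas:
            g.add_node(mir, node_class="miRNA")
            g.add_edge(row.circ_id, mir, edge_type="circRNA-miRNA")
    return g
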