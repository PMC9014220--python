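"""miRNA seed-site discovery on linear 3'UTRs and circular transcripts.

The seed is nucleotides 2-8 (or 2-7) of the mature miRNA. A canonical site on
a target, read 5'->3', is the reverse complement of the seed, optionally
followed by an adenine opposite miRNA position 1:

* 8mer     — perfect match to positions 2-8 plus the A1 adenine;
* 7mer-m8  — perfect match to positions 2-8;
* 7mer-A1  — match to positions 2-7 plus the A1 adenine;
* 6mer     — match to positions 2-7 only.

Circular targets are scanned on the doubled string with starts restricted to
one period, so sites spanning the back-splice junction (the covalent joint
closing the circle) are found and flagged. The default rule set accepts only
7mer-m8 and its 8mer upgrade — the strictest common convention — with G:U
wobble pairs disallowed; the weaker 6mer/7mer-A1 classes are opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

# strongest first; used both for per-start classification and sort order
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}


class SequenceError(ValueError):
    """Raised on invalid alphabets or impossible sequence geometry."""


def canonical_rna(seq: str) -> str:
    """Uppercase, DNA->RNA (T->U), validated against {A,C,G,U}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def revcomp_rna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_of(mir_sequence: str, span: str = "2_8") -> str:
    """Seed substring at 1-based miRNA positions 2-7 or 2-8."""
    s = canonical_rna(mir_sequence)
    if len(s) < 8:
        raise SequenceError("miRNA shorter than 8 nt")
    if span == "2_8":
        return s[1:8]
    if span == "2_7":
        return s[1:7]
    raise ValueError(f"unknown seed span {span!r}")


@dataclass(frozen=True)
class MatchRules:
    """Which canonical site classes count as a match."""

    allowed_types: frozenset = field(
        default_factory=lambda: frozenset({"7mer-m8", "8mer"})
    )

    def __post_init__(self) -> None:
        unknown = self.allowed_types - set(SITE_TYPES)
        if unknown:
            raise ValueError(f"unknown site types: {sorted(unknown)}")


DEFAULT_RULES = MatchRules()
ALL_RULES = MatchRules(allowed_types=frozenset(SITE_TYPES))


@dataclass(frozen=True)
class SeedSite:
    """One seed match: 0-based half-open on the canonical linearization."""

    mir_id: str
    target_id: str
    site_type: str
    start: int
    end: int
    spans_junction: bool = False


def _classify_start(padded: str, pos: int, core7: str, core6: str) -> str | None:
    """Best site class anchored at ``pos``, or None."""
    if padded[pos : pos + 7] == core7:
        if padded[pos + 7 : pos + 8] == "A":
            return "8mer"
        return "7mer-m8"
    if padded[pos : pos + 6] == core6:
        if padded[pos + 6 : pos + 7] == "A":
            return "7mer-A1"
        return "6mer"
    return None


def _scan(
    padded: str,
    n_starts: int,
    mir: str,
    rules: MatchRules,
    mir_id: str,
    target_id: str,
    circular_len: int | None,
) -> list[SeedSite]:
    core7 = revcomp_rna(seed_of(mir, "2_8"))
    core6 = core7[1:]  # reverse complement of positions 2-7
    sites = []
    for pos in range(n_starts):
        site_type = _classify_start(padded, pos, core7, core6)
        if site_type is None or site_type not in rules.allowed_types:
            continue
        end = pos + SITE_LENGTH[site_type]
        spans = circular_len is not None and end > circular_len
        sites.append(
            SeedSite(
                mir_id=mir_id,
                target_id=target_id,
                site_type=site_type,
                start=pos,
                end=end,
                spans_junction=spans,
            )
        )
    sites.sort(key=lambda s: (s.target_id, s.start, s.site_type))
    return sites


def find_sites_linear(
    target: str,
    mir: str,
    rules: MatchRules = DEFAULT_RULES,
    mir_id: str = "mir",
    target_id: str = "target",
) -> list[SeedSite]:
    """All seed sites on a linear target, 5'->3', one per start position."""
    t = canonical_rna(target)
    if not t:
        raise SequenceError("empty target sequence")
    return _scan(t, len(t), mir, rules, mir_id, target_id, circular_len=None)


def find_sites_circular(
    circ: str,
    mir: str,
    rules: MatchRules = DEFAULT_RULES,
    mir_id: str = "mir",
    target_id: str = "target",
) -> list[SeedSite]:
    """Seed sites on a circular target given as its back-splice linearization.

    The doubled string is scanned with starts restricted to the first period;
    ``spans_junction`` marks sites wrapping past the end of the
    linearization. Coordinates stay on the as-given linearization.
    """
    c = canonical_rna(circ)
    max_len = max(SITE_LENGTH[t] for t in rules.allowed_types)
    if len(c) < max_len:
        raise SequenceError(
            f"circle of {len(c)} nt shorter than longest allowed site ({max_len} nt)"
        )
    return _scan(c + c, len(c), mir, rules, mir_id, target_id, circular_len=len(c))


def find_all_sites(
    targets: dict[str, str],
    mirs: dict[str, str],
    circular: bool,
    rules: MatchRules = DEFAULT_RULES,
) -> list[SeedSite]:
    """Scan every (miRNA, target) pair; deterministic order."""
    finder = find_sites_circular if circular else find_sites_linear
    sites: list[SeedSite] = []
    for tid in sorted(targets):
        for mid in sorted(mirs):
            sites.extend(
                finder(targets[tid], mirs[mid], rules, mir_id=mid, target_id=tid)
            )
    sites.sort(key=lambda s: (s.target_id, s.start, s.site_type, s.mir_id))
    return sites


def sites_table(sites: list[SeedSite]) -> pd.DataFrame:
    """BED-like table: target, start, end, mir, site type, junction flag."""
    return pd.DataFrame(
        {
            "target_id": [s.target_id for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "mir_id": [s.mir_id for s in sites],
            "site_type": [s.site_type for s in sites],
            "spans_junction": [s.spans_junction for s in sites],
        }
    )


def write_sites(sites: list[SeedSite], path: str | Path) -> None:
    sites_table(sites).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> list[SeedSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        SeedSite(
            mir_id=str(r.mir_id),
            target_id=str(r.target_id),
            site_type=str(r.site_type),
            start=int(r.start),
            end=int(r.end),
            spans_junction=bool(r.spans_junction),
        )
        for r in df.itertuples()
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: canonical RNA sequence}, insertion-ordered."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = canonical_rna(str(rec.seq))
    return seqs
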