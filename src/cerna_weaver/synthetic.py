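"""Synthetic sequences and counts with planted, recoverable sponge triplets.

The generator emulates the statistical structure the inference assumes,
without any read-level simulation:

* **Sequences.** Each planted triplet's miRNA seed (positions 2-8) has its
  reverse complement embedded ``site_count`` times in the triplet's circRNA
  (optionally with one copy spanning the back-splice junction) and mRNA
  3'UTR. All other sequences are rejection-sampled until they contain no
  seed site for any generated miRNA under the operative matching rules, so a
  run with nothing planted yields no pairs at all.

* **Counts.** Negative binomial with variance = mean + dispersion * mean^2
  (dispersion 0 degenerates to Poisson). Differential expression enters as a
  log2 group effect on the aging samples. Sponge coupling enters as a
  per-sample latent miRNA-activity factor shared within each triplet: the
  circRNA and mRNA means are multiplied by 2**z, the miRNA mean by
  2**(-loading * z), z ~ Normal(0, latent_sigma). This produces the positive
  circRNA-mRNA and negative miRNA-target correlations the scoring step looks
  for. The default scenario (effects +3/-6/+3 log2, latent_sigma 0.6,
  loading 2) keeps the miRNA's age and latent loadings proportional to the
  targets', which is what makes the sensitivity correlation identifiable at
  all from 3 replicates per group.

A :class:`SyntheticTruth` ledger records planted triplets, truly-DE feature
ids and the seed, and round-trips through JSON without loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .seeds import (
    DEFAULT_RULES,
    MatchRules,
    SequenceError,
    find_sites_circular,
    find_sites_linear,
    revcomp_rna,
    seed_of,
)

AGES = ("young", "aging")
CONDITIONS = ("control", "surgery")
_ALPHABET = np.array(list("ACGU"))


class GenerationError(RuntimeError):
    """Raised when rejection sampling or embedding cannot succeed."""


@dataclass(frozen=True)
class StudyDesign:
    """2x2 (age x condition) design with equal replication."""

    groups: tuple = (
        ("young", "control"),
        ("young", "surgery"),
        ("aging", "control"),
        ("aging", "surgery"),
    )
    replicates_per_group: int = 3

    def __post_init__(self) -> None:
        if len(self.groups) != 4 or len(set(self.groups)) != 4:
            raise ValueError("design must have exactly 4 distinct groups")
        for age, cond in self.groups:
            if age not in AGES or cond not in CONDITIONS:
                raise ValueError(f"unknown group label ({age}, {cond})")
        if not isinstance(self.replicates_per_group, int):
            raise ValueError("replicate count must be an integer")
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group for correlations")

    def sample_ids(self) -> list[str]:
        return [
            f"{age}_{cond}_{r + 1}"
            for age, cond in self.groups
            for r in range(self.replicates_per_group)
        ]

    def samples_for(self, age: str | None = None, condition: str | None = None) -> list[str]:
        out = []
        for a, c in self.groups:
            if (age is None or a == age) and (condition is None or c == condition):
                out.extend(f"{a}_{c}_{r + 1}" for r in range(self.replicates_per_group))
        return out

    def is_aging(self, sample_id: str) -> bool:
        return sample_id.startswith("aging_")


@dataclass
class PlantedTriplet:
    """One ground-truth sponge triplet and its planted parameters."""

    circ_id: str
    mir_id: str
    mrna_id: str
    effect_log2fc_circ: float = 3.0
    effect_log2fc_mir: float = -6.0
    effect_log2fc_mrna: float = 3.0
    site_count_circ: int = 2
    site_count_mrna: int = 2
    junction_spanning: bool = True

    def __post_init__(self) -> None:
        if self.site_count_circ < 1 or self.site_count_mrna < 1:
            raise ValueError("planted triplets must have >= 1 site on each target")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for a generated dataset."""

    triplets: list[PlantedTriplet]
    feature_ids: dict[str, list[str]]
    extra_de_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    mrna_length_bp: dict[str, int] = field(default_factory=dict)
    rng_seed: int = 0

    @property
    def de_features(self) -> dict[str, set[str]]:
        """Per-class ids of truly differential features (triplets + extras)."""
        de = {
            "circ": {t.circ_id for t in self.triplets},
            "mir": {t.mir_id for t in self.triplets},
            "mrna": {t.mrna_id for t in self.triplets},
        }
        for cls, effects in self.extra_de_effects.items():
            de.setdefault(cls, set()).update(effects)
        return de

    def true_edges(self) -> set[tuple[str, str]]:
        """Undirected planted edge set (both arms of every triplet)."""
        edges = set()
        for t in self.triplets:
            edges.add(tuple(sorted((t.circ_id, t.mir_id))))
            edges.add(tuple(sorted((t.mir_id, t.mrna_id))))
        return edges

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "feature_ids": self.feature_ids,
            "extra_de_effects": self.extra_de_effects,
            "mrna_length_bp": self.mrna_length_bp,
            "triplets": [vars(t) for t in self.triplets],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            triplets=[PlantedTriplet(**t) for t in payload["triplets"]],
            feature_ids={k: list(v) for k, v in payload["feature_ids"].items()},
            extra_de_effects={
                k: {i: float(e) for i, e in v.items()}
                for k, v in payload["extra_de_effects"].items()
            },
            mrna_length_bp={k: int(v) for k, v in payload["mrna_length_bp"].items()},
            rng_seed=int(payload["rng_seed"]),
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))

def _clean_of_cores(seq: str, cores: list[str], circular: bool) -> bool:
    hay = seq + seq if circular else seq
    return not any(core in hay for core in cores)


def _embed_sites(
    rng: np.random.Generator,
    length: int,
    core: str,
    n_sites: int,
    junction_spanning: bool,
    other_cores: list[str],
    circular: bool,
    max_attempts: int,
) -> str:
    """Random sequence of ``length`` carrying exactly ``n_sites`` copies of
    ``core`` (one wrapping the junction if requested) and no other core."""
    k = len(core)
    n_interior = n_sites - (1 if junction_spanning else 0)
    # interior copies sit at evenly spaced, non-overlapping, non-wrapping slots
    lo, hi = k + 1, length - 2 * k
    if hi - lo < n_interior * (k + 1) or (junction_spanning and not circular):
        raise SequenceError(
            f"cannot embed {n_sites} sites of {k} nt in a {length} nt sequence"
        )
    positions = [lo + i * (hi - lo) // max(n_interior, 1) for i in range(n_interior)]
    all_cores = [core] + other_cores
    for _ in range(max_attempts):
        seq = list(_random_seq(rng, length))
        if not _clean_of_cores("".join(seq), all_cores, circular):
            continue
        for pos in positions:
            seq[pos : pos + k] = core
        if junction_spanning:
            split = int(rng.integers(1, k))  # split >= 1 nt on each side
            seq[length - split :] = core[:split]
            seq[: k - split] = core[split:]
        out = "".join(seq)
        # embedding may create accidental extra sites; verify exactly
        hay = out + out if circular else out
        own = {
            i % length if circular else i
            for i in range(length if circular else length - k + 1)
            if hay[i : i + k] == core
        }
        if len(own) != n_sites:
            continue
        if any(c in hay for c in other_cores):
            continue
        if junction_spanning and not any(i + k > length for i in {
            i for i in range(length) if (out + out)[i : i + k] == core
        }):
            continue
        return out
    raise GenerationError(
        f"failed to embed {n_sites} site(s) within {max_attempts} attempts"
    )


def _background_seq(
    rng: np.random.Generator,
    length: int,
    cores: list[str],
    circular: bool,
    max_attempts: int,
) -> str:
    for _ in range(max_attempts):
        seq = _random_seq(rng, length)
        if _clean_of_cores(seq, cores, circular):
            return seq
    raise GenerationError(
        f"failed to draw a site-free background sequence in {max_attempts} attempts"
    )


def generate_sequences(
    n_circ: int,
    n_mir: int,
    n_mrna: int,
    n_planted: int = 0,
    rng_seed: int = 0,
    circ_length: int = 400,
    utr_length: int = 800,
    mir_length: int = 22,
    n_de_extra: int = 0,
    de_extra_effect: float = 2.0,
    rules: MatchRules = DEFAULT_RULES,
    max_attempts: int = 1000,
) -> tuple[dict[str, dict[str, str]], SyntheticTruth]:
    """Generate FASTA-ready sequence sets plus the ground-truth ledger.

    The first ``n_planted`` ids of each class form the planted triplets; the
    next ``n_de_extra`` background ids of each class are marked as plain
    (uncoupled) differential features with effect ``de_extra_effect`` log2.
    """
    if n_planted > min(n_circ, n_mir, n_mrna):
        raise ValueError("n_planted exceeds a class size")
    if not 20 <= mir_length <= 24:
        raise ValueError("miRNA length must be 20-24 nt")
    rng = np.random.default_rng(rng_seed)

    ids = {
        "circ": [f"circ_{i:04d}" for i in range(n_circ)],
        "mir": [f"mir_{i:04d}" for i in range(n_mir)],
        "mrna": [f"mrna_{i:04d}" for i in range(n_mrna)],
    }

    # miRNAs with pairwise-distinct seed cores, so planted sites are unambiguous
    mir_seqs: dict[str, str] = {}
    cores: list[str] = []
    for mid in ids["mir"]:
        for _ in range(max_attempts):
            cand = _random_seq(rng, mir_length)
            core = revcomp_rna(seed_of(cand, "2_8"))
            if core not in cores:
                mir_seqs[mid] = cand
                cores.append(core)
                break
        else:
            raise GenerationError("could not draw miRNAs with distinct seeds")

    triplets = [
        PlantedTriplet(
            circ_id=ids["circ"][i], mir_id=ids["mir"][i], mrna_id=ids["mrna"][i]
        )
        for i in range(n_planted)
    ]

    circ_seqs: dict[str, str] = {}
    mrna_seqs: dict[str, str] = {}
    for i, cid in enumerate(ids["circ"]):
        if i < n_planted:
            t = triplets[i]
            own = cores[i]
            others = [c for j, c in enumerate(cores) if j != i]
            circ_seqs[cid] = _embed_sites(
                rng, circ_length, own, t.site_count_circ, t.junction_spanning,
                others, circular=True, max_attempts=max_attempts,
            )
        else:
            circ_seqs[cid] = _background_seq(
                rng, circ_length, cores, circular=True, max_attempts=max_attempts
            )
    for i, tid in enumerate(ids["mrna"]):
        if i < n_planted:
            t = triplets[i]
            own = cores[i]
            others = [c for j, c in enumerate(cores) if j != i]
            mrna_seqs[tid] = _embed_sites(
                rng, utr_length, own, t.site_count_mrna, False,
                others, circular=False, max_attempts=max_attempts,
            )
        else:
            mrna_seqs[tid] = _background_seq(
                rng, utr_length, cores, circular=False, max_attempts=max_attempts
            )

    # planted sites must be discoverable under the operative rules
    for i, t in enumerate(triplets):
        n_c = len({s.start for s in find_sites_circular(
            circ_seqs[t.circ_id], mir_seqs[t.mir_id], rules)})
        n_m = len({s.start for s in find_sites_linear(
            mrna_seqs[t.mrna_id], mir_seqs[t.mir_id], rules)})
        if n_c < t.site_count_circ or n_m < t.site_count_mrna:
            raise GenerationError("planted sites not recovered by the matcher")

    extra: dict[str, dict[str, float]] = {}
    if n_de_extra:
        for cls in ("circ", "mir", "mrna"):
            pool = ids[cls][n_planted : n_planted + n_de_extra]
            if len(pool) < n_de_extra:
                raise ValueError(f"not enough background {cls} features for extras")
            extra[cls] = {fid: float(de_extra_effect) for fid in pool}

    truth = SyntheticTruth(
        triplets=triplets,
        feature_ids=ids,
        extra_de_effects=extra,
        mrna_length_bp={tid: len(s) for tid, s in mrna_seqs.items()},
        rng_seed=rng_seed,
    )
    return {"circ": circ_seqs, "mir": mir_seqs, "mrna": mrna_seqs}, truth


def simulate_counts(
    design: StudyDesign,
    truth: SyntheticTruth,
    baseline_mean: float = 500.0,
    dispersion: float = 0.1,
    latent_sigma: float = 0.6,
    mir_latent_loading: float = 2.0,
    rng_seed: int = 0,
) -> dict[str, CountMatrix]:
    """NB count matrices for all three classes under the planted truth.

    ``latent_sigma`` is the log2 SD of the per-sample, per-triplet shared
    miRNA-activity factor; ``mir_latent_loading`` is how many log2 units the
    miRNA moves per unit movement of its targets (targets respond to the
    sponge factor with 1/loading-fold damping).
    """
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(rng_seed)
    samples = design.sample_ids()
    aging = np.array([design.is_aging(s) for s in samples], dtype=float)
    n_s = len(samples)

    # per-feature log2 age effects
    effects: dict[str, dict[str, float]] = {c: {} for c in ("circ", "mir", "mrna")}
    for t in truth.triplets:
        effects["circ"][t.circ_id] = t.effect_log2fc_circ
        effects["mir"][t.mir_id] = t.effect_log2fc_mir
        effects["mrna"][t.mrna_id] = t.effect_log2fc_mrna
    for cls, d in truth.extra_de_effects.items():
        effects[cls].update(d)

    # shared latent factor per triplet per sample (log2 scale)
    latent = {
        i: rng.normal(0.0, latent_sigma, n_s) if latent_sigma > 0 else np.zeros(n_s)
        for i in range(len(truth.triplets))
    }
    latent_term: dict[str, dict[str, np.ndarray]] = {c: {} for c in ("circ", "mir", "mrna")}
    for i, t in enumerate(truth.triplets):
        latent_term["circ"][t.circ_id] = latent[i]
        latent_term["mrna"][t.mrna_id] = latent[i]
        latent_term["mir"][t.mir_id] = -mir_latent_loading * latent[i]

    out: dict[str, CountMatrix] = {}
    for cls in ("circ", "mir", "mrna"):
        fids = truth.feature_ids[cls]
        log2_mu = np.zeros((len(fids), n_s))
        for r, fid in enumerate(fids):
            log2_mu[r] += effects[cls].get(fid, 0.0) * aging
            if fid in latent_term[cls]:
                log2_mu[r] += latent_term[cls][fid]
        mu = baseline_mean * np.exp2(log2_mu)
        if dispersion == 0:
            counts = rng.poisson(mu)
        else:
            size = 1.0 / dispersion
            counts = rng.negative_binomial(size, size / (size + mu))
        df = pd.DataFrame(counts, index=fids, columns=samples)
        # library size emulates total mapped reads: a depth far above the
        # class-assigned column sums, so normalization denominators are not
        # perturbed by the planted features (no composition bias)
        depth = int(np.ceil(10 * baseline_mean * len(fids)))
        lib = pd.Series(
            np.maximum(depth, df.sum(axis=0).to_numpy()), index=samples
        )
        lengths = None
        if cls == "mrna" and truth.mrna_length_bp:
            lengths = pd.Series(
                {fid: truth.mrna_length_bp.get(fid, 1000) for fid in fids}
            )
        out[cls] = CountMatrix(df, library_size=lib, feature_length_bp=lengths)
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, circular: bool = False) -> None:
    """Deterministic FASTA; circRNA records carry ``circular=true``."""
    with open(path, "w") as fh:
        for sid in seqs:
            desc = " circular=true" if circular else ""
            fh.write(f">{sid}{desc}\n{seqs[sid]}\n")
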