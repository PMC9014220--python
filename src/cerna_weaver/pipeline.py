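"""End-to-end orchestration: simulate/load -> quantify -> DE -> sites ->
triplets -> network -> enrichment, with config, manifest, and logging.

A run is driven by a :class:`RunConfig` (YAML round-trippable). The 2x2
design yields two two-group contrasts by slicing — aging vs young within
each condition — and each contrast gets its own DE tables, triplet table and
network files in a flat per-comparison directory, plus one shared
``manifest.json`` recording versions, thresholds, seed and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import DEThresholds, call_de, de_table, write_de_table
from .enrichment import (
    EnrichmentThresholds,
    enrich,
    enrichment_table,
    read_gmt,
    term_similarity_network,
)
from .matrix import CountMatrix, read_length_table
from .network import (
    CeRNANetwork,
    TripletThresholds,
    assemble,
    candidate_pairs,
    score_triplets,
    triplet_table,
)
from .quantify import normalize
from .seeds import MatchRules, find_all_sites, read_fasta, write_sites
from .synthetic import StudyDesign, generate_sequences, simulate_counts, write_fasta

logger = logging.getLogger(__name__)

RNA_CLASSES = ("circ", "mir", "mrna")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained (exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class SyntheticConfig:
    n_circ: int = 40
    n_mir: int = 30
    n_mrna: int = 60
    n_planted: int = 5
    baseline_mean: float = 500.0
    dispersion: float = 0.1
    latent_sigma: float = 0.6
    mir_latent_loading: float = 2.0
    circ_length: int = 400
    utr_length: int = 800


@dataclass
class InputPaths:
    counts_circ: str = ""
    counts_mir: str = ""
    counts_mrna: str = ""
    fasta_circ: str = ""
    fasta_mir: str = ""
    fasta_mrna: str = ""
    mrna_lengths: str = ""
    gmt: str = ""


@dataclass
class Comparison:
    name: str
    group_a: dict = field(default_factory=lambda: {"age": "young"})
    group_b: dict = field(default_factory=lambda: {"age": "aging"})


def default_comparisons() -> list[Comparison]:
    return [
        Comparison(
            "aging_vs_young_control",
            {"age": "young", "condition": "control"},
            {"age": "aging", "condition": "control"},
        ),
        Comparison(
            "aging_vs_young_surgery",
            {"age": "young", "condition": "surgery"},
            {"age": "aging", "condition": "surgery"},
        ),
    ]


@dataclass
class RunConfig:
    """Full run description; round-trips through YAML unchanged."""

    rng_seed: int = 0
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    inputs: InputPaths = field(default_factory=InputPaths)
    de: DEThresholds = field(default_factory=DEThresholds)
    triplet: TripletThresholds = field(default_factory=TripletThresholds)
    enrichment: EnrichmentThresholds = field(default_factory=EnrichmentThresholds)
    kappa_min: float = 0.3
    allowed_site_types: tuple = ("7mer-m8", "8mer")
    require_opposite_direction: bool = False
    replicates_per_group: int = 3
    comparisons: list[Comparison] = field(default_factory=default_comparisons)

    def match_rules(self) -> MatchRules:
        return MatchRules(allowed_types=frozenset(self.allowed_site_types))

    def validate(self) -> None:
        try:
            self.match_rules()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        for thr, lo, hi, name in (
            (self.de.max_p, 0, 1, "de.max_p"),
            (self.triplet.cor_min, -1, 1, "triplet.cor_min"),
            (self.enrichment.max_p, 0, 1, "enrichment.max_p"),
            (self.kappa_min, -1, 1, "kappa_min"),
        ):
            if not lo <= thr <= hi:
                raise ConfigError(f"{name}={thr} outside [{lo}, {hi}]")
        if self.de.min_abs_log2fc < 0 or self.enrichment.min_count < 0:
            raise ConfigError("thresholds must be non-negative")
        if self.synthetic is None:
            missing = [
                f
                for f in (
                    self.inputs.counts_circ,
                    self.inputs.counts_mir,
                    self.inputs.counts_mrna,
                    self.inputs.fasta_circ,
                    self.inputs.fasta_mir,
                    self.inputs.fasta_mrna,
                )
                if not f or not Path(f).exists()
            ]
            if missing:
                raise ConfigError(f"missing input files: {missing}")
        if self.inputs.gmt and not Path(self.inputs.gmt).exists():
            raise ConfigError(f"GMT file not found: {self.inputs.gmt}")
        if not self.comparisons:
            raise ConfigError("at least one comparison required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_site_types"] = list(self.allowed_site_types)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if "inputs" in d:
            d["inputs"] = InputPaths(**d["inputs"])
        if "de" in d:
            d["de"] = DEThresholds(**d["de"])
        if "triplet" in d:
            d["triplet"] = TripletThresholds(**d["triplet"])
        if "enrichment" in d:
            d["enrichment"] = EnrichmentThresholds(**d["enrichment"])
        if "allowed_site_types" in d:
            d["allowed_site_types"] = tuple(d["allowed_site_types"])
        if "comparisons" in d:
            d["comparisons"] = [
                c if isinstance(c, Comparison) else Comparison(**c)
                for c in d["comparisons"]
            ]
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad config: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        return cls.from_dict(payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def one_read_pseudocounts(counts: dict[str, CountMatrix]) -> dict:
    """Class-unit value of a single read, for log-transform regularization.

    One back-splice read in SRPBM units (at the median library size), one
    miRNA read in TPM units (at the median class total), and one mRNA
    fragment in FPKM units (per-feature, via its length). Using the one-read
    scale makes the log pseudocount independent of each unit's arbitrary
    magnitude — the log-CPM prior-count convention.
    """
    pc = {}
    pc["circ"] = 1e9 / float(np.median(counts["circ"].library_size))
    pc["mir"] = 1e6 / float(np.median(counts["mir"].counts.sum(axis=0)))
    mrna = counts["mrna"]
    lib_term = 1e6 / float(np.median(mrna.library_size))
    if mrna.feature_length_bp is not None:
        pc["mrna"] = (1e3 / mrna.feature_length_bp.astype(float)) * lib_term
    else:
        pc["mrna"] = lib_term
    return pc


def infer_network(
    counts: dict[str, CountMatrix],
    sites_circ,
    sites_mrna,
    samples_a: list[str],
    samples_b: list[str],
    de_thresholds: DEThresholds = DEThresholds(),
    triplet_thresholds: TripletThresholds = TripletThresholds(),
    require_opposite_direction: bool = False,
):
    """Run DE -> pairing -> scoring -> assembly for one two-group contrast.

    Returns ``(network, de_records, triplets)`` where ``de_records`` maps
    class name to the full DE table for the contrast.
    """
    samples = samples_a + samples_b
    de_records = {}
    expr = {}
    for cls in RNA_CLASSES:
        cm = counts[cls]
        ex = normalize(cm, cls)
        expr[cls] = ex.values
        de_records[cls] = call_de(
            ex.values[samples_a],
            ex.values[samples_b],
            cm.subset_samples(samples_a),
            cm.subset_samples(samples_b),
            de_thresholds,
        )
    circ_pairs, mrna_pairs = candidate_pairs(
        de_records["circ"],
        de_records["mir"],
        de_records["mrna"],
        sites_circ,
        sites_mrna,
        require_opposite_direction=require_opposite_direction,
    )
    triplets = score_triplets(
        circ_pairs,
        mrna_pairs,
        expr["circ"][samples],
        expr["mir"][samples],
        expr["mrna"][samples],
        triplet_thresholds,
        pseudocounts=one_read_pseudocounts(counts),
    )
    direction = {
        r.feature_id: r.direction for recs in de_records.values() for r in recs
    }
    log2fc = {
        r.feature_id: r.log2_fold_change
        for recs in de_records.values()
        for r in recs
    }
    net = assemble(triplets, de_direction=direction, de_log2fc=log2fc)
    return net, de_records, triplets


@_stage("inputs")
def _obtain_inputs(config: RunConfig, outdir: Path):
    design = StudyDesign(replicates_per_group=config.replicates_per_group)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    if config.synthetic is not None:
        syn = config.synthetic
        seqs, truth = generate_sequences(
            syn.n_circ,
            syn.n_mir,
            syn.n_mrna,
            n_planted=syn.n_planted,
            rng_seed=config.rng_seed,
            circ_length=syn.circ_length,
            utr_length=syn.utr_length,
            rules=config.match_rules(),
        )
        counts = simulate_counts(
            design,
            truth,
            baseline_mean=syn.baseline_mean,
            dispersion=syn.dispersion,
            latent_sigma=syn.latent_sigma,
            mir_latent_loading=syn.mir_latent_loading,
            rng_seed=config.rng_seed + 1,
        )
        write_fasta(seqs["circ"], indir / "circ.fa", circular=True)
        write_fasta(seqs["mir"], indir / "mir.fa")
        write_fasta(seqs["mrna"], indir / "mrna.fa")
        truth.to_json(indir / "truth.json")
        for cls in RNA_CLASSES:
            counts[cls].write_tsv(indir / f"counts_{cls}.tsv")
        logger.info(
            "stage=inputs mode=synthetic circ=%d mir=%d mrna=%d planted=%d",
            syn.n_circ, syn.n_mir, syn.n_mrna, syn.n_planted,
        )
    else:
        seqs = {
            "circ": read_fasta(config.inputs.fasta_circ),
            "mir": read_fasta(config.inputs.fasta_mir),
            "mrna": read_fasta(config.inputs.fasta_mrna),
        }
        lengths = (
            read_length_table(config.inputs.mrna_lengths)
            if config.inputs.mrna_lengths
            else None
        )
        counts = {
            "circ": CountMatrix.read_tsv(config.inputs.counts_circ),
            "mir": CountMatrix.read_tsv(config.inputs.counts_mir),
            "mrna": CountMatrix.read_tsv(
                config.inputs.counts_mrna, feature_length_bp=lengths
            ),
        }
        logger.info("stage=inputs mode=files")
    return design, seqs, counts


@_stage("quantify")
def _quantify(counts, outdir: Path):
    exprs = {}
    for cls in RNA_CLASSES:
        exprs[cls] = normalize(counts[cls], cls)
        exprs[cls].write_tsv(outdir / f"expression_{cls}.tsv")
        logger.info(
            "stage=quantify class=%s unit=%s features=%d",
            cls, exprs[cls].unit, len(exprs[cls].feature_ids),
        )
    return exprs


@_stage("sites")
def _sites(seqs, rules: MatchRules, outdir: Path):
    sites_circ = find_all_sites(seqs["circ"], seqs["mir"], circular=True, rules=rules)
    sites_mrna = find_all_sites(seqs["mrna"], seqs["mir"], circular=False, rules=rules)
    write_sites(sites_circ, outdir / "sites_circ.tsv")
    write_sites(sites_mrna, outdir / "sites_mrna.tsv")
    logger.info(
        "stage=sites circ_sites=%d mrna_sites=%d", len(sites_circ), len(sites_mrna)
    )
    return sites_circ, sites_mrna


@_stage("network")
def _comparison_outputs(
    config: RunConfig, design, counts, sites_circ, sites_mrna, comp, outdir: Path
) -> dict:
    samples_a = design.samples_for(**comp.group_a)
    samples_b = design.samples_for(**comp.group_b)
    if not samples_a or not samples_b:
        raise ConfigError(f"comparison {comp.name}: empty sample group")
    cdir = outdir / comp.name
    cdir.mkdir(parents=True, exist_ok=True)
    net, de_records, triplets = infer_network(
        counts,
        sites_circ,
        sites_mrna,
        samples_a,
        samples_b,
        de_thresholds=config.de,
        triplet_thresholds=config.triplet,
        require_opposite_direction=config.require_opposite_direction,
    )
    for cls in RNA_CLASSES:
        write_de_table(de_records[cls], cdir / f"de_{cls}.tsv")
    triplet_table(triplets).to_csv(cdir / "triplets.tsv", sep="\t", index=False)
    net.write_edges(cdir / "network_edges.tsv")
    net.write_graphml(cdir / "network.graphml")
    counts_summary = {
        "de_passing": {
            cls: sum(r.passes_filter for r in de_records[cls]) for cls in RNA_CLASSES
        },
        "triplets_scored": len(triplets),
        "triplets_valid": sum(t.valid for t in triplets),
        "nodes": net.n_nodes,
        "edges": net.n_edges,
    }
    logger.info("stage=network comparison=%s %s", comp.name, counts_summary)

    if config.inputs.gmt:
        terms = read_gmt(config.inputs.gmt)
        background = counts["mrna"].feature_ids
        gene_list = net.nodes_of_class("mRNA")
        if gene_list:
            enriched = enrich(gene_list, terms, background, config.enrichment)
            enrichment_table(enriched).to_csv(
                cdir / "enrichment.tsv", sep="\t", index=False
            )
            tg = term_similarity_network(enriched, terms, background, config.kappa_min)
            import networkx as nx

            nx.write_graphml(tg, str(cdir / "term_network.graphml"))
            counts_summary["terms_passing"] = sum(t.passes for t in enriched)
            logger.info(
                "stage=enrich comparison=%s terms_passing=%d",
                comp.name, counts_summary["terms_passing"],
            )
    return counts_summary


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    written before the failure are retained for inspection.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design, seqs, counts = _obtain_inputs(config, outdir)
    _quantify(counts, outdir)
    sites_circ, sites_mrna = _sites(seqs, config.match_rules(), outdir)
    stage_counts = {}
    for comp in config.comparisons:
        stage_counts[comp.name] = _comparison_outputs(
            config, design, counts, sites_circ, sites_mrna, comp, outdir
        )
    manifest = {
        "package": "cerna-weaver",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "rng_seed": config.rng_seed,
        "config": config.to_dict(),
        "input_checksums": {
            p.name: _sha256(p) for p in sorted((outdir / "inputs").glob("*"))
        }
        if (outdir / "inputs").exists()
        else {},
        "stage_counts": stage_counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("stage=done outdir=%s", outdir)
    return outdir
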