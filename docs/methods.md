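# Methods

## Scope and data model

The pipeline starts from integer count matrices — one per RNA class, features
× samples — over a 2×2 design (age: young/aging × condition:
control/surgery) with equal replication (default 3, the usual depth of mouse
hippocampus studies). circRNAs are quantified by back-splice-junction reads,
miRNAs by mature-read counts, mRNAs by fragments with an exon-model length
per feature. Library size is the per-sample total of mapped reads and may far
exceed a class's column sum; when no mapping total is supplied, the column
sum is used as a self-contained fallback. Contrasts are always two-group and
obtained by slicing the design (aging vs young within each condition); no
interaction modeling is attempted.

## Normalization

* SRPBM = count / library_size × 10⁹ (junction reads per billion mapped).
* miRNA "TPM" = count / class column sum × 10⁶. Mature miRNAs are ~22 nt, so
  the length term of transcript TPM is a constant; reads-per-million over the
  class is the miRNA-seq convention and is what is implemented. Columns of
  the output sum to 10⁶ by construction.
* FPKM = count / (length/10³) / (library_size/10⁶).

SRPBM and FPKM are invariant under joint scaling of counts and library sizes;
all three units are recorded in the output files (`# unit=` header).

## Differential expression

Replicates are pooled per group and each feature is tested on the 2×2 table
[[count_a, lib_a − count_a], [count_b, lib_b − count_b]] with the two-sided
Fisher exact test (point-probability summation), BH-adjusted across features.
Fold changes use normalized expression means with pseudocount 0.1 so
zero-count features remain representable. The filter is |log2FC| ≥ 1 and raw
P ≤ 0.05 (both configurable); adjusted P is always reported but not filtered
on, matching the stated criteria of the source analysis. Ties in output order
are broken by feature id.

### Calibration of the pooled Fisher test

Pooling replicates before an exact test discards biological (between-
replicate) variance. Under the test's own sampling assumptions — counts with
no overdispersion — the test is exact and, being discrete, slightly
conservative: on simulated null Poisson counts the empirical rejection rate
at P ≤ 0.05 is ≈ 0.046 (the suite asserts ≤ nominal + 2 MC SE). On
negative-binomial counts with dispersion 0.1 the same procedure rejects
≈ 0.78 of null features: the conditional variance of the pooled count given
the margins is ~50× the hypergeometric variance, so the exact P-values are
badly anti-conservative. The acceptance suite measures and reports this
honestly rather than hiding it; the practical remedy (an exact test with an
estimated dispersion, edgeR-style) is deliberately out of scope because the
implemented procedure is the one under study. Consequence for interpretation:
with overdispersed data the P ≤ 0.05 criterion behaves as a weak filter and
the fold-change threshold does most of the work.

## Seed matching

The seed is miRNA positions 2–8 (1-based). On a target read 5′→3′ a site is
the reverse complement of the seed, optionally followed by an adenine
opposite miRNA position 1: 8mer (2–8 + A1), 7mer-m8 (2–8), 7mer-A1 (2–7 +
A1), 6mer (2–7). The default rule set accepts 7mer-m8/8mer only — perfect
Watson–Crick pairing, no G:U — because that is the strictest common
convention; the weaker classes are opt-in flags. T and U are interchangeable
on input; coordinates are 0-based half-open on the as-given linearization.
Circular targets are scanned on the doubled string with starts restricted to
one period; a site whose end exceeds the period spans the back-splice
junction and is flagged. Circular site counts are never below linear counts
and are invariant under rotation of the linearization (both properties are
tested against brute-force rotation enumeration). Thermodynamic scoring,
conservation and 3′-supplementary pairing are out of scope.

## Triplet scoring and network assembly

Candidate pairs require both members to pass the DE filter and at least one
seed site (site support counted as distinct start positions). miRNAs present
in both a circRNA pair and an mRNA pair ("intersection miRNAs") define the
candidate triplets. An optional constraint requiring the miRNA's DE direction
to oppose both partners is off by default — the packaged published tables
pair a down-regulated circRNA with a down-regulated miRNA, so the source
analysis cannot have enforced it.

Scoring uses Pearson correlations across the contrast's six samples on
log2-transformed normalized expression. The transform adds the class-unit
value of **one read** before the log (one junction read in SRPBM units, one
miRNA read in TPM units, one fragment in FPKM units at the feature's length)
— the log-CPM prior-count convention. A fixed +1 would be unit-dependent: a
no-op at SRPBM magnitudes, dominant at FPKM magnitudes, and the analysis
would change under a pure rescaling of units. The sensitivity value

S = cor_xy − (cor_xy − cor_cm·cor_tm)/√((1−cor_cm²)(1−cor_tm²))

is the raw circ–mRNA correlation minus their partial correlation given the
miRNA; it is near zero when the miRNA is uninvolved (cor_cm = cor_tm = 0 ⇒
S = 0) and large when conditioning on the miRNA collapses the coupling. The
partial-correlation term is verified against an independent
regression-residual oracle to 10⁻¹⁰. Defaults cor_xy ≥ 0.7 and S ≥ 0.3 are
effect-size thresholds; with n = 6 samples correlation P-values are
uninformative and are not computed. Triplets with a zero-variance member are
dropped with a logged reason. Valid triplets are assembled into a graph
bipartite between miRNAs and {circRNAs, mRNAs}; nodes carry class, DE
direction and log2FC, edges carry arm type, site support and owning triplet
ids; node and edge order is deterministic.

## Enrichment

Terms are scored by the hypergeometric upper tail P(X ≥ count) of the overlap
between the query list and the term within a background universe (default:
all quantified mRNA features; configurable), BH-adjusted across terms.
Passing requires raw P < 0.05, count ≥ 3 and enrichment factor
(count/list)/(term/background) > 1.5. Passing terms form a similarity network
with edges where Cohen's kappa of the two membership indicator vectors over
the background exceeds 0.3 — kappa being the documented convention behind
"similarity" in Metascape-style term networks. Collections are supplied as
GMT files; no live database access, no GO DAG propagation, no ID conversion.
Multi-list runs produce one result table per list plus a terms × lists
−log10 P heatmap table.

## Synthetic data generator

The generator emulates the structure the inference assumes, not the
sequencing process (no reads, no alignment, no isoforms, no batch effects).

**Sequences.** miRNAs are random 20–24-mers with pairwise-distinct seeds.
Planted circRNAs/3′UTRs carry exactly `site_count` embedded copies of their
miRNA's site (default 2 per arm; one circRNA copy spans the junction), are
verified post-embedding by the matcher itself, and contain no site for any
other miRNA. All background sequences are rejection-sampled (≤ 1000 attempts,
then an explicit error) to be site-free for every generated miRNA under the
operative rules, so a run with nothing planted is structurally incapable of
producing pairs. Defaults: 400 nt circles, 800 nt UTRs.

**Counts.** NB(mean, dispersion) with variance = mean + dispersion·mean²
(dispersion 0 → Poisson), baseline mean 500, dispersion 0.1 — a typical bulk
RNA-seq biological CV of ~32%. Differential expression enters as a log2 group
effect on aging samples. Sponge coupling is a per-triplet, per-sample latent
miRNA-activity factor z ~ N(0, σ) (log2 scale): planted circRNA and mRNA
means are multiplied by 2^z, the miRNA mean by 2^(−L·z). Reported library
sizes emulate total mapped reads (10 × baseline × features), so normalization
denominators are not perturbed by the planted features.

**Default "strong coupling" scenario** (5 triplets): target effects +3 log2,
miRNA effect −6 log2, σ = 0.6, loading L = 2. These values come from a
design-time power analysis of the n = 3-per-group setting: the sample partial
correlation from six samples has Fisher-z SD ≈ 0.7, so per-triplet recovery
is limited by estimator noise, not by biology. Two facts shape the choice:
(i) the miRNA's age-effect : latent-loading ratio must equal the targets'
(effects −6 : +3 match the latent loadings −2 : +1), otherwise conditioning on the miRNA
cannot remove the age-driven covariance and S collapses; (ii) the miRNA must
read the shared factor with low relative noise (loading 2 halves its
effective measurement noise), otherwise the partial correlation has a floor
of σ²_mir/(σ²_mir + σ²_target) = 0.5 and S rarely clears 0.3 at any coupling
strength. At the chosen point per-triplet recovery is ≈ 0.7–0.8 and the
pooled edge-set F1 over 20 seeds is ≈ 0.83 (recomputed by the acceptance
suite). What passing recovery shows: the chain DE → sites → intersection →
scoring → assembly is wired correctly and identifiable under its own
assumptions. What it does not show: performance on real tissue, where
effects are weaker, dispersions vary per gene, miRNA action is shared across
many targets, and sites are not the only coupling mechanism.

## Numerical and degenerate-input choices

* Fisher P via two-sided point-probability summation (tested to 10⁻¹²
  against exact rational enumeration); count > library is an error.
* BH via the standard step-up, clipped at 1 (tested to 10⁻¹² against a
  hand-rolled oracle); inputs outside [0,1] rejected.
* log2FC pseudocount 0.1 (report scale); one-read pseudocount (correlation
  scale) — two different roles, documented above.
* Pearson requires ≥ 3 paired samples and non-zero variance; |cor| = 1 on a
  conditioning arm makes the partial correlation undefined and drops the
  triplet.
* Hypergeometric terms with empty in-background membership are skipped;
  query genes outside the background are dropped with a logged count.
* All orderings (DE tables, sites, triplets, graph nodes/edges) are
  deterministic; identical seeds give byte-identical outputs.

## Problem sizes used by the shipped experiments

Recovery: 40/30/60 features, 5 planted triplets, seeds 1–20. Null-network:
12/10/16 features, 100 seeds. Null calibration: 2000 features per dataset,
3 datasets in the test suite, 10 in the acceptance script. Chosen as the
smallest sizes at which the Monte-Carlo error of each estimate is well below
its decision margin.

## Known limitations

* The pooled Fisher test ignores overdispersion (measured above); it is the
  procedure under study, not a recommendation.
* S thresholds are heuristics; with six samples the S estimate is noisy, and
  real studies should treat the triplet list as candidates for validation.
* The miRNA "TPM" is class-internal and sensitive to composition shifts of
  highly expressed miRNAs.
* Enrichment assumes an unstructured background; GO term relationships are
  not modeled.
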