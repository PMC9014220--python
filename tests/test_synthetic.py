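"""Generator contracts: planted sites, NB counts, coupling, determinism."""

import numpy as np
import pytest

from cerna_weaver import (
    ALL_RULES,
    CountMatrix,
    PlantedTriplet,
    StudyDesign,
    SyntheticTruth,
    call_de,
    find_sites_circular,
    find_sites_linear,
    generate_sequences,
    simulate_counts,
    write_fasta,
)
from cerna_weaver.synthetic import GenerationError


class TestStudyDesign:
    def test_default_design_has_twelve_samples(self, design):
        ids = design.sample_ids()
        assert len(ids) == 12
        assert ids[0] == "young_control_1"

    def test_group_slicing(self, design):
        ctrl = design.samples_for(condition="control")
        assert len(ctrl) == 6
        assert all("control" in s for s in ctrl)
        aging_surgery = design.samples_for(age="aging", condition="surgery")
        assert aging_surgery == ["aging_surgery_1", "aging_surgery_2", "aging_surgery_3"]

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(replicates_per_group=1)


class TestGenerateSequences:
    def test_vacuous_planting_leaves_no_sites_anywhere(self):
        seqs, truth = generate_sequences(10, 8, 12, n_planted=0, rng_seed=7)
        assert truth.triplets == []
        for cid, cseq in seqs["circ"].items():
            for mseq in seqs["mir"].values():
                assert find_sites_circular(cseq, mseq) == []
        for tseq in seqs["mrna"].values():
            for mseq in seqs["mir"].values():
                assert find_sites_linear(tseq, mseq) == []

    def test_planted_sites_discoverable_at_requested_counts(self):
        seqs, truth = generate_sequences(6, 6, 6, n_planted=3, rng_seed=11)
        for t in truth.triplets:
            circ_sites = find_sites_circular(
                seqs["circ"][t.circ_id], seqs["mir"][t.mir_id]
            )
            mrna_sites = find_sites_linear(
                seqs["mrna"][t.mrna_id], seqs["mir"][t.mir_id]
            )
            assert len({s.start for s in circ_sites}) == t.site_count_circ
            assert len({s.start for s in mrna_sites}) == t.site_count_mrna

    def test_junction_spanning_site_invisible_to_linear_scan(self):
        seqs, truth = generate_sequences(4, 4, 4, n_planted=1, rng_seed=3)
        t = truth.triplets[0]
        assert t.junction_spanning
        circ = seqs["circ"][t.circ_id]
        mir = seqs["mir"][t.mir_id]
        circular = find_sites_circular(circ, mir)
        linear = find_sites_linear(circ, mir)
        assert any(s.spans_junction for s in circular)
        assert len(linear) < len(circular)

    def test_cross_triplet_sequences_carry_no_foreign_sites(self):
        seqs, truth = generate_sequences(5, 5, 5, n_planted=3, rng_seed=19)
        for t in truth.triplets:
            for other in truth.triplets:
                if other.mir_id == t.mir_id:
                    continue
                mir = seqs["mir"][other.mir_id]
                assert find_sites_circular(seqs["circ"][t.circ_id], mir) == []
                assert find_sites_linear(seqs["mrna"][t.mrna_id], mir) == []

    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        out = []
        for run in (0, 1):
            seqs, _ = generate_sequences(8, 6, 8, n_planted=2, rng_seed=42)
            p = tmp_path / f"circ_{run}.fa"
            write_fasta(seqs["circ"], p, circular=True)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_circular_flag_written_to_fasta(self, tmp_path):
        seqs, _ = generate_sequences(2, 2, 2, rng_seed=0)
        p = tmp_path / "circ.fa"
        write_fasta(seqs["circ"], p, circular=True)
        assert "circular=true" in p.read_text()

    def test_impossible_embedding_rejected_with_message(self):
        with pytest.raises((GenerationError, ValueError), match="embed|short"):
            generate_sequences(
                2, 2, 2, n_planted=1, rng_seed=0, circ_length=24, utr_length=800
            )

    def test_planted_exceeding_class_size_rejected(self):
        with pytest.raises(ValueError, match="n_planted"):
            generate_sequences(2, 3, 4, n_planted=3)

    def test_truth_round_trips_through_json(self, tmp_path):
        _, truth = generate_sequences(6, 5, 7, n_planted=2, rng_seed=9, n_de_extra=1)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = SyntheticTruth.from_json(p)
        assert back.triplets == truth.triplets
        assert back.feature_ids == truth.feature_ids
        assert back.extra_de_effects == truth.extra_de_effects
        assert back.rng_seed == truth.rng_seed
        assert back.de_features == truth.de_features


class TestSimulateCounts:
    def test_null_poisson_means_match_baseline(self, design):
        """All effects zero, dispersion zero, baseline 1000: per-feature mean
        within 5 standard errors of baseline over >= 50 draws."""
        _, truth = generate_sequences(5, 4, 5, n_planted=0, rng_seed=1)
        counts = simulate_counts(
            design, truth, baseline_mean=1000.0, dispersion=0.0, rng_seed=2
        )
        pooled = np.concatenate(
            [counts[c].counts.to_numpy().ravel() for c in counts]
        )
        assert pooled.size >= 50
        se = np.sqrt(1000.0 / pooled.size)
        assert abs(pooled.mean() - 1000.0) <= 5 * se

    def test_determinism(self, design):
        _, truth = generate_sequences(5, 4, 5, n_planted=2, rng_seed=1)
        a = simulate_counts(design, truth, rng_seed=8)
        b = simulate_counts(design, truth, rng_seed=8)
        for cls in a:
            assert a[cls].counts.equals(b[cls].counts)

    def test_library_size_dominates_column_sums(self, design):
        _, truth = generate_sequences(5, 4, 5, n_planted=2, rng_seed=1)
        counts = simulate_counts(design, truth, rng_seed=3)
        for cm in counts.values():
            assert (cm.library_size >= cm.counts.sum(axis=0)).all()

    def test_de_power_of_planted_effect(self, design):
        """A feature with a planted 2-log2 effect at baseline 500 is flagged
        by the Fisher+filter pipeline in >= 90 of 100 seeded simulations."""
        _, truth = generate_sequences(
            6, 4, 6, n_planted=0, rng_seed=1, n_de_extra=1, de_extra_effect=2.0
        )
        target = next(iter(truth.extra_de_effects["mrna"]))
        young = design.samples_for(age="young", condition="control")
        aging = design.samples_for(age="aging", condition="control")
        hits = 0
        for seed in range(1, 101):
            counts = simulate_counts(design, truth, baseline_mean=500.0, rng_seed=seed)
            cm = counts["mrna"]
            expr = cm.counts.astype(float)
            records = call_de(
                expr[young], expr[aging],
                cm.subset_samples(young), cm.subset_samples(aging),
            )
            by_id = {r.feature_id: r for r in records}
            hits += by_id[target].passes_filter
        assert hits >= 90

    def test_planted_fold_change_recovered_in_median(self, design):
        """Median observed log2FC across 100 seeds within +-0.3 of truth."""
        _, truth = generate_sequences(
            4, 3, 4, n_planted=0, rng_seed=1, n_de_extra=1, de_extra_effect=2.0
        )
        target = next(iter(truth.extra_de_effects["circ"]))
        young = design.samples_for(age="young", condition="control")
        aging = design.samples_for(age="aging", condition="control")
        fcs = []
        for seed in range(1, 101):
            counts = simulate_counts(design, truth, baseline_mean=500.0, rng_seed=seed)
            row = counts["circ"].counts.loc[target]
            fcs.append(
                np.log2((row[aging].mean() + 0.1) / (row[young].mean() + 0.1))
            )
        assert abs(np.median(fcs) - 2.0) <= 0.3

    def test_sponge_coupling_sign(self, design):
        """Planted circRNA and mRNA co-vary positively (and each against the
        miRNA negatively) in >= 95 of 100 simulations."""
        _, truth = generate_sequences(4, 3, 4, n_planted=1, rng_seed=1)
        t = truth.triplets[0]
        samples = design.samples_for(condition="control")
        pos = neg = 0
        for seed in range(1, 101):
            counts = simulate_counts(design, truth, rng_seed=seed)
            c = np.log2(counts["circ"].counts.loc[t.circ_id, samples] + 1.0)
            m = np.log2(counts["mir"].counts.loc[t.mir_id, samples] + 1.0)
            g = np.log2(counts["mrna"].counts.loc[t.mrna_id, samples] + 1.0)
            pos += np.corrcoef(c, g)[0, 1] > 0
            neg += np.corrcoef(c, m)[0, 1] < 0
        assert pos >= 95
        assert neg >= 95

    def test_invalid_parameters_rejected(self, design):
        _, truth = generate_sequences(2, 2, 2, rng_seed=0)
        with pytest.raises(ValueError):
            simulate_counts(design, truth, baseline_mean=0.0)
        with pytest.raises(ValueError):
            simulate_counts(design, truth, dispersion=-0.5)

    def test_planted_triplet_requires_sites(self):
        with pytest.raises(ValueError, match="site"):
            PlantedTriplet("c", "m", "t", site_count_circ=0)
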