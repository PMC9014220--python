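"""Triplet scoring (cor_xy, sensitivity S), pairing, and network assembly."""

import numpy as np
import pandas as pd
import pytest

from cerna_weaver import (
    DERecord,
    SeedSite,
    TripletThresholds,
    assemble,
    candidate_pairs,
    fixture_network,
    load_control_table,
    load_surgery_table,
    pearson,
    relationship_s,
    score_triplets,
    shared_mirnas,
)


def _de(fid, lfc, passes=True, direction=None):
    return DERecord(
        feature_id=fid,
        mean_expr_a=1.0,
        mean_expr_b=2.0,
        log2_fold_change=lfc,
        p_value=0.01,
        p_adjusted=0.02,
        direction=direction or ("up" if lfc > 0 else "down"),
        passes_filter=passes,
    )


def _site(target, mir, start=0):
    return SeedSite(
        mir_id=mir, target_id=target, site_type="7mer-m8", start=start, end=start + 7
    )


class TestPearson:
    def test_identity(self):
        assert pearson([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = np.array([0.3, 1.7, 2.2, 4.0])
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroDivisionError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestRelationshipS:
    def test_no_mirna_involvement_means_no_sensitivity(self):
        for cor_xy in (-0.9, 0.0, 0.5, 0.99):
            assert relationship_s(cor_xy, 0.0, 0.0) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        s = relationship_s(0.9, -0.8, -0.8)
        assert s == pytest.approx(0.9 - (0.9 - 0.64) / 0.36)
        assert s == pytest.approx(0.1778, abs=5e-5)

    def test_partial_term_matches_regression_residual_oracle(self, rng):
        """The conditioned term equals the correlation of the residuals of
        circ ~ miR and mRNA ~ miR ordinary least squares fits."""
        for _ in range(200):
            n = int(rng.integers(6, 30))
            m = rng.normal(size=n)
            c = 0.5 * m + rng.normal(size=n)
            t = -0.7 * m + rng.normal(size=n)
            cor_xy, cor_cm, cor_tm = pearson(c, t), pearson(c, m), pearson(t, m)
            design = np.column_stack([np.ones(n), m])
            res_c = c - design @ np.linalg.lstsq(design, c, rcond=None)[0]
            res_t = t - design @ np.linalg.lstsq(design, t, rcond=None)[0]
            partial = cor_xy - relationship_s(cor_xy, cor_cm, cor_tm)
            assert partial == pytest.approx(pearson(res_c, res_t), abs=1e-10)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relationship_s(0.5, 1.0, -0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            relationship_s(1.5, 0.0, 0.0)


class TestCandidatePairs:
    def test_pair_needs_both_de_and_a_site(self):
        de_c = [_de("c1", 2.0), _de("c2", 2.0, passes=False)]
        de_m = [_de("m1", -2.0)]
        de_t = [_de("t1", 2.0)]
        sites_c = [_site("c1", "m1"), _site("c2", "m1")]
        sites_t = [_site("t1", "m1"), _site("t1", "m_other")]
        cp, tp = candidate_pairs(de_c, de_m, de_t, sites_c, sites_t)
        assert cp == {("c1", "m1"): 1}
        assert tp == {("t1", "m1"): 1}

    def test_no_sites_no_pairs(self):
        cp, tp = candidate_pairs([_de("c", 2)], [_de("m", -2)], [_de("t", 2)], [], [])
        assert cp == {} and tp == {}

    def test_site_count_uses_distinct_starts(self):
        de_c, de_m, de_t = [_de("c", 2)], [_de("m", -2)], [_de("t", 2)]
        sites = [_site("c", "m", 0), _site("c", "m", 0), _site("c", "m", 9)]
        cp, _ = candidate_pairs(de_c, de_m, de_t, sites, [])
        assert cp == {("c", "m"): 2}

    def test_direction_constraint_removes_same_direction_pairs(self):
        de_c = [_de("c_up", 2.0), _de("c_dn", -2.0)]
        de_m = [_de("m_dn", -2.0)]
        de_t = [_de("t", 2.0)]
        sites_c = [_site("c_up", "m_dn"), _site("c_dn", "m_dn")]
        loose, _ = candidate_pairs(de_c, de_m, de_t, sites_c, [])
        strict, _ = candidate_pairs(
            de_c, de_m, de_t, sites_c, [], require_opposite_direction=True
        )
        assert set(loose) == {("c_up", "m_dn"), ("c_dn", "m_dn")}
        assert set(strict) == {("c_up", "m_dn")}

    def test_published_pairings_need_the_constraint_off(self):
        """The printed control table pairs the down-regulated circ_003736
        with miR-298-5p, itself down-regulated in the study — so the
        direction constraint cannot have been enforced and defaults off."""
        row = next(
            r for r in load_control_table() if r.circ_id == "mm9_circ_003736"
        )
        assert row.direction == "down"
        assert "mmu-miR-298-5p" in row.mirna_set


class TestSharedMirnas:
    def test_disjoint_sets_empty(self):
        assert shared_mirnas({("c", "m1"): 1}, {("t", "m2"): 1}) == set()

    def test_singleton_intersection(self):
        assert shared_mirnas({("c", "m"): 1}, {("t", "m"): 1}) == {"m"}

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(50):
            cp = {(f"c{i}", f"m{rng.integers(8)}"): 1 for i in range(10)}
            tp = {(f"t{i}", f"m{rng.integers(8)}"): 1 for i in range(10)}
            expected = {m for _, m in cp} & {m for _, m in tp}
            assert shared_mirnas(cp, tp) == expected


def _expr(data: dict, samples=None) -> pd.DataFrame:
    samples = samples or [f"s{i}" for i in range(len(next(iter(data.values()))))]
    return pd.DataFrame(data, index=samples).T


class TestScoreAndAssemble:
    def _scored(self, coupling=1.0, thresholds=TripletThresholds()):
        rng = np.random.default_rng(5)
        m = rng.normal(0, 2, 6)
        c = coupling * -m + rng.normal(0, 0.05, 6) + 10
        t = coupling * -m + rng.normal(0, 0.05, 6) + 10
        ec = _expr({"c": np.exp2(c)})
        em = _expr({"m": np.exp2(m + 10)})
        et = _expr({"t": np.exp2(t)})
        return score_triplets(
            {("c", "m"): 2}, {("t", "m"): 1}, ec, em, et, thresholds
        )

    def test_strongly_coupled_triplet_is_valid(self):
        (trip,) = self._scored()
        assert trip.cor_xy > 0.9
        assert trip.cor_cm < -0.9
        assert trip.s_value > 0.3
        assert trip.valid
        assert (trip.n_sites_circ, trip.n_sites_mrna) == (2, 1)

    def test_raising_thresholds_never_adds_triplets(self):
        loose = {
            (t.circ_id, t.mir_id, t.mrna_id)
            for t in self._scored(thresholds=TripletThresholds(0.5, 0.1))
            if t.valid
        }
        tight = {
            (t.circ_id, t.mir_id, t.mrna_id)
            for t in self._scored(thresholds=TripletThresholds(0.9, 0.5))
            if t.valid
        }
        assert tight <= loose

    def test_zero_variance_member_dropped_not_fatal(self):
        ec = _expr({"c": [1.0] * 6})
        em = _expr({"m": [1, 2, 3, 4, 5, 6.0]})
        et = _expr({"t": [2, 1, 4, 3, 6, 5.0]})
        assert score_triplets({("c", "m"): 1}, {("t", "m"): 1}, ec, em, et) == []

    def test_assemble_empty(self):
        net = assemble([])
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_assemble_minimal_network(self):
        (trip,) = self._scored()
        net = assemble([trip], de_direction={"c": "up", "m": "down", "t": "up"})
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.graph.nodes["m"]["node_class"] == "miRNA"
        assert net.graph.nodes["c"]["direction"] == "up"
        types = {d["edge_type"] for _, _, d in net.graph.edges(data=True)}
        assert types == {"circRNA-miRNA", "miRNA-mRNA"}

    def test_network_is_bipartite_mirna_vs_targets(self):
        (trip,) = self._scored()
        net = assemble([trip])
        for u, v in net.graph.edges:
            classes = {net.graph.nodes[u]["node_class"], net.graph.nodes[v]["node_class"]}
            assert "miRNA" in classes and len(classes) == 2

    def test_all_assembled_triplets_satisfy_thresholds(self):
        thr = TripletThresholds()
        net = assemble(self._scored(thresholds=thr))
        for t in net.triplets:
            assert t.cor_xy >= thr.cor_min and t.s_value >= thr.s_min

    def test_mirnas_in_network_equal_shared_mirnas_of_valid_triplets(self):
        trips = self._scored()
        net = assemble(trips)
        valid_mirs = {t.mir_id for t in trips if t.valid}
        assert set(net.nodes_of_class("miRNA")) == valid_mirs


class TestFixtureNetworks:
    def test_control_network_composition(self):
        g = fixture_network(load_control_table())
        circ = [n for n, d in g.nodes(data=True) if d["node_class"] == "circRNA"]
        mir = [n for n, d in g.nodes(data=True) if d["node_class"] == "miRNA"]
        assert len(circ) == 6 and len(mir) == 6

    def test_surgery_network_composition(self):
        g = fixture_network(load_surgery_table())
        circ = [n for n, d in g.nodes(data=True) if d["node_class"] == "circRNA"]
        mir = [n for n, d in g.nodes(data=True) if d["node_class"] == "miRNA"]
        assert len(circ) == 13 and len(mir) == 8

    def test_hub_circrna_degree(self):
        g = fixture_network(load_control_table())
        assert g.degree["mm9_circ_003736"] == 4
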