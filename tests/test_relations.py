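"""Hypergeometric relations, permutation null, health flags, networks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpsets.containers import CHARACTER_SUBSCALES, SubjectSet
from snpsets.nmf import TemperamentSignature
from snpsets.relations import (
    attach_health,
    build_network,
    find_hubs,
    health_flags,
    hypergeom_relation,
    permutation_null,
    relation_screen,
    switch_features,
    trait_pipelines,
)

from conftest import make_genotypes


def _set(label, ids, feats=("f",)):
    return SubjectSet(label, list(ids), list(feats))


def _subjects(n):
    return [f"s{i:05d}" for i in range(n)]


class TestHypergeometric:
    def test_disjoint_small_sets_worked_example(self):
        # two 5-subject sets in a 20-subject cohort overlapping completely:
        # P(overlap >= 5) = 1 / C(20, 5) = 1 / 15504
        ids = _subjects(20)
        e = hypergeom_relation(_set("G_2_1", ids[:5]), _set("T_2_1", ids[:5]), 20)
        assert e.p_hyper == pytest.approx(1 / 15504, rel=1e-12)

    def test_zero_overlap_has_p_one(self):
        ids = _subjects(20)
        e = hypergeom_relation(_set("G_2_1", ids[:5]), _set("T_2_1", ids[5:10]), 20)
        assert e.k_overlap == 0
        assert e.p_hyper == 1.0

    def test_screen_applies_threshold(self):
        ids = _subjects(40)
        a = _set("G_2_1", ids[:10])
        hit = _set("T_2_1", ids[:10])
        miss = _set("T_2_2", ids[10:20])
        edges = relation_screen([a], [hit, miss], 40, p_threshold=1e-3)
        assert [(e.snp_set_label, e.temp_set_label) for e in edges] == [
            ("G_2_1", "T_2_1")
        ]


class TestPermutationNull:
    def test_extreme_dependence_hits_the_floor(self):
        ids = _subjects(100)
        a = _set("G_2_1", ids[:30])
        b = _set("T_2_1", ids[:30])
        edges = relation_screen([a], [b], 100, p_threshold=1.1)
        edges = permutation_null(edges, [a], [b], ids, n_perm=500, seed=1)
        # observed overlap can be tied by permutations only with tiny
        # probability, so the empirical p sits at its 1/(R+1) floor
        assert edges[0].p_perm == pytest.approx(1 / 501, rel=1e-6)

    def test_fewer_than_100_permutations_rejected(self):
        ids = _subjects(20)
        a, b = _set("G_2_1", ids[:5]), _set("T_2_1", ids[:5])
        with pytest.raises(ValueError, match="100 permutations"):
            permutation_null([], [a], [b], ids, n_perm=50)

    def test_permutation_p_tracks_hypergeometric_p(self):
        # graded overlaps: empirical and analytic p must agree in rank
        ids = _subjects(300)
        rng = np.random.default_rng(2)
        snp_sets, temp_sets = [], []
        for i, k in enumerate(range(12, 37, 2)):
            a_ids = list(rng.choice(ids, 60, replace=False))
            rest = [s for s in ids if s not in set(a_ids)]
            b_ids = a_ids[:k] + list(rng.choice(rest, 80 - k, replace=False))
            snp_sets.append(_set(f"G_{i + 2}_1", a_ids))
            temp_sets.append(_set(f"T_{i + 2}_1", b_ids))
        edges = [
            hypergeom_relation(a, b, 300) for a, b in zip(snp_sets, temp_sets)
        ]
        edges = permutation_null(edges, snp_sets, temp_sets, ids,
                                 n_perm=2000, seed=3)
        rho = stats.spearmanr(
            [e.p_hyper for e in edges], [e.p_perm for e in edges]
        ).statistic
        assert rho > 0.9


class TestHealthFlags:
    def _scores(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.standard_normal((n, len(CHARACTER_SUBSCALES))) + 10.0,
            columns=list(CHARACTER_SUBSCALES),
            index=_subjects(n),
        )

    def test_exactly_floor_n_over_10_flags(self):
        for n in (10, 23, 105):
            flags = health_flags(self._scores(n, seed=n))
            assert flags.well_being.sum() == n // 10
            assert flags.ill_being.sum() == n // 10

    def test_flags_invariant_under_increasing_affine_transform(self):
        scores = self._scores(50, seed=4)
        flags = health_flags(scores)
        flags2 = health_flags(scores * 3.0 + 5.0)
        pd.testing.assert_series_equal(flags.well_being, flags2.well_being)
        pd.testing.assert_series_equal(flags.ill_being, flags2.ill_being)

    def test_all_identical_scores_break_ties_by_subject_order(self):
        scores = pd.DataFrame(
            10.0, index=_subjects(20), columns=list(CHARACTER_SUBSCALES)
        )
        flags = health_flags(scores)
        assert list(flags.well_being[flags.well_being].index) == _subjects(2)
        assert list(flags.ill_being[flags.ill_being].index) == _subjects(2)

    def test_fewer_than_10_subjects_raise(self):
        with pytest.raises(ValueError, match="at least 10"):
            health_flags(self._scores(9))

    def test_missing_character_columns_raise(self):
        scores = self._scores(20).drop(columns=[c for c in CHARACTER_SUBSCALES
                                                if c.startswith("st")])
        with pytest.raises(ValueError, match="subscales"):
            health_flags(scores)

    def test_attach_health_reports_joint_fractions(self):
        scores = self._scores(20, seed=5)
        flags = health_flags(scores)
        ids = list(scores.index)
        a, b = _set("G_2_1", ids[:10]), _set("T_2_1", ids[5:15])
        edges = [hypergeom_relation(a, b, 20)]
        attach_health(edges, [a], [b], flags)
        shared = ids[5:10]
        assert edges[0].wb_joint == pytest.approx(
            flags.well_being.loc[shared].mean()
        )
        assert edges[0].ib_joint == pytest.approx(
            flags.ill_being.loc[shared].mean()
        )


class TestNetwork:
    def _star(self):
        # hub shares 20 SNPs with each of 6 pairwise-disjoint spokes
        hub_feats = [f"f{i}" for i in range(120)]
        sets = [SubjectSet("G_8_1", ["h0"], hub_feats)]
        for i in range(6):
            feats = hub_feats[20 * i: 20 * (i + 1)] + [f"x{i}_{j}" for j in range(10)]
            sets.append(SubjectSet(f"G_8_{i + 2}", [f"p{i}"], feats))
        return sets

    def test_star_fixture_has_a_unique_hub(self):
        net = build_network(self._star(), n_subjects=1000, n_snps=1000)
        assert net.degree("G_8_1") == 6
        assert find_hubs(net) == ["G_8_1"]
        assert all(d["kind"] == "snps" for _, _, d in net.edges(data=True))

    def test_disjoint_sets_produce_no_edges(self):
        sets = [
            SubjectSet(f"G_3_{i + 1}", [f"s{i}"], [f"f{i}"]) for i in range(3)
        ]
        net = build_network(sets, n_subjects=100, n_snps=100)
        assert net.number_of_edges() == 0
        assert find_hubs(net) == []

    def test_two_communities_stay_separate_components(self):
        import networkx as nx
        ids = _subjects(200)
        feats = [f"f{i}" for i in range(200)]
        sets = [
            SubjectSet("G_4_1", ids[:40], feats[:30]),
            SubjectSet("G_4_2", ids[10:50], feats[5:35]),
            SubjectSet("G_4_3", ids[100:140], feats[100:130]),
            SubjectSet("G_4_4", ids[110:150], feats[105:135]),
        ]
        net = build_network(sets, n_subjects=200, n_snps=200)
        comps = list(nx.connected_components(net))
        assert len(comps) == 2
        assert {"G_4_1", "G_4_2"} in comps and {"G_4_3", "G_4_4"} in comps

    def test_edge_set_invariant_under_catalog_order(self):
        sets = self._star()
        net1 = build_network(sets, 1000, 1000)
        net2 = build_network(sets[::-1], 1000, 1000)
        assert set(map(frozenset, net1.edges())) == set(map(frozenset, net2.edges()))


class TestTraitPipelinesAndSwitches:
    def _edge(self, t_label):
        return hypergeom_relation(
            _set("G_2_1", _subjects(5)), _set(t_label, _subjects(5)), 20
        )

    def test_single_profile_pipeline_is_direct(self):
        sig = TemperamentSignature(
            flags={"ns1": "high", "ns2": "high", "ns3": "high", "ns4": "high"},
            profile="Antisocial",
        )
        pipes = trait_pipelines([self._edge("T_3_1")], {"T_3_1": sig})
        assert pipes["novelty_seeking_high"]["composite"] is False
        assert len(pipes["novelty_seeking_high"]["relations"]) == 1

    def test_two_profiles_make_a_composite_pipeline(self):
        sig_a = TemperamentSignature(flags={"ha1": "high", "ha2": "high"},
                                     profile="Sensitive")
        sig_b = TemperamentSignature(flags={"ha1": "high", "ha3": "high"},
                                     profile="Reliable")
        pipes = trait_pipelines(
            [self._edge("T_3_1"), self._edge("T_3_2")],
            {"T_3_1": sig_a, "T_3_2": sig_b},
        )
        assert pipes["harm_avoidance_high"]["composite"] is True

    def test_edges_without_signature_are_skipped(self):
        assert trait_pipelines([self._edge("T_3_1")], {}) == {}

    def test_switch_feature_detected_and_noise_ignored(self):
        rng = np.random.default_rng(6)
        n = 60
        vals = rng.integers(0, 3, size=(n, 3)).astype(np.int8)
        # snp0: half the members carry the modal genotype 2 and score higher
        vals[:20, 0] = 2
        vals[20:40, 0] = 0
        vals[:, 2] = 1  # constant within members: not a switch candidate
        g = make_genotypes(vals)
        members = g.subject_ids[:40]
        well = pd.Series(rng.standard_normal(n), index=g.subject_ids)
        well.iloc[:20] += 3.0
        out = switch_features(
            SubjectSet("G_2_1", members, g.snp_ids), g, well, p_threshold=0.01
        )
        found = {o["snp_id"] for o in out}
        assert "snp000000" in found
        assert "snp000002" not in found
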