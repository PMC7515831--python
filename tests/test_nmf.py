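"""NMF machinery: encodings, factorization, set extraction, rank selection."""

import numpy as np
import pandas as pd
import pytest

from snpsets.containers import MISSING, TEMPERAMENT_SUBSCALES
from snpsets.nmf import (
    ConsensusResult,
    Factorization,
    cophenetic_correlation,
    encode_folded,
    encode_genotypes_onehot,
    extract_sets,
    factorize,
    select_superset_rank,
    sweep_ranks,
    _threshold_members,
)
from snpsets.simulate import CohortConfig, BlockSpec, simulate_cohort

from conftest import make_genotypes


class TestEncodings:
    def test_onehot_rows_stay_on_the_simplex(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
        vals[rng.random((30, 10)) < 0.15] = MISSING
        g = make_genotypes(vals)
        x, feats, groups = encode_genotypes_onehot(g)
        assert x.shape == (30, 30)
        assert len(feats) == len(groups) == 30
        # each SNP's three state columns sum to 1, missing soft-imputed
        sums = x.reshape(30, 10, 3).sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
        assert feats[0] == "snp000000|0" and groups[0] == "snp000000"

    def test_folded_encoding_reconstructs_zscores(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
        x, feats, groups = encode_folded(df)
        assert (x >= 0).all()
        z = ((df - df.mean()) / df.std()).to_numpy()
        np.testing.assert_allclose(x[:, 0::2] - x[:, 1::2], z, atol=1e-5)
        assert feats[:2] == ["a|high", "a|low"]
        assert groups[:2] == ["a", "a"]

    def test_folded_encoding_handles_constant_columns(self):
        df = pd.DataFrame({"a": np.ones(20), "b": np.arange(20.0)})
        x, _, _ = encode_folded(df)
        assert np.isfinite(x).all()
        assert np.all(x[:, 0:2] == 0.0)  # constant column folds to zero


class TestFactorization:
    def test_objective_is_monotone_nonincreasing(self):
        rng = np.random.default_rng(2)
        x = rng.random((40, 25))
        fac = factorize(x, 3, n_restarts=1, seed=3, max_iter=200, tol=0.0)
        obj = np.array(fac.objective)
        assert np.all(np.diff(obj) <= 1e-6 * np.maximum(obj[:-1], 1.0))

    def test_rank_one_matrix_is_recovered_nearly_exactly(self):
        rng = np.random.default_rng(4)
        x = np.outer(rng.random(30), rng.random(20))
        fac = factorize(x, 1, n_restarts=3, seed=5, max_iter=2000, tol=0.0)
        rel = np.linalg.norm(x - fac.W @ fac.H) / np.linalg.norm(x)
        assert rel < 1e-6

    def test_block_diagonal_matrix_separates_subjects(self):
        rng = np.random.default_rng(6)
        a = rng.random((15, 10)) + 0.5
        b = rng.random((20, 12)) + 0.5
        x = np.zeros((35, 22))
        x[:15, :10] = a
        x[15:, 10:] = b
        fac = factorize(x, 2, n_restarts=5, seed=7)
        labels = fac.W.argmax(axis=1)
        assert len(set(labels[:15])) == 1
        assert len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]

    def test_same_seed_is_bitwise_deterministic(self):
        rng = np.random.default_rng(8)
        x = rng.random((25, 15))
        f1 = factorize(x, 3, n_restarts=4, seed=9)
        f2 = factorize(x, 3, n_restarts=4, seed=9)
        np.testing.assert_array_equal(f1.W, f2.W)
        np.testing.assert_array_equal(f1.H, f2.H)

    def test_negative_input_and_bad_rank_are_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            factorize(np.array([[-1.0, 1.0]]), 1)
        with pytest.raises(ValueError, match="rank"):
            factorize(np.ones((4, 4)), 5)


class TestMembershipThreshold:
    def test_2means_splits_a_clear_spike(self):
        v = np.array([0.01] * 50 + [1.0] * 10)
        members = _threshold_members(v, rule="2means")
        np.testing.assert_array_equal(members, np.arange(50, 60))

    def test_constant_loadings_give_no_members(self):
        assert _threshold_members(np.ones(20)).size == 0

    def test_mean_sd_rule_matches_its_definition(self):
        rng = np.random.default_rng(10)
        v = rng.random(100)
        members = _threshold_members(v, rule="mean_sd", n_sd=1.0)
        np.testing.assert_array_equal(members, np.where(v > v.mean() + v.std())[0])


class TestExtraction:
    def _manual_factorization(self, n=30, m=8, k=2):
        w = np.full((n, k), 0.01)
        w[:10, 0] = 1.0
        w[10:22, 1] = 1.0
        h = np.full((k, m), 0.01)
        h[0, :3] = 1.0
        h[1, 3:6] = 1.0
        return Factorization(w, h, [1.0], True)

    def test_extraction_is_equivariant_under_joint_permutation(self):
        fac = self._manual_factorization()
        rng = np.random.default_rng(11)
        n, m = fac.W.shape[0], fac.H.shape[1]
        sids = [f"s{i:02d}" for i in range(n)]
        fids = [f"f{i}" for i in range(m)]
        raw = rng.standard_normal((n, m))
        base = extract_sets(fac, 2, sids, fids, prefix="T", raw_values=raw)

        ps = rng.permutation(n)
        pf = rng.permutation(m)
        fac_p = Factorization(fac.W[ps], fac.H[:, pf], [1.0], True)
        perm = extract_sets(
            fac_p, 2, [sids[i] for i in ps], [fids[j] for j in pf], prefix="T",
            raw_values=raw[np.ix_(ps, pf)],
        )
        key = lambda s: (sorted(s.subject_ids), sorted(s.feature_ids))
        assert sorted(map(key, base)) == sorted(map(key, perm))

    def test_labels_follow_prefix_rank_order_convention(self):
        fac = self._manual_factorization()
        sets = extract_sets(fac, 2, [f"s{i}" for i in range(30)],
                            [f"f{i}" for i in range(8)], prefix="T")
        assert [s.label for s in sets] == ["T_2_1", "T_2_2"]

    def test_perfect_planted_block_has_cohesion_one(self):
        # integer raw values: cohesion = modal-genotype agreement inside the set
        raw = np.random.default_rng(12).integers(0, 3, size=(30, 8)).astype(np.int8)
        raw[:10, :3] = 2
        fac = self._manual_factorization()
        sets = extract_sets(
            fac, 2, [f"s{i}" for i in range(30)], [f"f{i}" for i in range(8)],
            prefix="G", raw_values=raw,
        )
        block_set = next(s for s in sets if set(s.feature_ids) == {"f0", "f1", "f2"})
        assert block_set.cohesion == 1.0
        assert block_set.label == "G_2_1"  # highest cohesion first
        assert all(block_set.feature_values[f] == 2.0 for f in block_set.feature_ids)


class TestSweepAndRankSelection:
    def test_perfect_consensus_has_cophenetic_one(self):
        labels = np.array([0] * 10 + [1] * 10)
        consensus = (labels[:, None] == labels[None, :]).astype(float)
        assert cophenetic_correlation(consensus) == pytest.approx(1.0, abs=1e-9)

    def test_catalog_is_deduplicated(self, small_cohort):
        g = small_cohort.genotypes
        x, feats, groups = encode_genotypes_onehot(g)
        catalog, consensus = sweep_ranks(
            x, list(g.subject_ids), feats, (2, 4), n_restarts=3, seed=13,
            prefix="G", raw_values=g.values, feature_groups=groups,
        )
        from snpsets.containers import feature_jaccard, subject_jaccard
        for i, a in enumerate(catalog):
            for b in catalog[i + 1:]:
                assert not (subject_jaccard(a, b) > 0.95 and feature_jaccard(a, b) > 0.95)
        assert len(consensus) == 3  # one per rank

    def test_planted_block_is_recovered_from_onehot_sweep(self, small_cohort):
        from snpsets.benchmarks import best_block_match
        g = small_cohort.genotypes
        x, feats, groups = encode_genotypes_onehot(g)
        catalog, _ = sweep_ranks(
            x, list(g.subject_ids), feats, (2, 4), n_restarts=5, seed=14,
            prefix="G", raw_values=g.values, feature_groups=groups,
        )
        block = small_cohort.truth.blocks[0]
        sj, fj = best_block_match(block.subject_ids, block.snp_ids, catalog)
        assert sj >= 0.8 and fj >= 0.8

    def test_exact_tie_across_ranks_selects_smallest_k(self):
        consensus_matrix = np.eye(6)
        results = [ConsensusResult(k, consensus_matrix, 0.9) for k in (2, 3, 4)]
        k, _ = select_superset_rank(results, [], None)
        assert k == 2

    def test_minimize_direction_picks_least_stable_rank(self):
        results = [
            ConsensusResult(2, np.eye(4), 0.99),
            ConsensusResult(3, np.eye(4), 0.80),
            ConsensusResult(4, np.eye(4), 0.95),
        ]
        k, _ = select_superset_rank(results, [], None, direction="minimize")
        assert k == 3

    def test_maximize_takes_finest_rank_within_tolerance(self):
        results = [
            ConsensusResult(2, np.eye(4), 0.999),
            ConsensusResult(3, np.eye(4), 0.998),  # within 0.003 of best
            ConsensusResult(4, np.eye(4), 0.90),
        ]
        k, _ = select_superset_rank(results, [], None)
        assert k == 3

    def test_single_rank_raises(self):
        with pytest.raises(ValueError, match="two candidate ranks"):
            select_superset_rank([ConsensusResult(2, np.eye(3), 1.0)], [], None)

    def test_superset_assignment_groups_by_profile(self):
        # three temperament clusters grouped back into three super-sets
        cohort = simulate_cohort(
            CohortConfig(n_subjects=200, n_snps=10, blocks=[]), seed=15
        )
        phen = cohort.phenotypes[list(TEMPERAMENT_SUBSCALES)]
        x, feats, groups = encode_folded(phen)
        catalog, consensus = sweep_ranks(
            x, list(phen.index), feats, (2, 5), n_restarts=10, seed=15,
            prefix="T", raw_values=phen.to_numpy(), feature_groups=groups,
        )
        k, assignment = select_superset_rank(consensus, catalog, phen)
        assert set(assignment) == {s.label for s in catalog}
        assert 1 <= len(set(assignment.values())) <= max(k, len(catalog))
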