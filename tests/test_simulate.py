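"""Synthetic cohort generator: determinism, calibration, bookkeeping, truth."""

import numpy as np
import pandas as pd
import pytest

from snpsets.containers import (
    CHARACTER_SUBSCALES,
    MISSING,
    SubjectSet,
    TEMPERAMENT_SUBSCALES,
)
from snpsets.nmf import signature
from snpsets.simulate import (
    BlockSpec,
    CohortConfig,
    EnvSpec,
    PhenotypeModel,
    PlantedBlock,
    SyntheticTruth,
    character_template,
    generate_genotypes,
    generate_phenotypes,
    profile_template,
    simulate_cohort,
    write_cohort,
)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self, small_cohort):
        config = CohortConfig(
            n_subjects=150, n_snps=120, missing_rate=0.02, fst=0.01, fidelity=0.9,
            blocks=[BlockSpec(30, 15, cluster="Antisocial",
                              effect=("novelty_seeking", 0.8))],
            h2_target=0.3,
            env=[EnvSpec("stress", cluster="Antisocial", target_r=0.25)],
        )
        again = simulate_cohort(config, seed=20240)
        np.testing.assert_array_equal(again.genotypes.values, small_cohort.genotypes.values)
        pd.testing.assert_frame_equal(again.phenotypes, small_cohort.phenotypes)
        pd.testing.assert_frame_equal(again.environment, small_cohort.environment)
        assert again.truth.to_json() == small_cohort.truth.to_json()

    def test_written_cohort_is_byte_identical(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path / "a")
        write_cohort(small_cohort, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files_a == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        config = CohortConfig(n_subjects=50, n_snps=40, blocks=[])
        a = simulate_cohort(config, seed=1)
        b = simulate_cohort(config, seed=2)
        assert not np.array_equal(a.genotypes.values, b.genotypes.values)


class TestGenotypeGeneration:
    def test_zero_missing_rate_means_no_missing_calls(self):
        g = simulate_cohort(
            CohortConfig(n_subjects=100, n_snps=80, missing_rate=0.0, blocks=[]),
            seed=3,
        ).genotypes
        assert not (g.values == MISSING).any()

    def test_missing_rate_is_respected(self):
        g = simulate_cohort(
            CohortConfig(n_subjects=400, n_snps=200, missing_rate=0.05, blocks=[]),
            seed=4,
        ).genotypes
        frac = (g.values == MISSING).mean()
        assert abs(frac - 0.05) < 0.005

    def test_background_maf_matches_configuration(self):
        # pinned MAF, no structure, no drift: every SNP within 4 binomial SDs
        g, _ = generate_genotypes(
            500, 300, [], missing_rate=0.0, fst=0.0, maf_range=(0.3, 0.3), seed=11
        )
        freq = g.values.mean(axis=0) / 2.0
        sd = np.sqrt(0.3 * 0.7 / (2 * 500))
        assert np.abs(freq - 0.3).max() < 4 * sd

    def test_full_fidelity_block_carries_its_pattern_exactly(self):
        block = PlantedBlock(
            "block0",
            [f"s{i:05d}" for i in range(10)],
            [f"snp{j:06d}" for j in range(6)],
            [2, 0, 1, 2, 2, 0],
        )
        g, _ = generate_genotypes(40, 20, [block], missing_rate=0.0,
                                  fidelity=1.0, seed=12)
        sub = g.select_snp_ids(block.snp_ids).take_subjects(range(10))
        np.testing.assert_array_equal(
            sub.values, np.tile(block.allele_pattern, (10, 1))
        )

    def test_overlapping_blocks_earlier_wins(self):
        subjects = [f"s{i:05d}" for i in range(5)]
        snps = [f"snp{j:06d}" for j in range(4)]
        first = PlantedBlock("block0", subjects, snps, [2, 2, 2, 2])
        second = PlantedBlock("block1", subjects, snps, [0, 0, 0, 0])
        g, _ = generate_genotypes(10, 10, [first, second], missing_rate=0.0,
                                  fidelity=1.0, seed=13)
        sub = g.select_snp_ids(snps).take_subjects(range(5))
        assert (sub.values == 2).all()

    def test_block_members_outside_cohort_raise(self):
        bad = PlantedBlock("block0", ["s99999"], ["snp000000"], [2])
        with pytest.raises(ValueError, match="outside"):
            generate_genotypes(10, 10, [bad], seed=0)


class TestPhenotypes:
    def _truth(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        sids = [f"s{i:05d}" for i in range(n)]
        clusters = {s: ("Reliable", "Antisocial", "Sensitive")[i % 3]
                    for i, s in enumerate(sids)}
        return SyntheticTruth(
            seed=seed, blocks=[], cluster_assignments=clusters,
            sex={s: int(rng.integers(0, 2)) for s in sids},
            subpopulation={s: 0 for s in sids},
        )

    def _model(self, **kw):
        profiles = ("Reliable", "Antisocial", "Sensitive")
        return PhenotypeModel(
            templates={c: profile_template(c) for c in profiles},
            character_templates={c: character_template(c) for c in profiles},
            **kw,
        )

    def test_zero_noise_reproduces_templates_exactly(self):
        truth = self._truth()
        phen = generate_phenotypes(truth, self._model(noise_sd=0.0), seed=1)
        for s, c in truth.cluster_assignments.items():
            np.testing.assert_allclose(
                phen.loc[s, list(TEMPERAMENT_SUBSCALES)].to_numpy(dtype=float),
                profile_template(c),
            )
            np.testing.assert_allclose(
                phen.loc[s, list(CHARACTER_SUBSCALES)].to_numpy(dtype=float),
                10.0 + character_template(c),
            )

    def test_h2_bookkeeping_hits_target_analytically(self):
        cohort = simulate_cohort(
            CohortConfig(
                n_subjects=400, n_snps=100,
                blocks=[BlockSpec(40, 20, effect=("novelty_seeking", 1.0),
                                  effect_mode="additive")],
                h2_target=0.5,
            ),
            seed=21,
        )
        book = cohort.truth.h2_bookkeeping
        assert book["genetic_fraction"] == pytest.approx(0.5, abs=1e-9)
        assert book["effect_scale"] > 0

    def test_infeasible_h2_target_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_cohort(
                CohortConfig(n_subjects=50, n_snps=40, blocks=[], h2_target=0.5),
                seed=22,
            )

    def test_h2_target_zero_removes_genetic_effects(self):
        cohort = simulate_cohort(
            CohortConfig(
                n_subjects=100, n_snps=60,
                blocks=[BlockSpec(20, 10, effect=("novelty_seeking", 1.0))],
                h2_target=0.0,
            ),
            seed=23,
        )
        assert cohort.truth.h2_bookkeeping["genetic_fraction"] == 0.0
        assert cohort.truth.effect_map["block0"][1] == 0.0


class TestEnvironment:
    def test_continuous_target_correlation_is_realized(self):
        cohort = simulate_cohort(
            CohortConfig(
                n_subjects=2000, n_snps=10, blocks=[],
                env=[EnvSpec("stress", cluster="Antisocial", target_r=0.3)],
            ),
            seed=31,
        )
        ind = np.array(
            [cohort.truth.cluster_assignments[s] == "Antisocial"
             for s in cohort.environment.index], dtype=float,
        )
        r = np.corrcoef(cohort.environment["stress"], ind)[0, 1]
        assert abs(r - 0.3) < 0.05

    def test_zero_target_gives_near_zero_correlation(self):
        cohort = simulate_cohort(
            CohortConfig(
                n_subjects=2000, n_snps=10, blocks=[],
                env=[EnvSpec("noise_var", cluster="Antisocial", target_r=0.0)],
            ),
            seed=32,
        )
        ind = np.array(
            [cohort.truth.cluster_assignments[s] == "Antisocial"
             for s in cohort.environment.index], dtype=float,
        )
        assert abs(np.corrcoef(cohort.environment["noise_var"], ind)[0, 1]) < 0.08

    def test_binary_negative_target_has_negative_sign(self):
        cohort = simulate_cohort(
            CohortConfig(
                n_subjects=2000, n_snps=10, blocks=[],
                env=[EnvSpec("protective", cluster="Sensitive", target_r=-0.3,
                             binary=True, prevalence=0.4)],
            ),
            seed=33,
        )
        ind = np.array(
            [cohort.truth.cluster_assignments[s] == "Sensitive"
             for s in cohort.environment.index], dtype=float,
        )
        col = cohort.environment["protective"]
        assert set(np.unique(col)) <= {0.0, 1.0}
        assert np.corrcoef(col, ind)[0, 1] < -0.2

    def test_infeasible_binary_target_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_cohort(
                CohortConfig(
                    n_subjects=300, n_snps=10, blocks=[],
                    env=[EnvSpec("rare", cluster="Sensitive", target_r=0.9,
                                 binary=True, prevalence=0.02)],
                ),
                seed=34,
            )

    def test_out_of_range_target_rejected_at_spec_time(self):
        with pytest.raises(ValueError, match="correlation target"):
            EnvSpec("bad", target_r=1.0)


class TestTruthRoundtrip:
    def test_json_roundtrip_is_lossless(self, small_cohort):
        text = small_cohort.truth.to_json()
        back = SyntheticTruth.from_json(text)
        assert back.to_json() == text
        assert back.blocks[0].snp_ids == small_cohort.truth.blocks[0].snp_ids


class TestSignatures:
    def test_whole_cohort_set_is_unmarked_everywhere(self, small_cohort):
        phen = small_cohort.phenotypes[list(TEMPERAMENT_SUBSCALES)]
        whole = SubjectSet("T_2_1", list(phen.index), ["x"])
        sig = signature(whole, phen)
        assert all(v == "unmarked" for v in sig.flags.values())

    def test_sensitive_cluster_signature_matches_published_profile(self):
        # Sensitive = high Harm Avoidance, high Novelty Seeking, high Reward
        # Dependence (low Persistence)
        cohort = simulate_cohort(
            CohortConfig(n_subjects=300, n_snps=10, blocks=[]), seed=41
        )
        phen = cohort.phenotypes[list(TEMPERAMENT_SUBSCALES)]
        members = [s for s, c in cohort.truth.cluster_assignments.items()
                   if c == "Sensitive"]
        sig = signature(SubjectSet("T_3_1", members, ["x"]), phen)
        dims = sig.dimension_flags()
        assert sig.profile == "Sensitive"
        assert dims["harm_avoidance"] == 1
        assert dims["novelty_seeking"] == 1
        assert dims["reward_dependence"] == 1

    def test_negating_phenotypes_flips_high_and_low(self):
        cohort = simulate_cohort(
            CohortConfig(n_subjects=300, n_snps=10, blocks=[]), seed=42
        )
        phen = cohort.phenotypes[list(TEMPERAMENT_SUBSCALES)]
        members = [s for s, c in cohort.truth.cluster_assignments.items()
                   if c == "Antisocial"]
        sig = signature(SubjectSet("T_3_1", members, ["x"]), phen)
        neg = signature(SubjectSet("T_3_1", members, ["x"]), -phen)
        swap = {"high": "low", "low": "high", "unmarked": "unmarked"}
        assert neg.flags == {k: swap[v] for k, v in sig.flags.items()}

    def test_tiny_set_is_low_confidence(self, small_cohort):
        phen = small_cohort.phenotypes[list(TEMPERAMENT_SUBSCALES)]
        sig = signature(SubjectSet("T_2_1", list(phen.index[:2]), ["x"]), phen)
        assert sig.low_confidence
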