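"""Seeded synthetic cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be scored against a known truth:

* overlapping subject x SNP biclusters ("planted blocks") in which member
  subjects share an allele pattern at member SNPs with configurable fidelity;
* two Balding-Nichols subpopulations at configurable Fst, giving the ancestry
  PCs real structure to remove;
* subject clusters with distinct temperament-subscale profiles (default: the
  Reliable / Antisocial / Sensitive templates), plus character subscales that
  feed the well-/ill-being indices;
* planted block -> trait effects whose joint scale is solved analytically so
  the genetic share of the composite temperament index variance equals a
  target heritability;
* environment variables with target point-biserial correlations to cluster
  membership.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical (config, seed) pairs give
byte-identical cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CHARACTER_DIMENSIONS,
    CHARACTER_SUBSCALES,
    MISSING,
    TEMPERAMENT_DIMENSIONS,
    TEMPERAMENT_SUBSCALES,
    CovariateTable,
    GenotypeMatrix,
)
from .plink import write_plink

logger = logging.getLogger(__name__)

ALL_SUBSCALES = TEMPERAMENT_SUBSCALES + CHARACTER_SUBSCALES

# median-split signature templates for the three temperament profiles,
# expressed as per-dimension signs (+1 high, -1 low, 0 unmarked)
PROFILE_SIGNS: dict[str, dict[str, int]] = {
    "Reliable": {
        "novelty_seeking": -1,
        "harm_avoidance": -1,
        "reward_dependence": 1,
        "persistence": 1,
    },
    "Antisocial": {
        "novelty_seeking": 1,
        "harm_avoidance": 0,
        "reward_dependence": -1,
        "persistence": -1,
    },
    "Sensitive": {
        "novelty_seeking": 1,
        "harm_avoidance": 1,
        "reward_dependence": 1,
        "persistence": 0,
    },
}

# character-subscale signs per profile (drive the health indices: the
# Antisocial profile is planted low on Self-directedness/Cooperativeness,
# hence enriched for ill-being)
CHARACTER_SIGNS: dict[str, dict[str, float]] = {
    "Reliable": {"sd": 1.0, "co": 1.0, "st": 0.0},
    "Antisocial": {"sd": -1.0, "co": -1.0, "st": -0.5},
    "Sensitive": {"sd": -0.3, "co": 0.3, "st": 0.5},
}


def profile_template(profile: str, gap: float = 1.0) -> np.ndarray:
    """Mean temperament-subscale vector for a named profile."""
    signs = PROFILE_SIGNS[profile]
    tpl = np.zeros(len(TEMPERAMENT_SUBSCALES))
    names = list(TEMPERAMENT_SUBSCALES)
    for dim, subs in TEMPERAMENT_DIMENSIONS.items():
        for s in subs:
            tpl[names.index(s)] = signs[dim] * gap
    return tpl


def character_template(profile: str, gap: float = 1.0) -> np.ndarray:
    signs = CHARACTER_SIGNS[profile]
    return np.array([signs[name[:2]] * gap for name in CHARACTER_SUBSCALES])


# ---------------------------------------------------------------------------
# configuration / truth types
# ---------------------------------------------------------------------------


@dataclass
class PlantedBlock:
    """One planted subject x SNP bicluster with a shared allele pattern."""

    block_id: str
    subject_ids: list[str]
    snp_ids: list[str]
    allele_pattern: list[int]
    background_maf: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subject_ids or not self.snp_ids:
            raise ValueError(f"block {self.block_id}: empty member list")
        if len(self.allele_pattern) != len(self.snp_ids):
            raise ValueError(f"block {self.block_id}: pattern length mismatch")
        if any(a not in (0, 1, 2) for a in self.allele_pattern):
            raise ValueError(f"block {self.block_id}: pattern codes must be 0/1/2")
        if self.background_maf and not all(
            0.01 <= f <= 0.5 for f in self.background_maf
        ):
            raise ValueError(f"block {self.block_id}: background MAF outside [0.01,0.5]")


@dataclass
class BlockSpec:
    """Recipe for one planted block, resolved to a PlantedBlock at draw time.

    ``cluster`` biases block-subject sampling toward one phenotype cluster
    (with probability ``purity`` a member is drawn from that cluster), which
    plants a SNP-set x temperament-set relation. ``effect`` plants a genetic
    effect of block membership on one temperament dimension.
    """

    n_subjects: int
    n_snps: int
    cluster: str | None = None
    purity: float = 0.9
    effect: tuple[str, float] | None = None  # (dimension name, beta)
    #: "membership": members get +beta (plants set-level relations);
    #: "additive": beta scales the standardized dosage sum over the block's
    #: SNPs for every subject (a SNP-linear architecture, the appropriate
    #: ground truth for regression-based heritability)
    effect_mode: str = "membership"


@dataclass
class EnvSpec:
    """One environment variable tied to a phenotype cluster.

    ``target_r`` is the desired point-biserial correlation with the cluster
    indicator; binary variables are Bernoulli with cluster-dependent rates
    solved to hit the target at the configured overall prevalence.
    """

    name: str
    cluster: str | None = None
    target_r: float = 0.0
    binary: bool = False
    prevalence: float = 0.3

    def __post_init__(self) -> None:
        if not -1.0 < self.target_r < 1.0:
            raise ValueError(f"env {self.name}: correlation target outside (-1, 1)")


@dataclass
class PhenotypeModel:
    """Cluster templates, noise, and genetic-effect bookkeeping.

    ``h2_target`` (when set) rescales all block effects jointly so the genetic
    share of the variance of the composite temperament index (mean of the 12
    temperament subscales) equals the target analytically; templates and noise
    are left untouched. ``noise_sd`` is on the standardized subscale scale.
    """

    templates: dict[str, np.ndarray]
    character_templates: dict[str, np.ndarray]
    noise_sd: float = 1.0
    effect_map: dict[str, tuple[str, float]] = field(default_factory=dict)
    #: block ids whose effect is additive in dosage rather than membership
    additive_blocks: frozenset[str] = frozenset()
    h2_target: float | None = None

    def __post_init__(self) -> None:
        if self.h2_target is not None and not 0.0 <= self.h2_target < 1.0:
            raise ValueError("h2_target must be in [0, 1)")


@dataclass
class CohortConfig:
    n_subjects: int = 500
    n_snps: int = 1000
    missing_rate: float = 0.02
    fst: float = 0.01
    fidelity: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    cluster_proportions: dict[str, float] = field(
        default_factory=lambda: {"Reliable": 1 / 3, "Antisocial": 1 / 3, "Sensitive": 1 / 3}
    )
    template_gap: float = 1.0
    noise_sd: float = 1.0
    blocks: list[BlockSpec] = field(default_factory=list)
    h2_target: float | None = None
    env: list[EnvSpec] = field(default_factory=list)
    sex_effect: float = 0.0  # added to reward-dependence subscales for sex == 1


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate and score a cohort."""

    seed: int
    blocks: list[PlantedBlock]
    cluster_assignments: dict[str, str]
    sex: dict[str, int]
    subpopulation: dict[str, int]
    effect_map: dict[str, tuple[str, float]] = field(default_factory=dict)
    h2_bookkeeping: dict[str, float] = field(default_factory=dict)
    env_targets: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "blocks": [
                {
                    "block_id": b.block_id,
                    "subject_ids": b.subject_ids,
                    "snp_ids": b.snp_ids,
                    "allele_pattern": b.allele_pattern,
                    "background_maf": b.background_maf,
                }
                for b in self.blocks
            ],
            "cluster_assignments": self.cluster_assignments,
            "sex": self.sex,
            "subpopulation": self.subpopulation,
            "effect_map": {k: list(v) for k, v in self.effect_map.items()},
            "h2_bookkeeping": self.h2_bookkeeping,
            "env_targets": self.env_targets,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            blocks=[PlantedBlock(**b) for b in d["blocks"]],
            cluster_assignments=d["cluster_assignments"],
            sex={k: int(v) for k, v in d["sex"].items()},
            subpopulation={k: int(v) for k, v in d["subpopulation"].items()},
            effect_map={k: (v[0], float(v[1])) for k, v in d["effect_map"].items()},
            h2_bookkeeping=d["h2_bookkeeping"],
            env_targets=d["env_targets"],
        )


# ---------------------------------------------------------------------------
# genotype generation
# ---------------------------------------------------------------------------


def _subject_ids(n: int) -> list[str]:
    return [f"s{i:05d}" for i in range(n)]


def _snp_ids(m: int) -> list[str]:
    return [f"snp{j:06d}" for j in range(m)]


def generate_genotypes(
    n_subjects: int,
    n_snps: int,
    blocks: Sequence[PlantedBlock],
    missing_rate: float = 0.02,
    fst: float = 0.01,
    fidelity: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw background Hardy-Weinberg genotypes and plant the blocks.

    Background genotypes are Binomial(2, p) per SNP per subpopulation, with
    subpopulation frequencies drawn from the Balding-Nichols beta around each
    SNP's ancestral frequency. Inside each block, member cells carry the
    block's allele pattern with probability ``fidelity``. When overlapping
    blocks disagree on a cell, the block earlier in the list wins (logged).
    Missingness is completely at random at ``missing_rate``, applied last.
    """
    if not 0.0 <= missing_rate < 0.2:
        raise ValueError("missing_rate must be in [0, 0.2)")
    rng = np.random.default_rng(seed)
    sids = _subject_ids(n_subjects)
    vids = _snp_ids(n_snps)
    sid_pos = {s: i for i, s in enumerate(sids)}
    vid_pos = {v: j for j, v in enumerate(vids)}

    for b in blocks:
        if any(s not in sid_pos for s in b.subject_ids) or any(
            v not in vid_pos for v in b.snp_ids
        ):
            raise ValueError(f"block {b.block_id}: members outside cohort bounds")

    # ancestral frequencies; block SNPs may pin their own background MAF
    p_anc = rng.uniform(*maf_range, size=n_snps)
    for b in blocks:
        if b.background_maf:
            for v, f in zip(b.snp_ids, b.background_maf):
                p_anc[vid_pos[v]] = f

    # two subpopulations, Balding-Nichols draw
    subpop = (np.arange(n_subjects) >= n_subjects // 2).astype(int)
    values = np.empty((n_subjects, n_snps), dtype=np.int8)
    for pop in (0, 1):
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            bpar = (1 - p_anc) * (1 - fst) / fst
            p_pop = np.clip(rng.beta(a, bpar), 1e-4, 1 - 1e-4)
        else:
            p_pop = p_anc
        rows = subpop == pop
        values[rows] = rng.binomial(2, p_pop, size=(rows.sum(), n_snps)).astype(np.int8)

    # plant blocks; earlier blocks take precedence on conflicting cells
    assigned = np.zeros((n_subjects, n_snps), dtype=bool)
    for b in blocks:
        rows = np.array([sid_pos[s] for s in b.subject_ids])
        cols = np.array([vid_pos[v] for v in b.snp_ids])
        pattern = np.asarray(b.allele_pattern, dtype=np.int8)
        keep = rng.random((len(rows), len(cols))) < fidelity
        cell_rows = rows[:, None].repeat(len(cols), axis=1)
        cell_cols = cols[None, :].repeat(len(rows), axis=0)
        conflict = assigned[cell_rows, cell_cols] & keep
        if conflict.any():
            logger.info(
                "block %s: %d cells already set by an earlier block; keeping the "
                "earlier pattern", b.block_id, int(conflict.sum()),
            )
            keep = keep & ~assigned[cell_rows, cell_cols]
        target = np.broadcast_to(pattern, (len(rows), len(cols)))
        sub = values[np.ix_(rows, cols)]
        sub[keep] = target[keep]
        values[np.ix_(rows, cols)] = sub
        assigned[cell_rows[keep], cell_cols[keep]] = True

    if missing_rate > 0:
        mask = rng.random((n_subjects, n_snps)) < missing_rate
        values[mask] = MISSING

    sex = rng.integers(0, 2, size=n_subjects)
    snp_meta = pd.DataFrame(
        {
            "snp_id": vids,
            "chrom": 1 + (np.arange(n_snps) % 22),
            "pos": np.arange(1, n_snps + 1) * 1000,
            "a1": "A",
            "a2": "B",
        }
    )
    g = GenotypeMatrix(values, snp_meta, sids)
    truth = SyntheticTruth(
        seed=seed,
        blocks=list(blocks),
        cluster_assignments={},
        sex={s: int(x) for s, x in zip(sids, sex)},
        subpopulation={s: int(x) for s, x in zip(sids, subpop)},
    )
    return g, truth


# ---------------------------------------------------------------------------
# phenotype generation
# ---------------------------------------------------------------------------


def assign_clusters(
    subject_ids: Sequence[str], proportions: dict[str, float], seed: int
) -> dict[str, str]:
    """Deterministic proportional assignment, shuffled by seed."""
    rng = np.random.default_rng(seed)
    names = list(proportions)
    weights = np.array([proportions[c] for c in names], dtype=float)
    weights = weights / weights.sum()
    n = len(subject_ids)
    counts = np.floor(weights * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(weights * n - counts))] += 1
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    return {s: str(c) for s, c in zip(subject_ids, labels)}


def _genetic_component(
    subject_ids: Sequence[str],
    blocks: Sequence[PlantedBlock],
    effect_map: dict[str, tuple[str, float]],
    additive_blocks: frozenset[str] = frozenset(),
    genotypes: GenotypeMatrix | None = None,
) -> np.ndarray:
    """Per-subject genetic contribution to each subscale (unit scale).

    Membership-mode blocks add beta for member subjects; additive-mode blocks
    add beta times the standardized dosage sum over the block's SNPs for every
    subject. Effects can target temperament or character dimensions (the
    latter plant genetic structure in the health indices).
    """
    n = len(subject_ids)
    pos = {s: i for i, s in enumerate(subject_ids)}
    names = list(ALL_SUBSCALES)
    dims = {**TEMPERAMENT_DIMENSIONS, **CHARACTER_DIMENSIONS}
    gmat = np.zeros((n, len(names)))
    for b in blocks:
        if b.block_id not in effect_map:
            continue
        dim, beta = effect_map[b.block_id]
        subs = dims[dim]
        if b.block_id in additive_blocks:
            if genotypes is None:
                raise ValueError(
                    f"block {b.block_id}: additive effect mode needs genotypes"
                )
            gsub = genotypes.select_snp_ids(b.snp_ids)
            grow = {s: i for i, s in enumerate(genotypes.subject_ids)}
            score_all = gsub.imputed().sum(axis=1)
            score = np.array([score_all[grow[s]] for s in subject_ids])
            sd = score.std()
            score = (score - score.mean()) / (sd if sd > 0 else 1.0)
            for sub in subs:
                gmat[:, names.index(sub)] += beta * score
        else:
            rows = [pos[s] for s in b.subject_ids if s in pos]
            for sub in subs:
                gmat[rows, names.index(sub)] += beta
    return gmat


def generate_phenotypes(
    truth: SyntheticTruth,
    model: PhenotypeModel,
    seed: int,
    sex_effect: float = 0.0,
    genotypes: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Subject x subscale table: cluster template + genetic effects + noise.

    Returns a DataFrame indexed by subject id with the 12 temperament and 13
    character subscale columns. When ``model.h2_target`` is set, all block
    effects are rescaled jointly so that the genetic variance share of the
    composite index (mean of the temperament subscales) equals the target;
    the scale and the analytic variance decomposition are recorded in
    ``truth.h2_bookkeeping``.
    """
    subject_ids = list(truth.cluster_assignments)
    if not subject_ids:
        raise ValueError("truth has no cluster assignments")
    rng = np.random.default_rng(seed)
    n = len(subject_ids)
    n_temp = len(TEMPERAMENT_SUBSCALES)
    n_char = len(CHARACTER_SUBSCALES)

    tpl = np.zeros((n, n_temp))
    ctpl = np.zeros((n, n_char))
    for i, s in enumerate(subject_ids):
        c = truth.cluster_assignments[s]
        tpl[i] = model.templates[c]
        ctpl[i] = model.character_templates[c]

    g_unit = _genetic_component(
        subject_ids, truth.blocks, model.effect_map,
        additive_blocks=model.additive_blocks, genotypes=genotypes,
    )
    g_temp = g_unit[:, :n_temp]
    g_char = g_unit[:, n_temp:]
    # heritability bookkeeping is defined on the temperament composite
    comp_unit = g_temp.mean(axis=1)  # unit-scale genetic part of the composite
    v_g_unit = float(np.var(comp_unit))

    comp_tpl = tpl.mean(axis=1)
    v_template = float(np.var(comp_tpl))
    v_noise = model.noise_sd**2 / n_temp  # variance of the mean of iid noises
    v_nongenetic = v_template + v_noise

    if model.h2_target is None:
        scale = 1.0
    elif model.h2_target == 0.0:
        scale = 0.0
    else:
        if v_g_unit <= 0:
            raise ValueError(
                "h2_target infeasible: no block effect reaches the composite index "
                "(maximum achievable heritability is 0)"
            )
        scale = np.sqrt(
            model.h2_target / (1.0 - model.h2_target) * v_nongenetic / v_g_unit
        )

    v_g = scale**2 * v_g_unit
    denom = v_g + v_nongenetic
    truth.effect_map = {
        k: (dim, beta * scale) for k, (dim, beta) in model.effect_map.items()
    }
    truth.h2_bookkeeping = {
        "h2_target": float(model.h2_target) if model.h2_target is not None else -1.0,
        "effect_scale": float(scale),
        "genetic_var": v_g,
        "template_var": v_template,
        "noise_var": v_noise,
        "genetic_fraction": v_g / denom if denom > 0 else 0.0,
    }

    temp = tpl + scale * g_temp + rng.normal(0.0, model.noise_sd, size=(n, n_temp))
    # character scores live on a positive questionnaire-like scale so the
    # product-based well-being index is rank-meaningful
    char = 10.0 + ctpl + scale * g_char + rng.normal(0.0, model.noise_sd, size=(n, n_char))
    if sex_effect:
        sex = np.array([truth.sex[s] for s in subject_ids], dtype=float)
        names = list(TEMPERAMENT_SUBSCALES)
        for sub in TEMPERAMENT_DIMENSIONS["reward_dependence"]:
            temp[:, names.index(sub)] += sex_effect * sex

    df = pd.DataFrame(
        np.column_stack([temp, char]), index=subject_ids, columns=list(ALL_SUBSCALES)
    )
    df.index.name = "subject_id"
    return df


# ---------------------------------------------------------------------------
# environment generation
# ---------------------------------------------------------------------------


def generate_environment(
    truth: SyntheticTruth, specs: Sequence[EnvSpec], seed: int
) -> pd.DataFrame:
    """Subject x variable environment matrix with target cluster correlations."""
    subject_ids = list(truth.cluster_assignments)
    if not subject_ids:
        raise ValueError("truth has no cluster assignments")
    rng = np.random.default_rng(seed)
    n = len(subject_ids)
    cols: dict[str, np.ndarray] = {}
    for spec in specs:
        if spec.cluster is None or spec.target_r == 0.0:
            indicator = np.zeros(n)
        else:
            indicator = np.array(
                [truth.cluster_assignments[s] == spec.cluster for s in subject_ids],
                dtype=float,
            )
        r = spec.target_r
        if spec.binary:
            q = indicator.mean()
            e = spec.prevalence
            if r != 0.0 and 0 < q < 1:
                delta = r * np.sqrt(e * (1 - e) / (q * (1 - q)))
                p1 = e + (1 - q) * delta
                p0 = e - q * delta
                if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                    raise ValueError(
                        f"env {spec.name}: target r={r} with cluster "
                        f"{spec.cluster} infeasible at prevalence {e} "
                        f"(rates p1={p1:.3f}, p0={p0:.3f})"
                    )
            else:
                p1 = p0 = e
            p = np.where(indicator > 0, p1, p0)
            cols[spec.name] = (rng.random(n) < p).astype(float)
        else:
            if r != 0.0 and indicator.std() > 0:
                z = (indicator - indicator.mean()) / indicator.std()
            else:
                z = np.zeros(n)
            cols[spec.name] = r * z + np.sqrt(1 - r**2) * rng.standard_normal(n)
        truth.env_targets[spec.name] = r
    df = pd.DataFrame(cols, index=subject_ids)
    df.index.name = "subject_id"
    return df


# ---------------------------------------------------------------------------
# whole-cohort convenience
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame  # subject_id, sex, subpopulation
    environment: pd.DataFrame
    truth: SyntheticTruth


def _resolve_blocks(
    config: CohortConfig,
    clusters: dict[str, str],
    rng: np.random.Generator,
    reuse_blocks: Sequence[PlantedBlock] | None = None,
) -> tuple[list[PlantedBlock], dict[str, tuple[str, float]], frozenset[str]]:
    """Draw concrete block memberships and patterns from the block specs.

    ``reuse_blocks`` pins each block's SNP ids and allele pattern to an
    existing truth (same genetic architecture in a replication cohort);
    subject members are still drawn fresh from this cohort's clusters.
    """
    sids = np.array(list(clusters))
    vids = np.array(_snp_ids(config.n_snps))
    by_cluster = {
        c: sids[[clusters[s] == c for s in sids]] for c in config.cluster_proportions
    }
    blocks: list[PlantedBlock] = []
    effect_map: dict[str, tuple[str, float]] = {}
    additive: set[str] = set()
    available = list(range(config.n_snps))  # blocks get disjoint random SNPs
    for idx, spec in enumerate(config.blocks):
        block_id = f"block{idx}"
        if spec.cluster is not None:
            pool = by_cluster[spec.cluster]
            n_in = int(round(spec.purity * spec.n_subjects))
            n_in = min(n_in, len(pool))
            members = list(rng.choice(pool, size=n_in, replace=False))
            rest = np.setdiff1d(sids, pool, assume_unique=False)
            extra = spec.n_subjects - n_in
            if extra > 0:
                members += list(rng.choice(rest, size=extra, replace=False))
        else:
            members = list(rng.choice(sids, size=spec.n_subjects, replace=False))
        if reuse_blocks is not None:
            snps = list(reuse_blocks[idx].snp_ids)
            pattern = list(reuse_blocks[idx].allele_pattern)
        else:
            if spec.n_snps > len(available):
                raise ValueError("not enough SNPs for the requested disjoint blocks")
            chosen = sorted(
                rng.choice(len(available), size=spec.n_snps, replace=False)
            )
            snps = [vids[available[j]] for j in chosen]
            available = [a for j, a in enumerate(available) if j not in set(chosen)]
            # patterns lean toward minor-allele-rich genotypes so planted cells
            # contrast with the Hardy-Weinberg background (visible biclusters)
            pattern = list(
                rng.choice([0, 1, 2], p=[0.1, 0.3, 0.6], size=spec.n_snps)
            )
        blocks.append(
            PlantedBlock(
                block_id=block_id,
                subject_ids=sorted(map(str, members)),
                snp_ids=list(map(str, snps)),
                allele_pattern=[int(a) for a in pattern],
            )
        )
        if spec.effect is not None:
            effect_map[block_id] = (spec.effect[0], float(spec.effect[1]))
            if spec.effect_mode == "additive":
                additive.add(block_id)
    return blocks, effect_map, frozenset(additive)


def simulate_cohort(
    config: CohortConfig,
    seed: int,
    pattern_truth: SyntheticTruth | None = None,
) -> Cohort:
    """Generate a complete cohort (genotypes, phenotypes, covariates, env).

    ``pattern_truth`` replays another cohort's block SNP ids and allele
    patterns (a replication cohort sharing the genetic architecture) while
    drawing fresh subjects, genotypes, phenotypes and noise.
    """
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=5)

    sids = _subject_ids(config.n_subjects)
    clusters = assign_clusters(sids, config.cluster_proportions, int(sub_seeds[0]))
    blocks, effect_map, additive = _resolve_blocks(
        config,
        clusters,
        np.random.default_rng(int(sub_seeds[1])),
        reuse_blocks=pattern_truth.blocks if pattern_truth else None,
    )
    g, truth = generate_genotypes(
        config.n_subjects,
        config.n_snps,
        blocks,
        missing_rate=config.missing_rate,
        fst=config.fst,
        fidelity=config.fidelity,
        maf_range=config.maf_range,
        seed=int(sub_seeds[2]),
    )
    truth.cluster_assignments = clusters
    model = PhenotypeModel(
        templates={
            c: profile_template(c, config.template_gap)
            if c in PROFILE_SIGNS
            else np.zeros(len(TEMPERAMENT_SUBSCALES))
            for c in config.cluster_proportions
        },
        character_templates={
            c: character_template(c, config.template_gap)
            if c in CHARACTER_SIGNS
            else np.zeros(len(CHARACTER_SUBSCALES))
            for c in config.cluster_proportions
        },
        noise_sd=config.noise_sd,
        effect_map=effect_map,
        additive_blocks=additive,
        h2_target=config.h2_target,
    )
    phenotypes = generate_phenotypes(
        truth, model, int(sub_seeds[3]), sex_effect=config.sex_effect, genotypes=g
    )
    environment = generate_environment(truth, config.env, int(sub_seeds[4]))
    covariates = pd.DataFrame(
        {
            "subject_id": sids,
            "sex": [truth.sex[s] for s in sids],
            "subpopulation": [truth.subpopulation[s] for s in sids],
        }
    )
    return Cohort(g, phenotypes, covariates, environment, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write PLINK trio + phenotype/covariate/environment TSVs + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(cohort.genotypes, outdir / "genotypes")
    cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", float_format="%.6g")
    cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    cohort.environment.to_csv(
        outdir / "environment.tsv", sep="\t", float_format="%.6g"
    )
    (outdir / "truth.json").write_text(cohort.truth.to_json())
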