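"""Core in-memory containers shared across the pipeline.

Genotypes are held as an ``n_subjects x n_snps`` int8 matrix of minor-allele
counts in {0, 1, 2}, with :data:`MISSING` (-1) as the missing sentinel so a
missing call can never be confused with a homozygous-major genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call; outside the valid {0, 1, 2} codes
MISSING: int = -1

#: 12 TCI temperament subscales: Novelty Seeking (4), Harm Avoidance (4),
#: Reward Dependence (3), Persistence (1)
TEMPERAMENT_SUBSCALES: tuple[str, ...] = (
    "ns1", "ns2", "ns3", "ns4",
    "ha1", "ha2", "ha3", "ha4",
    "rd1", "rd2", "rd3",
    "ps1",
)

#: 13 TCI character subscales: Self-directedness (5), Cooperativeness (5),
#: Self-transcendence (3); used only for the health indices
CHARACTER_SUBSCALES: tuple[str, ...] = (
    "sd1", "sd2", "sd3", "sd4", "sd5",
    "co1", "co2", "co3", "co4", "co5",
    "st1", "st2", "st3",
)

#: the four temperament dimensions and the subscales that load on them
TEMPERAMENT_DIMENSIONS: dict[str, tuple[str, ...]] = {
    "novelty_seeking": ("ns1", "ns2", "ns3", "ns4"),
    "harm_avoidance": ("ha1", "ha2", "ha3", "ha4"),
    "reward_dependence": ("rd1", "rd2", "rd3"),
    "persistence": ("ps1",),
}

#: the three character dimensions (feed the well-/ill-being indices)
CHARACTER_DIMENSIONS: dict[str, tuple[str, ...]] = {
    "self_directedness": ("sd1", "sd2", "sd3", "sd4", "sd5"),
    "cooperativeness": ("co1", "co2", "co3", "co4", "co5"),
    "self_transcendence": ("st1", "st2", "st3"),
}


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive genotype matrix with SNP metadata.

    Parameters
    ----------
    values
        int8 array, entries in {0, 1, 2, MISSING}; rows are subjects.
    snp_meta
        One row per SNP with columns ``snp_id, chrom, pos, a1, a2``.
    subject_ids
        Unique subject labels, one per row.
    """

    values: np.ndarray
    snp_meta: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.subject_ids = [str(s) for s in self.subject_ids]
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (subjects x SNPs)")
        n, m = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match rows")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match columns")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject ids must be unique")
        if self.snp_meta["snp_id"].duplicated().any():
            raise ValueError("snp ids must be unique")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2} or MISSING")

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_meta["snp_id"].tolist()

    # -- derived per-SNP statistics -------------------------------------
    def dosages(self) -> np.ndarray:
        """float64 copy with missing entries as NaN."""
        d = self.values.astype(np.float64)
        d[self.values == MISSING] = np.nan
        return d

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency over non-missing calls, folded to <= 0.5."""
        d = self.dosages()
        with np.errstate(invalid="ignore"):
            f = np.nanmean(d, axis=0) / 2.0
        f = np.where(np.isnan(f), 0.0, f)
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return (self.values != MISSING).mean(axis=0)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries mean-imputed per SNP (for PCA/kernels only)."""
        d = self.dosages()
        mu = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        idx = np.where(np.isnan(d))
        d[idx] = mu[idx[1]]
        return d

    # -- subsetting ------------------------------------------------------
    def take_snps(self, cols: Sequence[int]) -> "GenotypeMatrix":
        cols = np.asarray(cols, dtype=int)
        return GenotypeMatrix(
            self.values[:, cols],
            self.snp_meta.iloc[cols].reset_index(drop=True),
            list(self.subject_ids),
        )

    def select_snp_ids(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in pos]
        if missing:
            raise KeyError(f"SNP ids not present: {missing[:5]}")
        return self.take_snps([pos[s] for s in snp_ids])

    def take_subjects(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=int)
        return GenotypeMatrix(
            self.values[rows],
            self.snp_meta.copy(),
            [self.subject_ids[i] for i in rows],
        )


@dataclass
class CovariateTable:
    """Per-subject covariates: sex plus the first ancestry PCs."""

    subject_ids: list[str]
    sex: np.ndarray
    ancestry_pcs: np.ndarray  # n_subjects x k, k = 3 by default

    def design(self) -> np.ndarray:
        """Covariate design matrix with a leading intercept column."""
        return np.column_stack(
            [np.ones(len(self.subject_ids)), self.sex, self.ancestry_pcs]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_ids, "sex": self.sex})
        for j in range(self.ancestry_pcs.shape[1]):
            df[f"pc{j + 1}"] = self.ancestry_pcs[:, j]
        return df


@dataclass
class SubjectSet:
    """A labeled, possibly overlapping bicluster of subjects and features.

    ``label`` follows the ``<prefix>_<k>_<i>`` convention: ``k`` is the rank of
    the factorization the set came from and ``i`` the order in which it was
    selected (descending cohesion). Prefix G for genotype sets, T for
    temperament sets, E for environment sets.
    """

    label: str
    subject_ids: list[str]
    feature_ids: list[str]
    membership_scores: dict[str, float] = field(default_factory=dict)
    cohesion: float = float("nan")
    #: per-feature summary of the set (modal genotype for SNP sets, member
    #: mean for continuous features); used by cross-cohort matching
    feature_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subject_ids or not self.feature_ids:
            raise ValueError(f"set {self.label!r} must have members on both axes")
        self.parse_label()

    def parse_label(self) -> tuple[str, int, int]:
        prefix, k, i = self.label.split("_")
        return prefix, int(k), int(i)

    @property
    def rank(self) -> int:
        return self.parse_label()[1]

    @property
    def order(self) -> int:
        return self.parse_label()[2]

    def to_dict(self) -> dict:
        return asdict(self)


def subject_jaccard(a: SubjectSet, b: SubjectSet) -> float:
    return _jaccard(a.subject_ids, b.subject_ids)


def feature_jaccard(a: SubjectSet, b: SubjectSet) -> float:
    return _jaccard(a.feature_ids, b.feature_ids)


def _jaccard(x: Sequence[str], y: Sequence[str]) -> float:
    sx, sy = set(x), set(y)
    union = sx | sy
    return len(sx & sy) / len(union) if union else 1.0
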