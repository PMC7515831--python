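"""Shared fixtures: small deterministic cohorts and genotype builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snpsets.containers import CovariateTable, GenotypeMatrix
from snpsets.simulate import BlockSpec, CohortConfig, EnvSpec, simulate_cohort


def make_genotypes(values: np.ndarray, subject_prefix: str = "s") -> GenotypeMatrix:
    """Wrap a raw {0,1,2,-1} array in a GenotypeMatrix with stock metadata."""
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(m)],
            "chrom": 1 + (np.arange(m) % 22),
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(values, meta, [f"{subject_prefix}{i:05d}" for i in range(n)])


def zero_covariates(subject_ids: list[str]) -> CovariateTable:
    """Covariate table with sex = 0 and all-zero PCs (intercept-only model)."""
    n = len(subject_ids)
    return CovariateTable(list(subject_ids), np.zeros(n), np.zeros((n, 3)))


@pytest.fixture(scope="session")
def small_cohort():
    """150-subject cohort with one planted block, an effect, and environment."""
    config = CohortConfig(
        n_subjects=150,
        n_snps=120,
        missing_rate=0.02,
        fst=0.01,
        fidelity=0.9,
        blocks=[BlockSpec(30, 15, cluster="Antisocial", effect=("novelty_seeking", 0.8))],
        h2_target=0.3,
        env=[EnvSpec("stress", cluster="Antisocial", target_r=0.25)],
    )
    return simulate_cohort(config, seed=20240)


@pytest.fixture(scope="session")
def null_genotypes():
    """200 x 60 genotypes with no planted structure and no missingness."""
    config = CohortConfig(n_subjects=200, n_snps=60, missing_rate=0.0, blocks=[])
    return simulate_cohort(config, seed=777).genotypes
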