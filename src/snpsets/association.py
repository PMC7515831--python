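"""Kernel (SKAT-style) association of SNP sets with a temperament index.

The test regresses the empirical temperament index on covariates only (linear
null model), scores the weighted additive genotypes of a SNP set against the
residuals, and evaluates the quadratic score statistic against its
mixture-of-chi-squares null distribution. Weights follow the SKAT convention
of a Beta(1, 25) density evaluated at each SNP's minor-allele frequency, which
up-weights rare variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chi2mix import mixture_sf
from .containers import (
    TEMPERAMENT_DIMENSIONS,
    TEMPERAMENT_SUBSCALES,
    CovariateTable,
    GenotypeMatrix,
    SubjectSet,
)
from .qc import single_snp_pvalues

_P_FLOOR = 1e-300


def empirical_index(phenotypes: pd.DataFrame) -> pd.Series:
    """Single comprehensive temperament measure: standardized first PC score.

    The first principal component of the standardized 12 temperament subscales,
    oriented so the index correlates positively with Persistence, then
    standardized to zero mean / unit variance.
    """
    cols = list(TEMPERAMENT_SUBSCALES)
    missing = [c for c in cols if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"temperament subscales missing from phenotypes: {missing}")
    x = phenotypes[cols].to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant temperament subscale; index undefined")
    z = (x - x.mean(axis=0)) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    score = z @ vt[0]
    ps = phenotypes[list(TEMPERAMENT_DIMENSIONS["persistence"])].mean(axis=1).to_numpy()
    if np.corrcoef(score, ps)[0, 1] < 0:
        score = -score
    score = (score - score.mean()) / score.std()
    return pd.Series(score, index=phenotypes.index, name="temperament_index")


@dataclass
class KernelSpec:
    """Weighted-linear kernel: w_j = Beta(a, b) density at MAF_j."""

    a: float = 1.0
    b: float = 25.0

    def weights(self, maf: np.ndarray) -> np.ndarray:
        maf = np.clip(np.asarray(maf, dtype=float), 1e-6, 0.5)
        w = stats.beta.pdf(maf, self.a, self.b)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("kernel weights must be positive and finite")
        return w


@dataclass
class AssociationResult:
    """One SNP set's kernel-test outcome plus per-SNP summaries."""

    set_label: str
    Q: float
    p_set: float
    p_best: float
    p_avg: float
    p_worst: float
    n_subjects: int
    n_snps: int
    testable: bool = True
    p_method: str = "imhof"
    snp_pvalues: dict[str, float] = field(default_factory=dict)


def _null_model(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """OLS of y on covariates: residuals, sigma^2, and the hat-complement basis."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid / dof)
    return resid, sigma2, beta


def skat_test(
    snp_set: SubjectSet,
    g: GenotypeMatrix,
    y: np.ndarray | pd.Series,
    cov: CovariateTable,
    spec: KernelSpec | None = None,
    compute_snp_pvalues: bool = True,
) -> AssociationResult:
    """Kernel score test of one SNP set against the temperament index.

    The statistic is ``Q = r' G W^2 G' r`` with ``r`` the null-model residuals
    and ``G`` the (mean-imputed) additive genotype columns of the set's SNPs.
    Under the null Q is a mixture of 1-df chi-squares with weights given by
    the eigenvalues of ``sigma^2 * W G' P G W`` (P the covariate-projection
    complement). Per-SNP p-values come from covariate-adjusted single-SNP
    fits with pairwise-complete subjects.
    """
    spec = spec or KernelSpec()
    y = np.asarray(y, dtype=float)
    X = cov.design()
    n = len(y)
    if n <= X.shape[1] + 2:
        raise ValueError("too few subjects for the null model")

    sub = g.select_snp_ids(snp_set.feature_ids)
    dosage = sub.imputed()
    poly = dosage.std(axis=0) > 0
    if not poly.any():
        return AssociationResult(
            set_label=snp_set.label,
            Q=0.0, p_set=float("nan"), p_best=float("nan"),
            p_avg=float("nan"), p_worst=float("nan"),
            n_subjects=len(snp_set.subject_ids), n_snps=sub.n_snps,
            testable=False, p_method="untestable",
        )
    gmat = dosage[:, poly]
    maf = sub.maf()[poly]
    w = spec.weights(maf)

    resid, sigma2, _ = _null_model(y, X)
    z = gmat * w  # n x m weighted genotypes
    score = z.T @ resid
    q_stat = float(score @ score)

    # project covariates out of the weighted genotypes for the null eigenvalues
    coef, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
    z_perp = z - X @ coef
    lam = np.linalg.eigvalsh(z_perp.T @ z_perp) * sigma2
    p_set, method = mixture_sf(q_stat, lam)

    if compute_snp_pvalues:
        snp_p = np.clip(single_snp_pvalues(sub, y, cov), _P_FLOOR, 1.0)
    else:
        snp_p = np.array([1.0])
    return AssociationResult(
        set_label=snp_set.label,
        Q=q_stat,
        p_set=p_set,
        p_best=float(snp_p.min()),
        p_avg=float(snp_p.mean()),
        p_worst=float(snp_p.max()),
        n_subjects=len(snp_set.subject_ids),
        n_snps=sub.n_snps,
        testable=True,
        p_method=method,
        snp_pvalues=dict(zip(sub.snp_ids, snp_p)) if compute_snp_pvalues else {},
    )


def inflation_check(
    p_kernel_marginal: np.ndarray, p_independent: np.ndarray
) -> dict[str, float]:
    """Agreement of the kernel machinery's marginal fits with an independent fit.

    Regresses -log10 p from one route on the other and reports R^2 and the
    F-test p-value; a high R^2 indicates the kernel machinery does not inflate
    single-SNP evidence.
    """
    x = -np.log10(np.clip(np.asarray(p_independent, float), _P_FLOOR, 1.0))
    yv = -np.log10(np.clip(np.asarray(p_kernel_marginal, float), _P_FLOOR, 1.0))
    if len(x) != len(yv) or len(x) < 3:
        raise ValueError("need >= 3 paired p-values")
    r = np.corrcoef(x, yv)[0, 1]
    r2 = float(r**2)
    dof = len(x) - 2
    if r2 >= 1.0:
        f_p = 0.0
    else:
        f_stat = r2 / (1 - r2) * dof
        f_p = float(stats.f.sf(f_stat, 1, dof))
    return {"r2": r2, "f_p": f_p, "n": len(x)}


def significance_screen(
    results: list[AssociationResult],
    threshold: float = 4e-4,
) -> pd.DataFrame:
    """Sets with p_set below the raw threshold, ascending, with multiplicity flags.

    Bonferroni and Benjamini-Hochberg flags at the same nominal level are
    reported alongside (the screen itself applies the raw threshold).
    """
    rows = [r for r in results if r.testable and np.isfinite(r.p_set)]
    if not rows:
        return pd.DataFrame(
            columns=["set_label", "Q", "p_set", "p_best", "p_avg", "p_worst",
                     "n_subjects", "n_snps", "bonferroni", "bh"]
        )
    m = len(rows)
    df = pd.DataFrame(
        {
            "set_label": [r.set_label for r in rows],
            "Q": [r.Q for r in rows],
            "p_set": [r.p_set for r in rows],
            "p_best": [r.p_best for r in rows],
            "p_avg": [r.p_avg for r in rows],
            "p_worst": [r.p_worst for r in rows],
            "n_subjects": [r.n_subjects for r in rows],
            "n_snps": [r.n_snps for r in rows],
        }
    ).sort_values("p_set", kind="stable").reset_index(drop=True)
    df["bonferroni"] = df["p_set"] < threshold / m
    ranks = np.arange(1, m + 1)
    below = df["p_set"].to_numpy() <= threshold * ranks / m
    cutoff = ranks[below].max() if below.any() else 0
    df["bh"] = ranks <= cutoff
    return df[df["p_set"] < threshold].reset_index(drop=True)
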