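"""Genotype QC, ancestry PCs, and covariate-adjusted SNP preselection.

Defaults follow PLINK-era convention: MAF >= 0.01, call rate >= 0.95,
Hardy-Weinberg exact-test p >= 1e-6, and a generously inclusive single-SNP
preselection threshold of p < 0.01 (uncorrected) against a continuous
temperament index with sex and the first three ancestry PCs as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, CovariateTable, GenotypeMatrix


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg equilibrium test (Wigginton et al. 2005).

    Returns the probability of observing a heterozygote count at least as
    extreme (in probability) as the one observed, conditional on the allele
    counts.
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # fold so "minor" really is the rarer allele
        n_minor = 2 * n - n_minor
    # heterozygote count has the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # unnormalized conditional distribution via the recurrence
    # P(h+2)/P(h) = hom_r(h) * hom_c(h) * 4 / ((h+2)(h+1)) with
    # hom_r = (n_minor - h)/2, hom_c = n - (n_minor + h)/2 evaluated at h
    log_probs = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i - 1]
        hom_r = (n_minor - h) / 2
        hom_c = n - (n_minor + h) / 2
        log_probs[i] = log_probs[i - 1] + np.log(
            4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    obs = np.searchsorted(hets, n_het)
    if obs >= len(hets) or hets[obs] != n_het:
        return 1.0  # inconsistent counts; treat as untestable
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


@dataclass
class QCReport:
    removed: pd.DataFrame  # snp_id, reason, value
    n_input: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return self.removed


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs failing MAF / call-rate / HWE thresholds; report every removal.

    A threshold of 0 disables the corresponding filter (a MAF-0 SNP is still
    removed only when ``maf_min > 0``). Raises if nothing survives.
    """
    maf = g.maf()
    call = g.call_rate()
    removed: list[tuple[str, str, float]] = []
    keep = np.ones(g.n_snps, dtype=bool)
    snp_ids = g.snp_ids

    hwe_p = np.ones(g.n_snps)
    if hwe_p_min > 0:
        for j in range(g.n_snps):
            col = g.values[:, j]
            obs = col[col != MISSING]
            hwe_p[j] = hwe_exact_p(
                int((obs == 1).sum()), int((obs == 2).sum()), int((obs == 0).sum())
            )

    for j in range(g.n_snps):
        if maf_min > 0 and maf[j] < maf_min:
            removed.append((snp_ids[j], "maf", float(maf[j])))
            keep[j] = False
        elif call_rate_min > 0 and call[j] < call_rate_min:
            removed.append((snp_ids[j], "call_rate", float(call[j])))
            keep[j] = False
        elif hwe_p_min > 0 and hwe_p[j] < hwe_p_min:
            removed.append((snp_ids[j], "hwe", float(hwe_p[j])))
            keep[j] = False

    if not keep.any():
        raise ValueError("QC removed every SNP; thresholds are too strict for this data")
    report = QCReport(
        removed=pd.DataFrame(removed, columns=["snp_id", "reason", "value"]),
        n_input=g.n_snps,
        n_retained=int(keep.sum()),
    )
    return g.take_snps(np.where(keep)[0]), report


def ancestry_pcs(g: GenotypeMatrix, sex: np.ndarray | None = None, k: int = 3) -> CovariateTable:
    """First ``k`` principal components of the standardized genotype matrix.

    Missing genotypes are mean-imputed per SNP for this computation only.
    The sign of each component is fixed so its largest-magnitude SNP loading
    is positive.
    """
    if g.n_subjects <= k:
        raise ValueError("need more subjects than components")
    x = g.imputed()
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > 1e-9 * s[0]).sum()) if s.size and s[0] > 0 else 0
    if k > rank:
        if rank == 0:  # identical subjects: PCs are all zero after centering
            scores = np.zeros((g.n_subjects, k))
            return CovariateTable(
                list(g.subject_ids),
                np.zeros(g.n_subjects) if sex is None else np.asarray(sex, float),
                scores,
            )
        raise ValueError(f"requested {k} PCs but genotype matrix has rank {rank}")
    flip = np.sign(vt[np.arange(k), np.abs(vt[:k]).argmax(axis=1)])
    scores = (u[:, :k] * s[:k]) * flip
    return CovariateTable(
        list(g.subject_ids),
        np.zeros(g.n_subjects) if sex is None else np.asarray(sex, float),
        scores,
    )


def single_snp_pvalues(
    g: GenotypeMatrix, y: np.ndarray, cov: CovariateTable
) -> np.ndarray:
    """Wald p-value of the genotype term in y ~ genotype + sex + PCs, per SNP.

    Missing genotypes are excluded pairwise (the model is refit on the
    non-missing subjects for each SNP).
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    X0 = cov.design()
    n, m = g.values.shape
    pvals = np.ones(m)
    dos = g.dosages()
    for j in range(m):
        gj = dos[:, j]
        ok = ~np.isnan(gj)
        X = np.column_stack([gj[ok], X0[ok]])
        yy = y[ok]
        if np.ptp(gj[ok]) == 0 or ok.sum() <= X.shape[1]:
            continue  # monomorphic or underdetermined: untestable, p = 1
        beta, _, rank_, _ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ beta
        dof = ok.sum() - X.shape[1]
        sigma2 = resid @ resid / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(sigma2 * xtx_inv[0, 0])
        t = beta[0] / se if se > 0 else 0.0
        pvals[j] = 2 * stats.t.sf(abs(t), dof)
    return pvals


def preselect_snps(
    g: GenotypeMatrix,
    y: np.ndarray,
    cov: CovariateTable,
    p_threshold: float = 0.01,
) -> tuple[list[str], np.ndarray]:
    """Retain SNPs with single-SNP association p below the (uncorrected) threshold."""
    pvals = single_snp_pvalues(g, y, cov)
    keep = pvals < p_threshold
    return [s for s, k in zip(g.snp_ids, keep) if k], pvals
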