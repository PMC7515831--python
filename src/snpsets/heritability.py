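"""SNP heritability via trimmed, cross-validated ridge regression, plus
environment sets and environment-mediated relations.

Heritability is reported as the out-of-sample R^2 of a multi-SNP ridge
predictor of the empirical temperament index: within each fold the model is
fit, the ``trim_fraction`` largest-residual training subjects are dropped, the
model refit, and held-out (untrimmed) subjects predicted. The ridge penalty is
chosen by inner cross-validation; multi-SNP OLS would be ill-posed when the
SNP count approaches the sample size. Adjusting for gene-environment
correlation repeats the estimate after partialling the environment columns
out of the phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.model_selection import KFold

from .containers import GenotypeMatrix, SubjectSet
from .nmf import ConsensusResult, encode_folded, sweep_ranks
from .relations import RelationEdge, hypergeom_relation, relation_screen

logger = logging.getLogger(__name__)

_ALPHAS = np.logspace(-2, 4, 13)


@dataclass
class HeritabilityEstimate:
    h2: float
    adjusted_h2: float
    se: float
    trim_fraction: float
    h2_insample: float
    clamped: bool = False


def _standardized(g: GenotypeMatrix) -> np.ndarray:
    x = g.imputed()
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _partial_out(y: np.ndarray, env: np.ndarray | None) -> np.ndarray:
    if env is None or env.size == 0:
        return y
    keep = env.std(axis=0) > 0  # zero-variance columns contribute nothing
    if not keep.any():
        return y
    X = np.column_stack([np.ones(len(y)), env[:, keep]])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta + y.mean()


def _cv_r2(
    x: np.ndarray,
    y: np.ndarray,
    trim_fraction: float,
    n_folds: int,
    seed: int,
    alpha: float | None = None,
) -> tuple[float, float]:
    """Out-of-sample R^2 with training-fold residual trimming.

    Returns (r2, alpha_used). Trimming removes the ``trim_fraction`` largest
    absolute-residual subjects from the training fold only, so the reported
    R^2 is evaluated on untrimmed held-out subjects.
    """
    n = len(y)
    preds = np.full(n, np.nan)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    alpha_used = alpha
    for train, test in kf.split(x):
        xt, yt = x[train], y[train]
        if alpha is None:
            model = RidgeCV(alphas=_ALPHAS).fit(xt, yt)
            alpha_used = float(model.alpha_)
        else:
            model = Ridge(alpha=alpha).fit(xt, yt)
        if trim_fraction > 0:
            resid = np.abs(yt - model.predict(xt))
            n_drop = int(np.floor(trim_fraction * len(yt)))
            if n_drop > 0:
                keep = np.argsort(resid, kind="stable")[: len(yt) - n_drop]
                model = Ridge(alpha=alpha_used).fit(xt[keep], yt[keep])
        preds[test] = model.predict(x[test])
    ss_res = np.sum((y - preds) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - ss_res / ss_tot, float(alpha_used)


def estimate_h2(
    g_selected: GenotypeMatrix,
    y: np.ndarray | pd.Series,
    env: np.ndarray | pd.DataFrame | None = None,
    trim_fraction: float = 0.05,
    n_boot: int = 200,
    n_folds: int = 5,
    seed: int = 0,
) -> HeritabilityEstimate:
    """Heritability of the temperament index from the selected SNPs.

    ``h2`` is the cross-validated out-of-sample R^2 (clamped to [0, 1], with
    clamping logged); ``adjusted_h2`` partials the environment columns out of
    the phenotype first (gene-environment correlation adjustment);
    ``se`` is a bootstrap standard error with the ridge penalty frozen at the
    full-sample choice; ``h2_insample`` is the in-sample trimmed R^2 for
    reference.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    y = np.asarray(y, dtype=float)
    x = _standardized(g_selected)
    env_arr = None if env is None else np.asarray(env, dtype=float)

    raw_h2, alpha = _cv_r2(x, y, trim_fraction, n_folds, seed)
    h2 = float(np.clip(raw_h2, 0.0, 1.0))
    clamped = h2 != raw_h2
    if clamped:
        logger.info("heritability estimate %.3f clamped into [0, 1]", raw_h2)

    y_adj = _partial_out(y, env_arr)
    if env_arr is None or np.allclose(y_adj, y):
        adj_h2 = h2
    else:
        adj_raw, _ = _cv_r2(x, y_adj, trim_fraction, n_folds, seed, alpha=alpha)
        adj_h2 = float(np.clip(adj_raw, 0.0, 1.0))

    # in-sample trimmed fit for reference
    model = Ridge(alpha=alpha).fit(x, y)
    resid = np.abs(y - model.predict(x))
    n_drop = int(np.floor(trim_fraction * len(y)))
    keep = np.argsort(resid, kind="stable")[: len(y) - n_drop] if n_drop else np.arange(len(y))
    model = Ridge(alpha=alpha).fit(x[keep], y[keep])
    pred = model.predict(x)
    h2_in = float(1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2))

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(y), size=len(y))
        if np.ptp(y[idx]) == 0:
            continue
        r2, _ = _cv_r2(x[idx], y[idx], trim_fraction, n_folds,
                       int(rng.integers(0, 2**31 - 1)), alpha=alpha)
        boots.append(np.clip(r2, 0.0, 1.0))
    se = float(np.std(boots)) if boots else float("nan")

    return HeritabilityEstimate(
        h2=h2, adjusted_h2=adj_h2, se=se, trim_fraction=trim_fraction,
        h2_insample=h2_in, clamped=clamped,
    )


def gxe_adjustment(
    h2_result: HeritabilityEstimate,
) -> dict[str, float]:
    """Report the environment-adjusted estimate alongside the unadjusted one."""
    return {
        "h2": h2_result.h2,
        "adjusted_h2": h2_result.adjusted_h2,
        "difference": h2_result.h2 - h2_result.adjusted_h2,
        "se": h2_result.se,
    }


def env_sets(
    env_matrix: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[list[SubjectSet], list[ConsensusResult]]:
    """Environment sets via the same NMF machinery, labeled E_k_i."""
    x, feats, groups = encode_folded(env_matrix)
    return sweep_ranks(
        x,
        subject_ids=[str(s) for s in env_matrix.index],
        feature_ids=feats,
        k_range=k_range,
        n_restarts=n_restarts,
        seed=seed,
        prefix="E",
        raw_values=env_matrix.to_numpy(dtype=float),
        feature_groups=groups,
    )


def mediated_relations(
    snp_sets: list[SubjectSet],
    temp_sets: list[SubjectSet],
    environment_sets: list[SubjectSet],
    subject_ids: list[str],
    p_threshold: float = 1e-3,
    overlap_p: float = 0.05,
    min_stratum: int = 20,
) -> list[RelationEdge]:
    """Relations that appear only within an environment-set stratum.

    For each environment set whose subjects significantly overlap a SNP set,
    the SNP-set x temperament-set relations are re-tested within the stratum;
    edges significant in the stratum but not marginally are reported with the
    mediating environment set attached. Strata smaller than ``min_stratum``
    are skipped (logged).
    """
    n_total = len(subject_ids)
    marginal = {
        (e.snp_set_label, e.temp_set_label)
        for e in relation_screen(snp_sets, temp_sets, n_total, p_threshold)
    }
    universe = set(subject_ids)
    out: list[RelationEdge] = []
    for env in environment_sets:
        stratum = sorted(set(env.subject_ids) & universe)
        if len(stratum) < min_stratum:
            logger.info("env set %s stratum of %d subjects skipped", env.label, len(stratum))
            continue
        stratum_set = set(stratum)
        n_env = len(stratum)
        for a in snp_sets:
            if hypergeom_relation(a, env, n_total).p_hyper >= overlap_p:
                continue
            a_in = sorted(set(a.subject_ids) & stratum_set)
            if not a_in:
                continue
            a_s = SubjectSet(a.label, a_in, a.feature_ids)
            for b in temp_sets:
                b_in = sorted(set(b.subject_ids) & stratum_set)
                if not b_in:
                    continue
                b_s = SubjectSet(b.label, b_in, b.feature_ids)
                e = hypergeom_relation(a_s, b_s, n_env)
                if e.p_hyper < p_threshold and (a.label, b.label) not in marginal:
                    e.env_label = env.label
                    out.append(e)
    return out
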