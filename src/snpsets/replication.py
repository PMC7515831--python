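"""Cross-cohort set replication (Pareto multi-objective matching) and
genotype -> phenotype classification.

A source set replicates in a target catalog when some target set is
non-dominated on the two matching objectives — hypergeometric significance of
shared SNP ids and cosine similarity of the sets' allele-pattern profiles —
and passes both configured floors. Classification predicts phenotype
super-set or health-flag membership from the subjects' SNP-set membership
indicators with an L2-regularized logistic model (optionally label-spreading
semi-supervised when some labels are missing), scored by stratified
cross-validated AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.semi_supervised import LabelSpreading

from .containers import SubjectSet


# ---------------------------------------------------------------------------
# Pareto set matching
# ---------------------------------------------------------------------------


@dataclass
class SetMatch:
    source_label: str
    target_label: str
    snp_identity_p: float
    profile_similarity: float
    pareto_rank: int


def pareto_ranks(objectives: np.ndarray) -> np.ndarray:
    """Non-domination ranks (1 = front) for rows of a maximize-all objective
    matrix, by repeated front peeling."""
    n = len(objectives)
    ranks = np.zeros(n, dtype=int)
    remaining = np.arange(n)
    level = 0
    while remaining.size:
        level += 1
        obj = objectives[remaining]
        dominated = np.zeros(len(remaining), dtype=bool)
        for i in range(len(remaining)):
            if dominated[i]:
                continue
            ge = np.all(obj >= obj[i], axis=1)
            gt = np.any(obj > obj[i], axis=1)
            if np.any(ge & gt & (np.arange(len(remaining)) != i)):
                dominated[i] = True
        front = remaining[~dominated]
        ranks[front] = level
        remaining = remaining[dominated]
    return ranks


def _pattern_vector(s: SubjectSet, universe: list[str]) -> np.ndarray:
    """Sparse allele-pattern profile of a set over the shared SNP universe.

    Entry = 1 + modal genotype for member SNPs (so pattern 0 is still
    distinguishable from non-membership), 0 elsewhere.
    """
    v = np.zeros(len(universe))
    pos = {u: i for i, u in enumerate(universe)}
    for f in s.feature_ids:
        if f in pos:
            v[pos[f]] = 1.0 + s.feature_values.get(f, 0.0)
    return v


def match_sets(
    catalog_a: list[SubjectSet],
    catalog_b: list[SubjectSet],
    snp_universe: list[str],
    p_floor: float = 1e-4,
    cosine_floor: float = 0.7,
) -> tuple[list[SetMatch], float]:
    """Match source sets to a replication catalog; return matches + rate.

    Objectives per candidate pair: (-log10 hypergeometric p of shared SNP ids
    over the universe, cosine similarity of allele-pattern profiles). Pareto
    fronts are computed per source set; a source set counts replicated when a
    rank-1 candidate passes both floors.
    """
    if not snp_universe:
        raise ValueError("shared SNP universe is empty")
    uni = [u for u in snp_universe]
    uni_set = set(uni)
    matches: list[SetMatch] = []
    replicated = 0
    for a in catalog_a:
        a_feats = set(a.feature_ids) & uni_set
        va = _pattern_vector(a, uni)
        na = np.linalg.norm(va)
        cand = []
        for b in catalog_b:
            b_feats = set(b.feature_ids) & uni_set
            k = len(a_feats & b_feats)
            p = float(
                stats.hypergeom.sf(k - 1, len(uni), len(a_feats), len(b_feats))
            )
            p = min(max(p, 1e-300), 1.0)
            vb = _pattern_vector(b, uni)
            nb = np.linalg.norm(vb)
            cos = float(va @ vb / (na * nb)) if na > 0 and nb > 0 else 0.0
            cand.append((b.label, p, cos))
        if not cand:
            continue
        obj = np.array([[-np.log10(p), cos] for _, p, cos in cand])
        ranks = pareto_ranks(obj)
        hit = False
        for (label, p, cos), r in zip(cand, ranks):
            matches.append(SetMatch(a.label, label, p, cos, int(r)))
            if r == 1 and p < p_floor and cos > cosine_floor:
                hit = True
        replicated += hit
    rate = replicated / len(catalog_a) if catalog_a else float("nan")
    return matches, rate


def matches_frame(matches: list[SetMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": [m.source_label for m in matches],
            "target": [m.target_label for m in matches],
            "snp_identity_p": [m.snp_identity_p for m in matches],
            "profile_similarity": [m.profile_similarity for m in matches],
            "pareto_rank": [m.pareto_rank for m in matches],
        }
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class ClassifierReport:
    probabilities: pd.DataFrame  # subject x class predicted probabilities
    auc: float
    classes: list[str]


def membership_matrix(
    snp_sets: list[SubjectSet], subject_ids: list[str]
) -> pd.DataFrame:
    """Subjects x SNP-set binary membership indicators."""
    data = {
        s.label: [1.0 if x in set(s.subject_ids) else 0.0 for x in subject_ids]
        for s in snp_sets
    }
    return pd.DataFrame(data, index=subject_ids)


def classify(
    membership: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierReport:
    """Predict phenotype/health membership from SNP-set membership.

    Missing labels (NaN) trigger semi-supervised label spreading over the
    indicator features before the supervised evaluation; the reported AUC is
    stratified cross-validated on the originally labeled subjects only.
    """
    labels = labels.loc[membership.index]
    known = labels.notna()
    if known.sum() < n_folds:
        raise ValueError("too few labeled subjects")
    y_known = labels[known]
    classes = sorted(map(str, y_known.unique()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    x = membership.to_numpy(dtype=float)
    if (~known).any():
        codes = pd.Series(-1, index=membership.index, dtype=int)
        codes[known] = [classes.index(str(v)) for v in y_known]
        ls = LabelSpreading(kernel="knn", n_neighbors=7)
        ls.fit(x, codes.to_numpy())
        # propagated labels are available for downstream use; evaluation
        # below stays on the originally labeled subjects

    xk = x[known.to_numpy()]
    yk = np.array([classes.index(str(v)) for v in y_known])
    clf = LogisticRegression(C=C, max_iter=2000)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proba = cross_val_predict(clf, xk, yk, cv=skf, method="predict_proba")
    if len(classes) == 2:
        auc = float(roc_auc_score(yk, proba[:, 1]))
    else:
        auc = float(roc_auc_score(yk, proba, multi_class="ovr", average="macro"))

    full = clf.fit(xk, yk).predict_proba(x)
    prob_df = pd.DataFrame(full, index=membership.index, columns=classes)
    return ClassifierReport(probabilities=prob_df, auc=auc, classes=classes)
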