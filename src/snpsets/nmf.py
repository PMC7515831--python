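"""NMF biclustering: SNP sets, temperament sets, and super-set rank selection.

Genotypes are one-hot expanded per genotype state (three non-negative columns
per SNP) so a factor can represent a shared allele *pattern*, not just dosage
magnitude. Factorization is multiplicative-update NMF (Frobenius loss) with
seeded restarts; each factor yields a bicluster whose subject and feature
members are the entries whose loading exceeds the column/row mean + 1 SD.
Sets are labeled ``<prefix>_<k>_<i>`` where ``k`` is the factorization rank
and ``i`` the selection order (descending cohesion). Rank sweeps accumulate a
deduplicated catalog and a consensus (co-clustering) matrix per rank whose
cophenetic correlation drives super-set rank selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .containers import (
    MISSING,
    TEMPERAMENT_DIMENSIONS,
    GenotypeMatrix,
    SubjectSet,
    feature_jaccard,
    subject_jaccard,
)

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# non-negative encodings
# ---------------------------------------------------------------------------


def encode_genotypes_onehot(
    g: GenotypeMatrix,
) -> tuple[np.ndarray, list[str], list[str]]:
    """One-hot expansion {0,1,2} -> 3 indicator columns per SNP.

    Missing calls are soft-imputed with the SNP's observed state frequencies
    so every row stays on the simplex. Returns (matrix, feature ids like
    ``snp000001|2``, parallel list of owning SNP ids).
    """
    n, m = g.values.shape
    x = np.zeros((n, 3 * m), dtype=np.float32)
    feature_ids: list[str] = []
    groups: list[str] = []
    snp_ids = g.snp_ids
    for state in (0, 1, 2):
        x[:, state::3] = (g.values == state).astype(np.float32)
    missing = g.values == MISSING
    if missing.any():
        freq = np.stack(
            [(g.values == state).sum(axis=0) for state in (0, 1, 2)], axis=0
        ).astype(np.float64)
        tot = freq.sum(axis=0)
        tot[tot == 0] = 1.0
        freq = freq / tot
        rows, cols = np.where(missing)
        for state in (0, 1, 2):
            x[rows, 3 * cols + state] = freq[state, cols]
    for sid in snp_ids:
        for state in (0, 1, 2):
            feature_ids.append(f"{sid}|{state}")
            groups.append(sid)
    return x, feature_ids, groups


def encode_nonneg(values: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Column-wise min-max scaling into [0, 1] (constant columns -> 0)."""
    x = np.asarray(values, dtype=np.float64)
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span[span == 0] = 1.0
    return ((x - lo) / span).astype(np.float32)


def encode_folded(
    values: pd.DataFrame,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Fold standardized columns into positive/negative deviation parts.

    Each column c becomes ``c|high`` = max(z, 0) and ``c|low`` = max(-z, 0)
    with z the column z-score. Unlike min-max scaling this removes the
    constant offset (which would otherwise absorb an NMF factor and blur
    subject clustering) and lets a factor represent a directional high/low
    profile — the median-split semantics of temperament signatures.
    Returns (matrix, encoded feature ids, parallel raw column ids).
    """
    z = (values - values.mean()) / values.std().replace(0.0, 1.0)
    z = z.to_numpy(dtype=np.float64)
    n, m = z.shape
    x = np.zeros((n, 2 * m), dtype=np.float32)
    x[:, 0::2] = np.clip(z, 0, None)
    x[:, 1::2] = np.clip(-z, 0, None)
    feature_ids: list[str] = []
    groups: list[str] = []
    for c in values.columns:
        feature_ids.extend([f"{c}|high", f"{c}|low"])
        groups.extend([str(c), str(c)])
    return x, feature_ids, groups


# ---------------------------------------------------------------------------
# factorization
# ---------------------------------------------------------------------------


@dataclass
class Factorization:
    W: np.ndarray  # subjects x k
    H: np.ndarray  # k x features
    objective: list[float]  # Frobenius error per iteration
    converged: bool


def _mu_nmf(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> Factorization:
    n, m = x.shape
    scale = np.sqrt(max(x.mean(), _EPS) / k)
    w = rng.random((n, k)).astype(x.dtype) * scale
    h = rng.random((k, m)).astype(x.dtype) * scale
    objective: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        h *= (w.T @ x) / (w.T @ w @ h + _EPS)
        w *= (x @ h.T) / (w @ (h @ h.T) + _EPS)
        err = float(np.linalg.norm(x - w @ h))
        objective.append(err)
        if prev - err < tol * max(prev, 1.0):
            converged = True
            break
        prev = err
    return Factorization(w.astype(np.float64), h.astype(np.float64), objective, converged)


def factorize(
    matrix: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> Factorization:
    """Best-of-restarts multiplicative-update NMF minimizing Frobenius error."""
    x = np.asarray(matrix, dtype=np.float32)
    if (x < 0).any():
        raise ValueError("NMF input must be non-negative")
    if not 1 <= k < min(x.shape) + 1:
        raise ValueError(f"rank {k} out of range for shape {x.shape}")
    rng = np.random.default_rng(seed)
    best: Factorization | None = None
    for _ in range(max(1, n_restarts)):
        fac = _mu_nmf(x, k, rng, max_iter, tol)
        if best is None or fac.objective[-1] < best.objective[-1]:
            best = fac
    assert best is not None
    if not best.converged:
        logger.warning("NMF did not converge within %d iterations", max_iter)
    return best


def consensus_restarts(
    matrix: np.ndarray,
    k: int,
    n_restarts: int,
    seed: int,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> tuple[Factorization, np.ndarray]:
    """Best factorization plus the subject co-clustering consensus matrix."""
    x = np.asarray(matrix, dtype=np.float32)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    consensus = np.zeros((n, n))
    best: Factorization | None = None
    for _ in range(max(1, n_restarts)):
        fac = _mu_nmf(x, k, rng, max_iter, tol)
        labels = fac.W.argmax(axis=1)
        consensus += labels[:, None] == labels[None, :]
        if best is None or fac.objective[-1] < best.objective[-1]:
            best = fac
    consensus /= max(1, n_restarts)
    assert best is not None
    return best, consensus


# ---------------------------------------------------------------------------
# set extraction
# ---------------------------------------------------------------------------


def _threshold_members(
    v: np.ndarray, rule: str = "2means", n_sd: float = 1.0
) -> np.ndarray:
    """Member indices of a loading vector.

    ``"2means"`` (default) splits the loadings into two 1-D k-means groups and
    keeps the upper one — robust whether the loading distribution is a sharp
    bicluster spike or graded cluster membership. ``"mean_sd"`` keeps loadings
    above mean + ``n_sd`` SD (tends to truncate graded memberships).
    """
    if rule == "mean_sd":
        return np.where(v > v.mean() + n_sd * v.std())[0]
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return np.array([], dtype=int)
    t = float(v.mean())
    for _ in range(100):
        below = v[v <= t]
        above = v[v > t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < 1e-10 * max(abs(hi), 1.0):
            break
        t = t_new
    return np.where(v > t)[0]


def _snp_cohesion(
    values: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> tuple[float, dict[str, int]]:
    """Fraction of member cells matching the per-SNP modal genotype."""
    sub = values[np.ix_(rows, cols)]
    agree = 0.0
    total = 0
    modal: dict[int, int] = {}
    for j in range(sub.shape[1]):
        col = sub[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            modal[j] = 0
            continue
        states, counts = np.unique(obs, return_counts=True)
        mode = int(states[counts.argmax()])
        modal[j] = mode
        agree += float((obs == mode).sum())
        total += obs.size
    return (agree / total if total else 0.0), modal


def _continuous_cohesion(values: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> float:
    """Mean fraction of members on the majority side of the cohort median."""
    med = np.median(values, axis=0)
    sub = values[np.ix_(rows, cols)] > med[cols]
    frac_high = sub.mean(axis=0)
    return float(np.maximum(frac_high, 1 - frac_high).mean())


def _contrast_features(
    x_onehot: np.ndarray,
    rows: np.ndarray,
    feature_groups: list[str],
    contrast: float,
) -> list[str]:
    """Grouped features whose within-member state frequency stands out.

    For every one-hot column the member frequency is contrasted with the
    non-member frequency; a SNP joins the set when some genotype state is at
    least ``contrast`` more frequent inside than outside — the shared allele
    pattern that defines a genotype bicluster. (A plain loading threshold on H
    cannot do this: a factor reconstructs its members' whole rows, so its
    loadings are high on background columns every subject shares.)
    """
    n = x_onehot.shape[0]
    member = np.zeros(n, dtype=bool)
    member[rows] = True
    if member.all() or not member.any():
        return []
    f_in = x_onehot[member].mean(axis=0)
    f_out = x_onehot[~member].mean(axis=0)
    diff = f_in - f_out
    groups = np.asarray(feature_groups)
    selected = []
    for grp in dict.fromkeys(feature_groups):
        mask = groups == grp
        if diff[mask].max() > contrast:
            selected.append(grp)
    return selected


def extract_sets(
    fac: Factorization,
    k: int,
    subject_ids: list[str],
    feature_ids: list[str],
    prefix: str = "G",
    raw_values: np.ndarray | None = None,
    feature_groups: list[str] | None = None,
    n_sd: float = 1.0,
    contrast: float = 0.25,
    member_rule: str = "2means",
    encoded: np.ndarray | None = None,
) -> list[SubjectSet]:
    """Turn each factor into a labeled bicluster.

    Subject members come from splitting the factor's loading column with
    ``member_rule`` (upper 2-means group by default). Feature members are,
    for continuous features, the analogous split of the H row; for one-hot
    genotype features (``feature_groups`` given), SNPs whose member-state
    frequency exceeds the non-member frequency by ``contrast``. ``raw_values``
    (subjects x raw features) supplies cohesion; factors with an empty
    membership on either axis are skipped and logged. Selection order (the
    ``i`` in the label) is descending cohesion.
    """
    candidates = []
    raw_ids = list(dict.fromkeys(feature_groups)) if feature_groups else feature_ids
    raw_pos = {f: i for i, f in enumerate(raw_ids)}
    for i in range(k):
        rows = _threshold_members(fac.W[:, i], rule=member_rule, n_sd=n_sd)
        if rows.size == 0:
            logger.info("factor %d of k=%d produced an empty set; skipped", i, k)
            continue
        if feature_groups is not None:
            if encoded is None:
                raise ValueError("one-hot extraction needs the encoded matrix")
            feats = _contrast_features(encoded, rows, feature_groups, contrast)
        else:
            enc_cols = _threshold_members(fac.H[i, :], rule=member_rule, n_sd=n_sd)
            feats = [feature_ids[c] for c in enc_cols]
        if not feats:
            logger.info("factor %d of k=%d produced an empty set; skipped", i, k)
            continue
        cols = np.array([raw_pos[f] for f in feats])
        feature_values: dict[str, float] = {}
        if raw_values is not None:
            if np.issubdtype(np.asarray(raw_values).dtype, np.integer):
                cohesion, modal = _snp_cohesion(raw_values, rows, cols)
                feature_values = {feats[j]: float(m) for j, m in modal.items()}
            else:
                cohesion = _continuous_cohesion(np.asarray(raw_values), rows, cols)
                sub_mean = np.asarray(raw_values)[np.ix_(rows, cols)].mean(axis=0)
                feature_values = {f: float(v) for f, v in zip(feats, sub_mean)}
        else:
            cohesion = float("nan")
        scores = {subject_ids[r]: float(fac.W[r, i]) for r in rows}
        candidates.append(
            (cohesion, [subject_ids[r] for r in rows], feats, scores, feature_values)
        )
    candidates.sort(key=lambda c: (-(c[0] if np.isfinite(c[0]) else -1.0)))
    sets = []
    for order, (cohesion, subj, feats, scores, fvals) in enumerate(candidates, start=1):
        sets.append(
            SubjectSet(
                label=f"{prefix}_{k}_{order}",
                subject_ids=subj,
                feature_ids=feats,
                membership_scores=scores,
                cohesion=cohesion,
                feature_values=fvals,
            )
        )
    return sets


@dataclass
class ConsensusResult:
    """Per-rank consensus co-clustering and its cophenetic correlation."""

    k: int
    consensus_matrix: np.ndarray
    rho_coph: float


def cophenetic_correlation(consensus: np.ndarray) -> float:
    """Correlation between consensus distances and their average-linkage
    dendrogram's cophenetic distances."""
    dist = squareform(1.0 - consensus, checks=False)
    if np.allclose(dist, dist.flat[0] if dist.size else 0.0):
        return 1.0
    link = hierarchy.average(dist)
    rho, _ = hierarchy.cophenet(link, dist)
    return float(rho)


def sweep_ranks(
    matrix: np.ndarray,
    subject_ids: list[str],
    feature_ids: list[str],
    k_range: tuple[int, int],
    n_restarts: int = 10,
    seed: int = 0,
    prefix: str = "G",
    raw_values: np.ndarray | None = None,
    feature_groups: list[str] | None = None,
    n_sd: float = 1.0,
    contrast: float = 0.25,
    member_rule: str = "2means",
    dedup_jaccard: float = 0.95,
    max_iter: int = 300,
) -> tuple[list[SubjectSet], list[ConsensusResult]]:
    """Union of extracted sets over ranks k_min..k_max, deduplicated.

    A set is dropped when both its subject- and feature-Jaccard with an
    earlier-kept set exceed ``dedup_jaccard`` ("non-identical but possibly
    overlapping"). A consensus matrix over restarts is kept per rank.
    """
    k_min, k_max = k_range
    catalog: list[SubjectSet] = []
    consensus_results: list[ConsensusResult] = []
    rng = np.random.default_rng(seed)
    for k in range(k_min, k_max + 1):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fac, consensus = consensus_restarts(
            matrix, k, n_restarts, sub_seed, max_iter=max_iter
        )
        consensus_results.append(
            ConsensusResult(k, consensus, cophenetic_correlation(consensus))
        )
        for s in extract_sets(
            fac, k, subject_ids, feature_ids, prefix=prefix,
            raw_values=raw_values, feature_groups=feature_groups, n_sd=n_sd,
            contrast=contrast, member_rule=member_rule,
            encoded=matrix if feature_groups is not None else None,
        ):
            dup = any(
                subject_jaccard(s, t) > dedup_jaccard
                and feature_jaccard(s, t) > dedup_jaccard
                for t in catalog
            )
            if not dup:
                catalog.append(s)
    return catalog, consensus_results


# ---------------------------------------------------------------------------
# super-set rank selection and signatures
# ---------------------------------------------------------------------------


def select_superset_rank(
    consensus: list[ConsensusResult],
    catalog: list[SubjectSet],
    phenotypes: pd.DataFrame | None = None,
    direction: str = "maximize",
    stability_tol: float = 0.003,
) -> tuple[int, dict[str, int]]:
    """Choose the super-set rank from per-rank cophenetic correlations.

    With ``direction='maximize'`` (default) the chosen rank is the *largest*
    k whose cophenetic correlation lies within ``stability_tol`` of the best:
    coarser clusterings of nested structure are also perfectly stable, so the
    finest rank that is still as stable as the best one marks where real
    structure ends and instability begins. ``'minimize'`` picks the rank of
    minimum cophenetic correlation (the alternative reading). Exact ties
    across every rank (e.g. identical consensus matrices) go to the smallest
    k. Fine-grained sets are then grouped into super-sets by average-linkage
    clustering of their mean member profiles cut at the chosen k.
    """
    if len(consensus) < 2:
        raise ValueError("need at least two candidate ranks")
    rhos = np.array([c.rho_coph for c in consensus])
    ks = np.array([c.k for c in consensus])
    if np.allclose(rhos, rhos[0]):
        logger.info("cophenetic tie across all k; choosing smallest")
        chosen_k = int(ks.min())
    elif direction == "minimize":
        chosen_k = int(ks[np.isclose(rhos, rhos.min())].min())
    else:
        stable = ks[rhos >= rhos.max() - stability_tol]
        chosen_k = int(stable.max())

    assignment: dict[str, int] = {}
    if catalog and phenotypes is not None:
        profiles = np.stack(
            [
                phenotypes.loc[s.subject_ids].mean(axis=0).to_numpy()
                for s in catalog
            ]
        )
        if len(catalog) <= chosen_k:
            assignment = {s.label: i + 1 for i, s in enumerate(catalog)}
        else:
            link = hierarchy.average(pdist(profiles))
            labels = hierarchy.fcluster(link, t=chosen_k, criterion="maxclust")
            assignment = {s.label: int(l) for s, l in zip(catalog, labels)}
    return chosen_k, assignment


@dataclass
class TemperamentSignature:
    """Median-split high/low flags per subscale plus a nearest profile."""

    flags: dict[str, str]  # subscale -> high | low | unmarked
    profile: str | None
    low_confidence: bool = False

    def dimension_flags(self) -> dict[str, int]:
        """Majority sign per temperament dimension: +1 high, -1 low, 0 unmarked."""
        out = {}
        for dim, subs in TEMPERAMENT_DIMENSIONS.items():
            votes = [
                {"high": 1, "low": -1, "unmarked": 0}[self.flags[s]]
                for s in subs
                if s in self.flags
            ]
            total = sum(votes)
            out[dim] = 0 if total == 0 else (1 if total > 0 else -1)
        return out


def signature(
    subject_set: SubjectSet,
    phenotypes: pd.DataFrame,
    profile_signs: dict[str, dict[str, int]] | None = None,
    dead_zone: float = 0.25,
) -> TemperamentSignature:
    """Median-split signature of a subject set.

    A subscale is flagged high (low) when the set-member mean lies more than
    ``dead_zone`` cohort SDs above (below) the cohort median; otherwise it is
    unmarked — a set equal to the whole cohort is unmarked everywhere. The
    profile is the configured template with the best dimension-sign agreement
    (None when nothing agrees). Sets with fewer than 3 members are flagged
    low-confidence.
    """
    from .simulate import PROFILE_SIGNS  # default templates

    profile_signs = profile_signs or PROFILE_SIGNS
    cols = [c for c in phenotypes.columns]
    med = phenotypes.median(axis=0)
    sd = phenotypes.std(axis=0).replace(0.0, 1.0)
    mean = phenotypes.loc[[s for s in subject_set.subject_ids if s in phenotypes.index]].mean(axis=0)
    flags = {}
    for c in cols:
        delta = (mean[c] - med[c]) / sd[c]
        flags[c] = "high" if delta > dead_zone else ("low" if delta < -dead_zone else "unmarked")
    sig = TemperamentSignature(
        flags=flags,
        profile=None,
        low_confidence=len(subject_set.subject_ids) < 3,
    )
    dims = sig.dimension_flags()
    best, best_score = None, 0
    for name, signs in profile_signs.items():
        score = sum(
            1 for d, v in signs.items() if v != 0 and dims.get(d, 0) == v
        ) - sum(1 for d, v in signs.items() if v != 0 and dims.get(d, 0) == -v)
        if score > best_score:
            best, best_score = name, score
    sig.profile = best
    return sig
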