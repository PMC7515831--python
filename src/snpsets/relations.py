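"""Many-to-many SNP-set x temperament-set relations, health fusion, networks.

A relation is an enrichment of shared subjects between a genotype bicluster
and a phenotype cluster, tested with the upper-tail hypergeometric
distribution and validated with a permutation null that shuffles whole
per-subject membership vectors (preserving within-subject set correlations).
Health flags mark the top decile of the product of the three character-trait
totals (well-being) and the bottom decile of Self-directedness +
Cooperativeness (ill-being).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, SubjectSet
from .nmf import TemperamentSignature

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# health indices
# ---------------------------------------------------------------------------


@dataclass
class HealthFlags:
    well_being: pd.Series  # boolean per subject
    ill_being: pd.Series
    well_score: pd.Series  # product of the three character totals
    ill_score: pd.Series  # sum of Self-directedness and Cooperativeness


def health_flags(character_scores: pd.DataFrame) -> HealthFlags:
    """Decile-based well-/ill-being flags from character subscale scores.

    Exactly ``floor(N/10)`` subjects carry each flag; ties at the decile
    boundary are broken by stable subject order (and logged). Requires the
    Self-directedness (sd*), Cooperativeness (co*) and Self-transcendence
    (st*) subscale columns.
    """
    n = len(character_scores)
    if n < 10:
        raise ValueError("need at least 10 subjects for decile flags")
    sd_cols = character_scores.filter(regex="^sd")
    co_cols = character_scores.filter(regex="^co")
    st_cols = character_scores.filter(regex="^st")
    if 0 in (sd_cols.shape[1], co_cols.shape[1], st_cols.shape[1]):
        raise ValueError("character subscales (sd*/co*/st*) are required")
    sd = sd_cols.sum(axis=1)
    co = co_cols.sum(axis=1)
    st = st_cols.sum(axis=1)
    well_score = sd * co * st
    ill_score = sd + co
    k = n // 10

    def _top_k(scores: pd.Series, largest: bool) -> pd.Series:
        vals = scores.to_numpy()
        order = np.argsort(-vals if largest else vals, kind="stable")
        chosen = order[:k]
        boundary = vals[order[k - 1]] if k > 0 else None
        if k < n and boundary is not None and vals[order[k]] == boundary:
            logger.info("decile boundary tie at %.6g broken by subject order", boundary)
        flags = np.zeros(n, dtype=bool)
        flags[chosen] = True
        return pd.Series(flags, index=scores.index)

    return HealthFlags(
        well_being=_top_k(well_score, largest=True),
        ill_being=_top_k(ill_score, largest=False),
        well_score=well_score,
        ill_score=ill_score,
    )


# ---------------------------------------------------------------------------
# hypergeometric relations
# ---------------------------------------------------------------------------


@dataclass
class RelationEdge:
    snp_set_label: str
    temp_set_label: str
    N: int
    n_a: int
    n_b: int
    k_overlap: int
    p_hyper: float
    p_perm: float = float("nan")
    wb_joint: float = float("nan")
    ib_joint: float = float("nan")
    env_label: str | None = None


def hypergeom_relation(a: SubjectSet, b: SubjectSet, n_total: int) -> RelationEdge:
    """Upper-tail hypergeometric enrichment of shared subjects."""
    sa, sb = set(a.subject_ids), set(b.subject_ids)
    k = len(sa & sb)
    p = float(stats.hypergeom.sf(k - 1, n_total, len(sa), len(sb)))
    return RelationEdge(
        snp_set_label=a.label,
        temp_set_label=b.label,
        N=n_total,
        n_a=len(sa),
        n_b=len(sb),
        k_overlap=k,
        p_hyper=min(max(p, np.nextafter(0, 1)), 1.0),
    )


def relation_screen(
    snp_sets: list[SubjectSet],
    temp_sets: list[SubjectSet],
    n_total: int,
    p_threshold: float = 1e-3,
) -> list[RelationEdge]:
    """Test every SNP-set x temperament-set pair; keep p below threshold."""
    edges = []
    for a in snp_sets:
        for b in temp_sets:
            e = hypergeom_relation(a, b, n_total)
            if e.p_hyper < p_threshold:
                edges.append(e)
    return edges


def permutation_null(
    edges: list[RelationEdge],
    snp_sets: list[SubjectSet],
    temp_sets: list[SubjectSet],
    subject_ids: list[str],
    n_perm: int = 2000,
    seed: int = 0,
) -> list[RelationEdge]:
    """Empirical p per edge by permuting whole temperament-membership vectors.

    Each permutation reassigns subjects' temperament-set membership rows as a
    block, preserving within-subject correlations between temperament sets.
    ``p_perm = (1 + #{permuted overlap >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    pos = {s: i for i, s in enumerate(subject_ids)}
    n = len(subject_ids)
    s_idx = {s.label: i for i, s in enumerate(snp_sets)}
    t_idx = {t.label: i for i, t in enumerate(temp_sets)}
    smat = np.zeros((n, len(snp_sets)), dtype=np.float32)
    tmat = np.zeros((n, len(temp_sets)), dtype=np.float32)
    for j, s in enumerate(snp_sets):
        smat[[pos[x] for x in s.subject_ids if x in pos], j] = 1
    for j, t in enumerate(temp_sets):
        tmat[[pos[x] for x in t.subject_ids if x in pos], j] = 1
    observed = smat.T @ tmat
    exceed = np.zeros_like(observed)
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += (smat.T @ tmat[perm]) >= observed
    pmat = (1.0 + exceed) / (n_perm + 1.0)
    for e in edges:
        e.p_perm = float(pmat[s_idx[e.snp_set_label], t_idx[e.temp_set_label]])
    return edges


def attach_health(
    edges: list[RelationEdge],
    snp_sets: list[SubjectSet],
    temp_sets: list[SubjectSet],
    flags: HealthFlags,
) -> list[RelationEdge]:
    """Joint well-/ill-being probabilities among the shared subjects of each edge."""
    by_label = {s.label: set(s.subject_ids) for s in snp_sets}
    by_label.update({t.label: set(t.subject_ids) for t in temp_sets})
    for e in edges:
        shared = sorted(by_label[e.snp_set_label] & by_label[e.temp_set_label])
        if shared:
            e.wb_joint = float(flags.well_being.loc[shared].mean())
            e.ib_joint = float(flags.ill_being.loc[shared].mean())
    return edges


def edges_frame(edges: list[RelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_set": [e.snp_set_label for e in edges],
            "temp_set": [e.temp_set_label for e in edges],
            "N": [e.N for e in edges],
            "n_snp_set": [e.n_a for e in edges],
            "n_temp_set": [e.n_b for e in edges],
            "k_overlap": [e.k_overlap for e in edges],
            "p_hyper": [e.p_hyper for e in edges],
            "p_perm": [e.p_perm for e in edges],
            "wb_joint": [e.wb_joint for e in edges],
            "ib_joint": [e.ib_joint for e in edges],
            "env_set": [e.env_label or "" for e in edges],
        }
    )


# ---------------------------------------------------------------------------
# SNP-set network
# ---------------------------------------------------------------------------


def build_network(
    snp_sets: list[SubjectSet],
    n_subjects: int,
    n_snps: int,
    p_threshold: float = 1e-3,
) -> nx.Graph:
    """Graph over SNP sets: edge when shared-SNP or shared-subject enrichment
    passes the hypergeometric threshold; edges typed accordingly."""
    g = nx.Graph()
    for s in snp_sets:
        g.add_node(s.label, n_subjects=len(s.subject_ids), n_snps=len(s.feature_ids))
    for i, a in enumerate(snp_sets):
        for b in snp_sets[i + 1 :]:
            k_snp = len(set(a.feature_ids) & set(b.feature_ids))
            p_snp = float(
                stats.hypergeom.sf(
                    k_snp - 1, n_snps, len(a.feature_ids), len(b.feature_ids)
                )
            )
            k_sub = len(set(a.subject_ids) & set(b.subject_ids))
            p_sub = float(
                stats.hypergeom.sf(
                    k_sub - 1, n_subjects, len(a.subject_ids), len(b.subject_ids)
                )
            )
            kinds = []
            if p_snp < p_threshold:
                kinds.append("snps")
            if p_sub < p_threshold:
                kinds.append("subjects")
            if kinds:
                g.add_edge(
                    a.label, b.label, kind="+".join(kinds), weight=min(p_snp, p_sub)
                )
    return g


def find_hubs(net: nx.Graph) -> list[str]:
    """Nodes of maximal degree within each connected component (degree > 0)."""
    hubs = []
    for comp in nx.connected_components(net):
        degs = {n: net.degree(n) for n in comp}
        top = max(degs.values())
        if top > 0:
            hubs.extend(sorted(n for n, d in degs.items() if d == top))
    return hubs


# ---------------------------------------------------------------------------
# trait pipelines and switch features
# ---------------------------------------------------------------------------


def trait_pipelines(
    edges: list[RelationEdge],
    signatures: dict[str, TemperamentSignature],
) -> dict[str, dict]:
    """Group relations by temperament dimension x {high, low}.

    A pipeline is *composite* when temperament sets from more than one profile
    contribute relations to the same trait pole (heterogeneity), *direct*
    otherwise.
    """
    pipelines: dict[str, dict] = {}
    for e in edges:
        sig = signatures.get(e.temp_set_label)
        if sig is None:
            continue
        for dim, flag in sig.dimension_flags().items():
            if flag == 0:
                continue
            key = f"{dim}_{'high' if flag > 0 else 'low'}"
            entry = pipelines.setdefault(key, {"relations": [], "profiles": set()})
            entry["relations"].append(e)
            if sig.profile:
                entry["profiles"].add(sig.profile)
    for entry in pipelines.values():
        entry["composite"] = len(entry["profiles"]) > 1
    return pipelines


def switch_features(
    snp_set: SubjectSet,
    g: GenotypeMatrix,
    well_score: pd.Series,
    p_threshold: float = 0.01,
) -> list[dict]:
    """Member SNPs whose modal-pattern carriage splits the set by well-being.

    For each member SNP, set members are split into carriers vs non-carriers
    of the set's modal genotype at that SNP and compared on the continuous
    well-being score with a rank-sum test.
    """
    members = [s for s in snp_set.subject_ids if s in well_score.index]
    sub = g.select_snp_ids(snp_set.feature_ids)
    row = {s: i for i, s in enumerate(g.subject_ids)}
    rows = np.array([row[s] for s in members])
    out = []
    for j, snp in enumerate(sub.snp_ids):
        col = sub.values[rows, j]
        obs = col != MISSING
        if obs.sum() < 4:
            continue
        vals = col[obs]
        states, counts = np.unique(vals, return_counts=True)
        mode = states[counts.argmax()]
        carriers = vals == mode
        if carriers.all() or not carriers.any():
            continue
        scores = well_score.loc[np.array(members)[obs]].to_numpy()
        try:
            stat, p = stats.mannwhitneyu(
                scores[carriers], scores[~carriers], alternative="two-sided"
            )
        except ValueError:
            continue
        if p < p_threshold:
            out.append(
                {"snp_id": snp, "modal_genotype": int(mode), "p_ranksum": float(p)}
            )
    return out
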