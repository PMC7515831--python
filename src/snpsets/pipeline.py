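"""End-to-end analysis pipeline on a synthetic (or pre-written) cohort.

Stages: simulate -> QC -> ancestry PCs -> empirical temperament index ->
single-SNP preselection -> NMF sweeps (SNP sets, temperament sets) ->
super-set rank selection and signatures -> SKAT set association ->
hypergeometric relations with permutation null and health fusion ->
SNP-set network and hubs -> heritability (+ environment sets, mediated
relations) -> genotype -> phenotype classifier. All outputs are plain-text
(TSV/JSON/GraphML) written with fixed formats so a fixed (config, seed) pair
reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as sio
from .association import KernelSpec, empirical_index, significance_screen, skat_test
from .containers import CHARACTER_SUBSCALES, TEMPERAMENT_SUBSCALES, CovariateTable
from .heritability import env_sets, estimate_h2, gxe_adjustment, mediated_relations
from .nmf import (
    encode_folded,
    encode_genotypes_onehot,
    select_superset_rank,
    signature,
    sweep_ranks,
)
from .qc import ancestry_pcs, preselect_snps, qc_filter
from .relations import (
    attach_health,
    build_network,
    edges_frame,
    find_hubs,
    health_flags,
    permutation_null,
    relation_screen,
)
from .replication import classify, membership_matrix
from .simulate import BlockSpec, CohortConfig, EnvSpec, simulate_cohort, write_cohort


def default_cohort_config() -> CohortConfig:
    """Desk-scale cohort with planted block -> profile -> health structure."""
    return CohortConfig(
        n_subjects=300,
        n_snps=600,
        missing_rate=0.02,
        fst=0.01,
        fidelity=0.9,
        blocks=[
            BlockSpec(60, 40, cluster="Antisocial", effect=("novelty_seeking", 0.8)),
            BlockSpec(60, 40, cluster="Sensitive", effect=("harm_avoidance", 0.8)),
            BlockSpec(60, 40, cluster="Reliable", effect=("persistence", 0.8)),
            BlockSpec(50, 40, cluster="Sensitive", effect=("reward_dependence", 0.6)),
        ],
        h2_target=0.4,
        env=[
            EnvSpec("low_parental_income", cluster="Antisocial", target_r=0.3, binary=True),
            EnvSpec("stressful_life_events", cluster="Antisocial", target_r=0.2),
            EnvSpec("childhood_tolerance", cluster="Sensitive", target_r=0.25),
            EnvSpec("urban_residence", target_r=0.0, binary=True, prevalence=0.5),
        ],
    )


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=default_cohort_config)
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    n_pcs: int = 3
    preselect_p: float = 0.01
    min_preselected: int = 20
    genotype_k: tuple[int, int] = (2, 8)
    genotype_restarts: int = 5
    phenotype_k: tuple[int, int] = (2, 8)
    phenotype_restarts: int = 30
    skat_threshold: float = 4e-4
    relation_p: float = 1e-3
    n_permutations: int = 2000
    perm_p_threshold: float = 4.6e-3
    trim_fraction: float = 0.05
    n_boot: int = 50
    env_k: tuple[int, int] = (2, 4)
    rank_direction: str = "maximize"


def run_pipeline(
    config: PipelineConfig, seed: int, outdir: str | Path
) -> dict:
    """Run the full analysis and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    seeds = {name: int(root.integers(0, 2**31 - 1)) for name in
             ("cohort", "gsweep", "tsweep", "perm", "h2", "env", "clf")}

    # --- cohort -----------------------------------------------------------
    cohort = simulate_cohort(config.cohort, seeds["cohort"])
    write_cohort(cohort, outdir / "cohort")
    g_raw = cohort.genotypes
    phen = cohort.phenotypes
    subject_ids = list(g_raw.subject_ids)
    n_total = len(subject_ids)

    # --- QC / PCs / index / preselection ---------------------------------
    g_qc, qc_report = qc_filter(
        g_raw, config.maf_min, config.call_rate_min, config.hwe_p_min
    )
    sio.write_tsv(qc_report.to_frame(), outdir / "qc_report.tsv")
    sex = cohort.covariates.set_index("subject_id")["sex"].loc[subject_ids].to_numpy()
    cov = ancestry_pcs(g_qc, sex=sex, k=config.n_pcs)
    sio.write_tsv(cov.to_frame(), outdir / "covariates_pcs.tsv")

    index = empirical_index(phen.loc[subject_ids])
    index.to_frame().to_csv(outdir / "temperament_index.tsv", sep="\t", float_format="%.6g")

    selected, snp_p = preselect_snps(g_qc, index.to_numpy(), cov, config.preselect_p)
    sio.write_tsv(
        pd.DataFrame({"snp_id": g_qc.snp_ids, "p": snp_p}), outdir / "preselect.tsv"
    )
    if len(selected) < config.min_preselected:
        selected = g_qc.snp_ids  # too few survivors to cluster meaningfully; keep all
    g_sel = g_qc.select_snp_ids(selected)

    # --- NMF sweeps -------------------------------------------------------
    x_g, feat_ids, groups = encode_genotypes_onehot(g_sel)
    snp_sets, _ = sweep_ranks(
        x_g, subject_ids, feat_ids, config.genotype_k,
        n_restarts=config.genotype_restarts, seed=seeds["gsweep"], prefix="G",
        raw_values=g_sel.values, feature_groups=groups,
    )
    temp_cols = list(TEMPERAMENT_SUBSCALES)
    x_t, t_feats, t_groups = encode_folded(phen.loc[subject_ids, temp_cols])
    temp_sets, consensus = sweep_ranks(
        x_t, subject_ids, t_feats, config.phenotype_k,
        n_restarts=config.phenotype_restarts, seed=seeds["tsweep"], prefix="T",
        raw_values=phen.loc[subject_ids, temp_cols].to_numpy(),
        feature_groups=t_groups,
    )
    chosen_k, superset_assignment = select_superset_rank(
        consensus, temp_sets, phen.loc[subject_ids, temp_cols],
        direction=config.rank_direction,
    )
    signatures = {
        t.label: signature(t, phen.loc[subject_ids, temp_cols]) for t in temp_sets
    }

    sio.sets_to_json(snp_sets, outdir / "snp_sets.json")
    sio.sets_to_json(temp_sets, outdir / "temperament_sets.json")
    cat_g = sio.catalog_frame(snp_sets)
    sio.write_tsv(cat_g, outdir / "snp_sets.tsv")
    cat_t = sio.catalog_frame(temp_sets)
    cat_t["profile"] = [signatures[l].profile or "" for l in cat_t["label"]]
    cat_t["superset"] = [superset_assignment.get(l, 0) for l in cat_t["label"]]
    sio.write_tsv(cat_t, outdir / "temperament_sets.tsv")

    # --- SKAT -------------------------------------------------------------
    results = [
        skat_test(s, g_qc, index.to_numpy(), cov, KernelSpec()) for s in snp_sets
    ]
    assoc = pd.DataFrame(
        {
            "set_label": [r.set_label for r in results],
            "skat_p": [r.p_set for r in results],
            "avg_snp_p": [r.p_avg for r in results],
            "best_snp_p": [r.p_best for r in results],
            "worst_snp_p": [r.p_worst for r in results],
            "n_subjects": [r.n_subjects for r in results],
            "n_snps": [r.n_snps for r in results],
        }
    )
    sio.write_tsv(assoc, outdir / "associations.tsv")
    significant = significance_screen(results, config.skat_threshold)
    sio.write_tsv(significant, outdir / "significant_sets.tsv")
    sig_labels = set(significant["set_label"])
    sig_sets = [s for s in snp_sets if s.label in sig_labels]

    # --- relations + health fusion ----------------------------------------
    flags = health_flags(phen.loc[subject_ids, list(CHARACTER_SUBSCALES)])
    edges = relation_screen(sig_sets or snp_sets, temp_sets, n_total, config.relation_p)
    edges = permutation_null(
        edges, sig_sets or snp_sets, temp_sets, subject_ids,
        n_perm=config.n_permutations, seed=seeds["perm"],
    )
    edges = [e for e in edges if e.p_perm < config.perm_p_threshold]
    edges = attach_health(edges, snp_sets, temp_sets, flags)
    sio.write_tsv(edges_frame(edges), outdir / "relations.tsv")

    net = build_network(snp_sets, n_total, g_sel.n_snps, config.relation_p)
    nx.write_graphml(net, outdir / "network.graphml", named_key_ids=True)
    edge_rows = [
        {"a": a, "b": b, "kind": d["kind"], "weight": d["weight"]}
        for a, b, d in sorted(net.edges(data=True))
    ]
    sio.write_tsv(pd.DataFrame(edge_rows, columns=["a", "b", "kind", "weight"]),
                  outdir / "network_edges.tsv")
    hubs = find_hubs(net)

    # --- heritability + environment ---------------------------------------
    h2_snps = sorted({f for s in (sig_sets or snp_sets) for f in s.feature_ids})
    h2 = estimate_h2(
        g_qc.select_snp_ids(h2_snps),
        index.to_numpy(),
        env=cohort.environment.loc[subject_ids].to_numpy(),
        trim_fraction=config.trim_fraction,
        n_boot=config.n_boot,
        seed=seeds["h2"],
    )
    env_catalog: list = []
    mediated: list = []
    if cohort.environment.shape[1] >= 2:
        env_catalog, _ = env_sets(
            cohort.environment.loc[subject_ids], config.env_k, seed=seeds["env"]
        )
        mediated = mediated_relations(
            sig_sets or snp_sets, temp_sets, env_catalog, subject_ids,
            p_threshold=config.relation_p,
        )
        sio.write_tsv(edges_frame(mediated), outdir / "mediated_relations.tsv")

    # --- classifier --------------------------------------------------------
    memb = membership_matrix(snp_sets, subject_ids)
    clf_out = {}
    for name, lab in (
        ("well_being", flags.well_being.map({True: "well", False: "other"})),
        ("ill_being", flags.ill_being.map({True: "ill", False: "other"})),
    ):
        report = classify(memb, lab, seed=seeds["clf"])
        clf_out[f"auc_{name}"] = round(report.auc, 6)

    summary = {
        "n_subjects": n_total,
        "n_snps_qc": g_qc.n_snps,
        "n_snps_preselected": g_sel.n_snps,
        "n_snp_sets": len(snp_sets),
        "n_temperament_sets": len(temp_sets),
        "chosen_superset_k": chosen_k,
        "n_significant_snp_sets": len(sig_sets),
        "n_relations": len(edges),
        "n_mediated_relations": len(mediated),
        "n_env_sets": len(env_catalog),
        "hubs": hubs,
        "h2": round(h2.h2, 6),
        "h2_adjusted": round(h2.adjusted_h2, 6),
        "h2_se": round(h2.se, 6) if h2.se == h2.se else None,
        **clf_out,
    }
    (outdir / "heritability.json").write_text(
        json.dumps(gxe_adjustment(h2), indent=1, sort_keys=True, default=float)
    )
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str)
    )
    return summary
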