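"""Quality control, ancestry PCs, and single-SNP preselection.

QC removes SNPs failing minor-allele-frequency, call-rate, and Hardy-Weinberg
thresholds. Ancestry principal components plus sex become the covariates for
every later association test. Preselection keeps SNPs with an uncorrected
single-SNP association p below 0.01 against the temperament index.
"""

import numpy as np

from snpsets.association import empirical_index
from snpsets.qc import ancestry_pcs, preselect_snps, qc_filter
from snpsets.simulate import BlockSpec, CohortConfig, simulate_cohort

config = CohortConfig(
    n_subjects=500,
    n_snps=400,
    fst=0.05,
    blocks=[
        # additive architecture: the causal SNPs carry a dosage-linear signal,
        # so single-SNP preselection has real power to find them
        BlockSpec(60, 10, effect=("novelty_seeking", 1.0), effect_mode="additive"),
    ],
    h2_target=0.4,
)
cohort = simulate_cohort(config, seed=7)

g_qc, report = qc_filter(cohort.genotypes, maf_min=0.01, call_rate_min=0.95,
                         hwe_p_min=1e-6)
print(f"QC: {report.n_input} SNPs in, {report.n_retained} retained")
if len(report.removed):
    print(report.removed.groupby("reason").size().to_string())

sex = cohort.covariates["sex"].to_numpy(dtype=float)
cov = ancestry_pcs(g_qc, sex=sex, k=3)
subpop = np.array([cohort.truth.subpopulation[s] for s in g_qc.subject_ids])
r = np.corrcoef(cov.ancestry_pcs[:, 0], subpop)[0, 1]
print(f"|corr(PC1, subpopulation)| = {abs(r):.3f}")

index = empirical_index(cohort.phenotypes)
kept, pvals = preselect_snps(g_qc, index.to_numpy(), cov, p_threshold=0.01)
planted = set(cohort.truth.blocks[0].snp_ids)
hits = sum(s in planted for s in kept)
print(f"preselection kept {len(kept)}/{g_qc.n_snps} SNPs; "
      f"{hits}/{len(planted)} planted SNPs among them")
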