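"""Simulate a cohort with planted structure and look at what was planted.

The generator produces genotypes (with missingness and mild population
structure), 12 temperament and 13 character subscale scores organized around
three phenotype profiles, environment variables, and a truth record that the
later examples score against.
"""

import numpy as np

from snpsets.simulate import BlockSpec, CohortConfig, EnvSpec, simulate_cohort

config = CohortConfig(
    n_subjects=300,
    n_snps=400,
    blocks=[
        # 50 subjects x 30 SNPs sharing an allele pattern at fidelity 0.9;
        # members are drawn mostly from the Antisocial profile cluster and
        # membership raises their novelty-seeking scores
        BlockSpec(50, 30, cluster="Antisocial", effect=("novelty_seeking", 0.8)),
    ],
    env=[EnvSpec("stress", cluster="Antisocial", target_r=0.25)],
    h2_target=0.3,
)

cohort = simulate_cohort(config, seed=7)

g = cohort.genotypes
print(f"genotypes: {g.n_subjects} subjects x {g.n_snps} SNPs")
print(f"missing rate: {np.mean(g.values == -1):.3f}")
print(f"MAF range: {g.maf().min():.3f} .. {g.maf().max():.3f}")
print(f"phenotype columns: {list(cohort.phenotypes.columns)}")

block = cohort.truth.blocks[0]
print(f"\nplanted block: {len(block.subject_ids)} subjects x {len(block.snp_ids)} SNPs")
print(f"allele pattern head: {block.allele_pattern[:8]}")

clusters = cohort.truth.cluster_assignments
members = set(block.subject_ids)
frac = np.mean([clusters[s] == "Antisocial" for s in members])
print(f"fraction of block members in the Antisocial cluster: {frac:.2f}")

ns = cohort.phenotypes[["ns1", "ns2", "ns3", "ns4"]].mean(axis=1)
inside = ns[ns.index.isin(members)].mean()
outside = ns[~ns.index.isin(members)].mean()
print(f"mean novelty seeking inside block {inside:.2f} vs outside {outside:.2f}")
print(f"env/stress correlation target: {cohort.truth.env_targets}")
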