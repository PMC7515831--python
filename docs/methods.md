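# Methods

Statistical model, parameter choices, and known limitations of each stage.
Every empirical statement here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what those runs measure.

## Synthetic cohort generator (`snpsets.simulate`)

**Genotypes.** An `n_subjects × n_snps` int8 matrix of minor-allele counts in
{0, 1, 2}, with −1 as the missing sentinel. Background SNPs are
Hardy–Weinberg binomial draws at MAFs uniform in `maf_range` (default
0.05–0.5). Two subpopulations receive Balding–Nichols perturbed frequencies
at a configurable Fst (default 0.01). Missing calls are masked uniformly at
`missing_rate` (default 0.02).

**Planted blocks.** A `BlockSpec` plants a subject × SNP bicluster: block
members carry a shared allele pattern (one genotype code per block SNP) with
probability `fidelity` (default 0.9) per call, and background draws
otherwise. `cluster` biases block-subject sampling toward one phenotype
cluster with probability `purity` (default 0.9), planting a SNP-set ×
temperament-set relation. `effect` plants a genetic effect on one temperament
dimension in one of two modes: `membership` adds the effect to members only
(a set-level, non-linear architecture), `additive` scales the standardized
dosage sum over the block's SNPs for every subject (a SNP-linear
architecture, the appropriate ground truth for regression-based
heritability).

**Phenotypes.** Twelve temperament and thirteen character subscales. Each
subject belongs to one of three profiles (Reliable, Antisocial, Sensitive)
whose mean templates are separated by `template_gap` (default 1.0) over
subscale noise of `noise_sd` (default 1.0). When `h2_target` is set, the
genetic component contributed by block effects is rescaled so that its
variance share of the standardized mean of the 12 temperament subscales
equals the target exactly (bookkept in the truth record); infeasible targets
raise.

**Environment.** Each `EnvSpec` draws a continuous or binary variable whose
point-biserial correlation with its cluster indicator is solved to hit
`target_r`; infeasible binary targets (given the prevalence) raise.

**Scope.** The generator makes no attempt at linkage disequilibrium decay,
realistic allele-frequency spectra, X-chromosome dosage, assortative mating,
or longitudinal structure. Population structure is a two-group
Balding–Nichols caricature. Phenotype noise is Gaussian and homoscedastic.
Cohorts are exchangeable draws given the seed; the only cross-cohort
dependence offered is `pattern_truth`, which replays block SNP ids and
allele patterns with fresh subjects.

## Genotype QC (`snpsets.qc`)

SNPs failing MAF < 0.01, call rate < 0.95, or an exact Hardy–Weinberg test
p < 1e-6 are removed (thresholds of 0 disable a filter; removals are
itemized with reasons). The HWE p-value is the standard exact conditional
test: the probability, given the minor-allele count, of heterozygote counts
with probability no larger than the observed one. Ancestry PCs are the top
right singular vectors of the mean-imputed, column-standardized genotype
matrix (k = 3 by default), returned with sex as the covariate table whose
design matrix (intercept + sex + PCs) is shared by all association models.
Preselection keeps SNPs whose covariate-adjusted single-SNP Wald p is below
an uncorrected 0.01, fitting each SNP on its pairwise-complete subjects.

## Set discovery (`snpsets.nmf`)

**Encodings.** Genotypes are one-hot encoded per dosage level (three columns
per SNP, missing calls contribute nothing), so a factor can capture a shared
allele *pattern* rather than allele load. Continuous matrices (phenotypes,
environment) use a folded encoding — positive and negative half-ranges of the
z-score in separate columns — which keeps the input non-negative while
preserving the direction of deviation; constant columns encode to zeros.

**Factorization.** Multiplicative-update NMF (Frobenius objective, 300
iterations, relative tolerance 1e-5), best of `n_restarts` by reconstruction
error. The objective is non-increasing by construction; rank-1 problems are
recovered to relative error below 1e-6 (asserted in the tests).

**Set extraction.** Subjects load on a factor when a 2-means split of the
factor's subject loadings puts them in the upper cluster (spike-safe; falls
back to mean + SD for degenerate splits). Features join a set when their
member frequency exceeds the non-member frequency by `contrast` = 0.25
within a one-hot group. Sets are labeled `<prefix>_<rank>_<order>`, ordered
by descending cohesion (modal-genotype agreement for SNP sets, member
z-score concentration for continuous features).

**Rank sweep and selection.** The catalog is the union over ranks
`k_min..k_max`, dropping any set whose subject- and feature-Jaccard against
an earlier set both exceed 0.95. Consensus (co-clustering) matrices over
restarts give a cophenetic correlation per rank; the chosen phenotype rank is
the smallest k whose cophenetic correlation is within `stability_tol` =
0.003 of the best, which prefers the finest stable description and resolves
exact ties toward fewer clusters.

## Set association (`snpsets.association`)

The phenotype is a comprehensive temperament index: the standardized first
principal component of the 12 standardized temperament subscales, oriented
positively with Persistence. Each SNP set is tested with a
variance-component score statistic `Q = r' G W² G' r`, where `r` are
residuals of the index on the covariate design and `W` holds per-SNP weights
(Beta(1, 25) density at the MAF, the conventional rare-variant weighting).
Under the null, Q is a mixture of 1-df chi-squares weighted by the
eigenvalues of the projected, weighted genotype cross-product; tail
probabilities are computed by Imhof's integral, with the Liu moment-matching
approximation as a fallback (the two disagree by < 10% in relative terms
over random spectra in the tests; single-eigenvalue cases reduce exactly to
a scaled chi-square). One-SNP sets reproduce the analytic score test; the
acceptance run also checks the empirical type-I error (0.04–0.06 band at
α = 0.05) and agreement with an explicit permutation oracle for 10-SNP sets.
Monomorphic sets are reported untestable rather than p = 1. The significance
screen applies a raw threshold (default 4e-4) and reports Bonferroni and
Benjamini–Hochberg flags alongside.

Two consequences of these choices are worth knowing (both demonstrated in
`examples/04_associations_relations_network.py`): the Beta(1, 25) weights
concentrate power on rarer variants, so a uniform common-variant signal is
better served by flat weights; and the ancestry PCs absorb strong block
structure (a large planted block dominates the genotype covariance), which
shrinks the kernel signal for exactly the sets that are easiest to discover.
The set-overlap relation machinery, not the kernel test, is the sensitive
detector of membership-type effects.

## Relations and network (`snpsets.relations`)

SNP-set × temperament-set overlaps are screened with the upper-tail
hypergeometric probability (exactly equal to exhaustive enumeration, checked
for all configurations with ≤ 12 subjects), then assigned an empirical p by
permuting whole temperament-membership rows: `p = (1 + #{permuted overlap ≥
observed}) / (R + 1)`. Because the overlap count is discrete with large tie
atoms, this estimator is *conservative*: its null mean is 0.5 plus half the
tie probability (measured ≈ 0.556 at 300 pairs, R = 500), while
`P(p ≤ α) ≤ α` holds at every level — the property the acceptance test
asserts. Health flags mark the top ⌊N/10⌋ subjects by the product of the
three character-dimension totals (well-being) and the bottom ⌊N/10⌋ by the
Self-directedness + Cooperativeness sum (ill-being); both depend only on
score ranks, so they are invariant to increasing affine transforms. The
SNP-set network connects sets whose shared SNPs or shared subjects are
hypergeometrically enriched; hubs are the maximal-degree nodes per connected
component.

## Heritability and environment (`snpsets.heritability`)

Heritability of the temperament index is the out-of-sample R² of a
cross-validated ridge regression on the standardized selected SNPs (5 folds;
penalty chosen on the full sample and frozen for the bootstrap), with the
most extreme `trim_fraction` = 0.05 of squared residuals trimmed per fold,
and the result clamped to [0, 1] (clamping is logged). This estimator is
deliberately conservative: cross-validated R² is biased slightly downward,
so estimates sit at or below the planted target (the acceptance run measures
means within ±0.1 of targets 0.2 and 0.5 at n = 1000, and ≈ 0 on null
cohorts). The adjusted estimate partials measured environment columns out of
the phenotype first; a zero-variance environment leaves the estimate exactly
unchanged. Environment sets reuse the NMF machinery on the folded
environment matrix (`E_` labels). Mediated relations re-test SNP-set ×
temperament-set pairs inside environment-set strata that significantly
overlap the SNP set, and report edges significant in the stratum but not
marginally; strata below `min_stratum` = 20 subjects are skipped.

## Replication and classification (`snpsets.replication`)

Set catalogs from two cohorts are matched on two objectives per candidate
pair: −log10 of the hypergeometric probability of the shared SNP ids over
the common universe, and the cosine similarity of allele-pattern profile
vectors. Pareto fronts are computed per source set; a set replicates when a
rank-1 candidate passes both floors (p < 1e-4 and cosine ≥ 0.7). Identical
membership with a disagreeing allele pattern therefore fails (the tests pin
a case with cosine exactly 0.6). Small sets are a known limitation: a
one-SNP set cannot reach the identity-p floor even against itself, so
self-replication below 1.0 for catalogs containing singleton sets is
expected behaviour. The classifier is an L2 logistic regression on binary
set-membership indicators, scored by stratified cross-validated AUC on
labeled subjects; missing labels trigger label spreading over the indicators
before the supervised evaluation, and the AUC is still computed on the
originally labeled subjects only.

## Determinism

Every routine takes an explicit seed; derived seeds are drawn below 2³¹ from
a `numpy` generator seeded by it. The CLI pipeline writes byte-identical
artifact trees for identical config + seed (asserted end to end in the
acceptance suite), including the PLINK .bed/.bim/.fam cohort output.

## Limitations

- The generator's simplifications (no LD, two-population structure, Gaussian
  noise) mean calibration and recovery results transfer to real genotype
  data only qualitatively.
- The kernel test's default rare-variant weighting and PC adjustment trade
  power against common-variant block signals, as described above.
- The permutation relation p is conservative for heavily tied overlaps;
  thresholds on it should be read as upper bounds on the false-positive rate.
- Cross-validated ridge R² is a lower-biased heritability proxy, not a
  variance-component (REML) estimate; it measures the linear dosage signal
  in the selected SNPs only.
- Cophenetic rank selection is evaluated on well-separated three-profile
  fixtures; closely spaced or unbalanced cluster structures may select
  adjacent ranks.
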