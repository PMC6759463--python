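# Methods

`lenspop` re-implements, as a tested library plus a sequence of analysis
drivers, the post-genotyping workflow used to characterize highly inbred
crop germplasm panels from GBS-style biallelic SNP data: quality control,
replicate-calibrated duplicate detection, population-structure inference
by three complementary routes, Weir–Cockerham F_ST analysis, distance
trees, randomized-block phenotype statistics, and kinship mixed-model
association. Raw-read processing and SNP calling are out of scope; the
input is a samples × loci matrix of alternate-allele counts (0/1/2 with a
missing sentinel).

## Data model

Genotypes are unphased diploid calls at biallelic SNPs. Because the
target crops (lentil-like cleistogamous selfers) are nearly completely
inbred, heterozygotes are rare and per-locus inbreeding coefficients are
expected near 1; several estimator choices below (observed heterozygosity
in the F_ST components, the inbreeding-coefficient QC filter) follow from
not assuming Hardy–Weinberg equilibrium. Missing calls are never imputed
at I/O time; each stage states its own policy:

* PCA / k-means / DAPC: per-locus mean imputation, then centre and scale;
* admixture likelihood, F_ST, IBS, Nei distances, LD r²: missing calls
  skipped exactly (pairwise-complete);
* GWAS marker columns: per-locus mean imputation.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is verified.

Genotypes follow the Balding–Nichols island model. Per locus an
ancestral frequency p ~ Uniform(0.05, 0.95) is drawn; subpopulation k
draws p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), so F_k is population
k's expected differentiation from the ancestral pool and is the quantity
the Weir–Cockerham estimator recovers. Within an individual, with
probability F_IS (default 0.95) one allele is drawn and doubled,
otherwise two alleles are drawn independently — reproducing the
homozygote excess of a selfing crop (the realized 1 − H_obs/H_exp tracks
F_IS; verified in the tests).

On top of the island model the generator plants the nuisance structure a
germplasm collection shows in practice, with defaults chosen to emulate a
Mediterranean lentil panel:

* five subpopulations of 33 accessions at F = 0.25–0.35 (pairwise
  differentiation lands in the low-0.2 to high-0.2 range);
* 19 admixed accessions with ancestry from a flat Dirichlet truncated so
  max q ≤ 0.6 — by construction they fail the q > 0.6 assignment rule;
* a four-way replicate set of one reference accession plus four more
  duplicate groups (8 extra copies), each copy differing from its source
  at a 1% per-call error rate;
* 5% uniformly random missing calls; transition alleles at 64% of loci.

Phenotypes follow a two-block randomized design: trait value = cluster
mean + block effect + β · (allele count at one causal marker) + Gaussian
residual. Default cluster means for the six traits (flowering time,
plant height, first-flowering-node height, seed area/perimeter/diameter)
reproduce the qualitative pattern of real cluster × trait tables for this
kind of panel: one small-seeded early cluster, one large-seeded cluster,
and intermediate clusters. The causal marker sits mid-panel and affects
the three seed-size traits with effects of about one residual SD per
allele, so the three traits are genetically correlated through it.

What the generator does **not** emulate: linkage (loci are exchangeable
and essentially LD-free, so the LD-pruning stage is nearly a no-op on
synthetic data — it is exercised by planted correlated columns in the
tests), genotyping-error structure beyond the duplicate-copy error model,
hierarchical population splits (tests that need nested structure build
frequencies hierarchically by composing two Balding–Nichols draws), and
any geographic or selective signal. Passing tests therefore demonstrate
estimator correctness and parameter recovery under the island model, not
robustness to real GBS artefacts.

Everything is deterministic given (`SimSpec`, seed): one `numpy`
Generator seeded from the `SimSpec` drives all draws, and identical
specs produce byte-identical outputs.

## Quality control

Per locus: minor allele frequency maf = min(p, 1−p) with p the mean call
over non-missing samples divided by 2; call rate; inbreeding coefficient
F = 1 − H_obs/H_exp with H_exp = 2p(1−p) (undefined for monomorphic
loci, which fail the MAF filter anyway). Filters are strict
inequalities: maf > 0.05, call rate > 0.80, F > 0.8; then samples with
call rate < 0.80 are removed. The filter order (MAF → call rate → F) only
affects the attrition report, never the kept set, and the cascade is
idempotent. The transition/transversion ratio counts {A,G} and {C,T}
allele pairs as transitions and is reported to two decimals.

LD pruning is a greedy sequential scan in file order: locus j is dropped
when its squared Pearson correlation (composite genotypic r², over
pairwise-complete samples) with any previously kept locus is ≥ 0.5.
There is no positional window because UNEAK-style GBS loci carry no
coordinates. Zero-variance loci count as r² = 0. The kept set provably
contains no pair at or above the threshold (checked against a brute-force
all-pairs oracle in the tests), and pruning is idempotent.

## Duplicate detection

Per locus the IBS score of two calls a, b is the shared-allele fraction
1 − |a−b|/2; a pair's similarity is the mean over loci where both calls
are present (pairs with no shared loci are flagged undefined, never
zeroed). The redundancy threshold is calibrated from designated
biological replicates as mean − 3·SD of their pairwise IBS values (sample
SD, ddof = 1; a single pair gives SD 0 with a warning). Redundancy
groups are the connected components of the graph linking pairs with IBS ≥
threshold — components rather than cliques because near-identical
genotypes should collapse transitively into disjoint groups. Each
group's representative is its highest-call-rate member (ties broken by
matrix order). On the default synthetic panel the calibrated threshold
lands near 0.97 with replicate means near 0.99, recovers every planted
duplicate and never merges accessions across populations (10 seeds).

## Population structure

**k-means + BIC.** Mean-imputed, scaled genotypes are projected onto the
smallest set of principal components explaining ≥ 95% of variance;
k-means (10 restarts) runs for k = 1..k_max and the selected k minimizes
BIC(k) = n·ln(WSS_k/n) + k·ln(n) on the PC scores. On five planted
populations at F = 0.3 the BIC minimum is k = 5 with assignments matching
the planted labels (ARI ≥ 0.95 over seeds).

**DAPC.** Linear discriminant axes are fitted on the PCA scores; the
retained PC count is chosen by stratified cross-validation of held-out
assignment error, with candidate counts starting at K−1 so the final
model carries the full K−1 discriminant axes. Ties go to fewer PCs.

**Admixture model.** Individual i has ancestry q_i (simplex over K
clusters); cluster k has per-locus alternate-allele frequencies f_kl.
The binomial log-likelihood

  ℓ(Q,F) = Σ_{il observed} [ g_il ln Σ_k q_ik f_kl + (2−g_il) ln Σ_k q_ik(1−f_kl) ]

is maximized by EM with multiplicative count-expectation updates
(frappe/ADMIXTURE-style), f clamped to [1e−6, 1−1e−6], best of 10 random
restarts, convergence when the improvement drops below tol. This is the
same model STRUCTURE fits by MCMC; EM gives desk-scale deterministic
runs, and run-to-run variability for the ΔK diagnostic comes from the
restarts. Monotonicity of ℓ is asserted at every iteration. K = 1 has
the closed form q ≡ 1, f = observed frequencies.

**ΔK.** With L̄(K) the mean and s(K) the SD of the best-run
log-likelihoods over runs, ΔK(K) = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / s(K),
defined for interior K only; s = 0 is flagged undefined. Samples are
assigned to argmax_k q_ik when max q > 0.6 (strict), else "admixed" — so
planted admixed individuals are unassignable by construction.

## Differentiation and trees

Per-locus Weir–Cockerham components use group sizes n_i, allele
frequencies p_i and *observed* heterozygote frequencies h_i (no HWE
assumption):

  n̄ = Σn_i/r, n_c = (r·n̄ − Σn_i²/(r·n̄))/(r−1), p̄ = Σn_i p_i/(r·n̄),
  s² = Σn_i(p_i−p̄)²/((r−1)n̄), h̄ = Σn_i h_i/(r·n̄)
  a = (n̄/n_c)[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
  b = (n̄/(n̄−1))[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
  c = h̄/2.

Multi-locus θ is the ratio of sums Σa/Σ(a+b+c), never the mean of
per-locus ratios. Two equal groups fixed for alternative alleles give
a = 0.5, b = c = 0, θ = 1 exactly — the estimator's analytic upper
limit. Identical copied groups give a small *negative* θ of order
−1/(n−1) (the finite-sample correction), vanishing as n grows. The
one-vs-rest screen reports per-locus two-group θ for each cluster against
the pooled rest, unclamped (clamping would bias the null behaviour of the
distinctive-allele screen), with flags at θ > 0.8 and θ > 0.95 and the
direction of the frequency difference.

Nei's (1972) standard distance between clusters uses
D = −ln(J_XY/√(J_X J_Y)) from group allele frequencies over loci present
in both groups; disjoint allele sets give infinite distance, flagged.
The cluster tree is Saitou–Nei neighbor joining (negative branches
clamped to zero), with support from resampling loci with replacement
(the standard phylogenetic bootstrap over characters; the resampling unit
is a design choice recorded here): support = % of replicates containing
each internal bipartition of the full-data tree. Under a symmetric
island model the true cluster tree is a star, so internal supports are
legitimately low; the bootstrap test uses hierarchically simulated
frequencies where the planted split earns ≥ 95% support.

Individual relationships use the allele-sharing distance 1 − IBS with
Ward linkage in the Ward.D2 convention (variance criterion on squared
distances), serialized as a rooted dendrogram with merge-height branch
lengths.

## Phenotype statistics

Per trait, genotypic effects are tested by two-way additive ANOVA
(genotype + block) with Type-II sums of squares (exact decomposition on
balanced data, checked to 1e−9). Broad-sense heritability is on an
entry-mean basis, H² = σ²_g/(σ²_g + σ²_e/r) with σ²_g = (MS_G − MS_E)/r
clamped at 0 and r the number of blocks — the standard choice for
replicated germplasm trials. Cluster comparisons use genotype means
(averaged over blocks) as analysis units, matching cluster-level
mean ± SD summaries across accessions: one-way ANOVA plus Tukey–Kramer
studentized-range comparisons (unequal group sizes supported), singleton
clusters excluded with a warning. The compact letter display is built
greedily from the nonsignificant-pair graph with a final pass
guaranteeing every nonsignificant pair shares a letter and no significant
pair does; adjusted p-values agree with a label-permutation oracle of the
family-wise range test within Monte-Carlo error.

## Mixed-model association

The trait is the per-genotype mean over blocks. The model is
y = Xβ + u + e with u ~ N(0, σ²_g K) for the IBS similarity matrix K
(used as-is, no centering or rescaling — flag available) and
e ~ N(0, σ²_e I). K is symmetrized and jittered to PSD if needed
(logged). Variance components are estimated once per cofactor set by
profile REML over the ratio δ = σ²_e/σ²_g on the spectral decomposition
of K (grid + bounded scalar refinement over ln δ ∈ [−10, 10]); each
marker is then tested by generalized least squares with the fitted
covariance and a Wald t test whose residual variance is re-estimated per
marker — so with K = I the scan reduces *exactly* to ordinary least
squares (verified to 1e−8). Forward selection re-scans with the best
marker added as a fixed cofactor while its Benjamini–Hochberg q-value
stays below the FDR level (default 0.05), re-estimating variance
components each step; markers collinear with the cofactors are skipped.
Under a kinship-structured null the empirical size at α = 0.05 stays
within [0.03, 0.07] (500 markers × 20 seeds).

## Numerical and design choices

* Strict inequalities on every printed QC threshold; sample exclusion at
  call rate < 0.80.
* Redundancy comparison is inclusive (IBS ≥ threshold): boundary pairs
  are declared redundant, the conservative choice for deduplication.
* k-means BIC uses the WSS form above; other BIC conventions shift all
  values by a constant and do not change the argmin.
* EM admixture: tol is on the log-likelihood increment; the analysis
  drivers use tol = 1e−3 and max_iter = 300 per run, which reaches the
  likelihood plateau on panels of ~200 × ~3,000 and keeps the 7-K × 10-run
  sweep to minutes on one CPU; the library defaults are stricter
  (1e−4 / 2000).
* Nei distance implements the 1972 standard form; the 1978 unbiased
  variant is not implemented (config flag reserved).
* Stage seeds in the pipeline derive from one master seed via SHA-256, so
  multi-run procedures are mutually independent but reproducible;
  re-running with the same config and seed reproduces every output file
  bit-identically.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on generated data
at these scales, chosen to make each claim decisive while keeping the
whole suite desk-scale: cluster-number recovery on 5 × 40 samples ×
1,000 loci; F_ST consistency on 2 × 100 × 2,000 (10 seeds); duplicate
recovery on the default 192-accession panel at 800–1,000 loci (10
seeds); mixed-model calibration on 90 samples × 500 markers × 20 seeds;
NJ topology checks against exhaustive search at 4–6 taxa; ANOVA null
calibration at 25 genotypes × 60 seeds.

## Known limitations

* The admixture fit is a maximum-likelihood point estimate; no posterior
  uncertainty on q, and ΔK inherits the restart-spread convention rather
  than MCMC run spread.
* The EMMAX-style per-marker test holds variance components fixed at the
  null fit of the current cofactor set; for very large marker effects the
  exact per-marker REML would differ slightly.
* Greedy sequential LD pruning depends on locus order (earlier loci win
  ties), as documented; no windowed or MAF-aware variant.
* The compact letter display is greedy and may not be the minimal letter
  assignment, though it is always consistent with the pairwise table.
* Phenotype ANOVA assumes an additive genotype + block model; no
  genotype × environment interaction.
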