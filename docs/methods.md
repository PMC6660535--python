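# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `ricapanel`, in the spirit of the methods sections of
the established quantitative-genetics packages.

## Genotype representation

Diploid calls are unordered allele pairs stored canonically with alleles
in alphabetical order ("AG", never "GA"); missing is "NN".  Every
comparison (repeatability, concordance, F1 similarity) operates on
canonical calls, so platform call orientation can never create spurious
mismatches.  Dosage coding counts the alphabetically second allele of
each marker's declared pair (0/1/2, NaN for missing); the choice of
counted allele is arbitrary but fixed, and all dosage-based statistics
(MAF, PCA, kernels, LD) are invariant to it up to sign.

Positions are 1-based MSU7 coordinates.  The packaged chromosome lengths
are the twelve MSU7 Nipponbare pseudomolecule sizes, which sum to
373,245,519 bp.  Genetic distance is the linear transform
cM = bp / 244,000; no regional recombination variation is modelled
because no analysis in scope needs more than this genome-wide constant.

## Panel design

Candidate filtering keeps markers with reference call rate strictly
greater than the threshold and MAF greater than or equal to it (defaults
0.95 and 0.40) — the asymmetry mirrors the "> 95%, ≥ 0.4" convention of
published panel designs.  Gap filling is a documented greedy stand-in for
the (unpublished) vendor design loop: repeatedly find the largest
remaining physical gap, counting chromosome ends as gaps from position 1
and to the chromosome length, and add the pool candidate nearest the gap
midpoint, ties to the lower coordinate.  Each successful step cannot
increase the maximum gap, and the procedure is deterministic.

## QC statistics and filters

Per marker: call rate = called/total samples; heterozygosity = het calls
among called; MAF from called allele counts.  Filter boundaries are
inclusive exactly as conventionally printed: markers fail at MAF ≤ 0.01,
het ≥ 0.10, call rate ≤ 0.75.  A marker with zero called samples has
call rate 0, undefined MAF/het, and fails only the call-rate rule.

Repeatability follows the per-locus error-rate formulation
`e_l = m_l / n_l`: among accessions with ≥ 4 independent replicates, each
replicate call is compared with the accession's strict-majority consensus
(ties and all-missing loci give a missing reference).  Any allelic
mismatch between two non-missing calls counts toward `m_l` — a
heterozygote sharing one allele with a homozygous reference is still a
mismatch.  Missing calls reduce `n_l` rather than counting as errors,
consistent with call rate being accounted separately.  `R = 100 (1 −
mean_l e_l)`.  The `drop_hets` mode blanks heterozygous replicate calls
before consensus and comparison, the analysis typically applied to inbred
material where residual hets are mostly miscalls.

Concordance intersects two platforms' markers by (chrom, pos) and counts
exact canonical-call matches over pairs called on both sides.  When the
declared allele pairs differ, the second platform is complemented; if
that reconciles the pairs the marker is compared on the complemented
calls (opposite-strand reporting), otherwise it is flagged and excluded —
which automatically excludes all strand-ambiguous A/T and C/G
disagreements, where strand cannot be determined from the alleles.

## LD-kNN imputation

For a missing call at (sample s, marker j): the 30 markers with the
highest r² to j (squared Pearson correlation of dosages over
pairwise-complete observations) define the context; the distance from s
to every other sample is the mean absolute dosage difference over those
sites, skipping missing pairs and excluding samples sharing no observed
site; the imputed dosage is the weighted mean of the 30 nearest
neighbours called at j with weights 1/(d + 1e−6), rounded to {0, 1, 2}.
An exact rounding tie takes the single nearest neighbour's genotype.
Non-missing calls are never altered, and unfillable calls stay missing.
The pairwise-complete r² is computed with masked cross-products, so no
per-pair Python loops are involved.

## Trait markers

The packaged definition table encodes 21 diagnostic SNPs across 11
genes/QTLs, each used either as a single SNP or as an ordered haplotype.
In haplotype mode a sample with missing or heterozygous components is
classified only if every completion of the haplotype maps to the same
class ("forced completion").  The *Wx* amylose haplotype table encodes
both published spellings of the high-amylose class (G-A-C and G-A-T);
the source references disagree and both triplets are valid under the
marker alleles, so both map to "high".

Utility excludes indeterminate calls from numerator and denominator (it
measures pool composition); FPR and FNR keep them in the totals (a marker
that cannot classify a known donor or recipient has failed on that
sample).  In single-SNP mode a heterozygote carrying the favorable allele
is reported as a carrier with a separate het flag — the dominant-reporting
convention relevant to breeding use; the assayed material is essentially
inbred, so the choice rarely matters.

## Mixed models and heritability

The plot model is `Y_ijk = μ + g_i + t_j + r(t)_jk + e_ijk`.  BLUEs use
cell-means fixed genotype coding with random trial and
replicate-within-trial effects; BLUPs make genotype random as well.
Variance components come from EM-REML on Henderson's mixed-model
equations: tolerance 1e−6 on the maximum relative component change, cap
2000 iterations.  Components that fall below 1e−3 × var(y) are pinned to
a floor near zero and removed from the convergence test; EM approaches a
zero boundary only at O(1/k), and without pinning the fit would spend
hundreds of iterations confirming a component that is already negligible.
Broad-sense heritability of accession means uses
`H² = σ²_g / (σ²_g + σ²_gy/t + σ²_e/(t r))` with t the mean number of
trials per accession and r the mean plots per accession per trial.  The
plot model carries no genotype-by-trial term, so σ²_gy defaults to 0 in
the formula; the discrepancy between the stated model and the formula is
surfaced in the API rather than hidden.

## Genomic prediction

The genomic relationship matrix is the VanRaden form
`G = W W′ / (2 Σ p_j (1 − p_j))` on column-centered dosages with observed
alternate-allele frequencies.  Fully inbred material has mean diagonal
near 2 (1 + F with F ≈ 1); outbred Hardy–Weinberg genotypes give mean
diagonal near 1.  The pedigree A matrix uses the tabular method on a
topologically sorted pedigree.

Ridge/GBLUP fits `y = 1μ + u + e`, `u ~ N(0, G σ²_u)` by REML: the
training kernel is eigendecomposed once and the restricted likelihood is
maximized over log λ (λ = σ²_u/σ²_e) by bounded scalar optimization on
[−12, 12] to 1e−8.  Candidates outside the training set get
`û = λ G[·, train] V⁻¹ (y − μ̂)` through the kernel cross-block.

The Bayesian alphabet uses single-site Gibbs sampling with a
numba-compiled sweep; all random draws are pre-generated from one NumPy
generator, so chains are exactly reproducible from the seed.  BayesA
places a scaled-inverse-χ² variance on every marker (df 5, scale set so
the prior explains R² = 0.5 of the phenotypic variance); BayesB combines
the per-marker variances with a point mass at zero; BayesC uses one
shared slab variance with a point mass; the Bayesian lasso gives each
effect an exponential-mixing normal with the penalty updated by its gamma
conditional.  The mixture inclusion probability π has a uniform Beta
prior and is sampled each sweep.  The residual-variance trace of the
thinned chain is kept on the result object and exportable to a plain-text
file for convergence inspection.  Default chain settings are 12,000
iterations, 2,000 burn-in, thinning 5; cross-validation uses a reduced
800/300/5 chain, which moves posterior-mean GEBVs by much less than the
fold-resampling noise.

The RKHS G+A model samples two random effects with covariances
proportional to G and A in each kernel's eigenbasis (eigenvalues below
1e−8 of the maximum dropped), giving diagonal full conditionals;
predictions extend to unphenotyped samples through each kernel's
cross-block.  Pedigree BLUP is the single-kernel ridge fit with A.

Adjusted phenotypes (BLUEs) enter cross-validation computed once from all
plots, the standard workflow for stage-wise analysis; a caller wanting
fold-safe adjustment can refit the plot model inside the `fit_predict`
closure, at the cost of re-running REML per fold.

Stratified cross-validation shuffles members within each family and deals
them round-robin to folds, rotating the dealing start across families so
fold sizes stay within one family-count of each other.  Predictive
ability pools the validation folds within a repeat (one Pearson
correlation per repeat, the convention of the breeding literature) and
averages over repeats; per-fold averaging is available but off by
default.

## Synthetic data: what it emulates and what it does not

Inbred lines are homozygous draws from subpopulation allele frequencies
generated by the Balding–Nichols model: each subpopulation frequency is
Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency p with
divergence F.  The default F = 0.4 reflects the deep *indica*/*japonica*
split; panel ancestral MAFs are uniform on [0.2, 0.5] (median 0.35,
quartiles ≈ 0.28/0.43), the spectrum a high-MAF *indica*-ascertained
assay targets.  Noise defaults: residual heterozygous-miscall rate 0.007
(the share of calls that are het miscalls in inbred material), per-call
missingness 0.05 at the matrix level or a per-marker profile in the
canonical scenarios (healthy markers 0.5–6% missing; deliberately failed
markers 30–95% to emulate assay dropouts), and a 1% per-locus error
between independent genotyping runs.

Markers are simulated in linkage equilibrium — per-marker statistics
(QC, MAF, polymorphism counts, kernels) do not need LD — except for a
correlated-blocks option (consecutive markers copy a latent block
haplotype with fidelity 0.95, within-block r² ≈ 0.8) used to exercise
LD-kNN imputation.  Crosses and RILs segregate markers independently
(no recombination map); downstream statistics in scope are per-marker,
so linkage would only add variance, not bias.  Consequences: simulated
panels cannot show realistic LD decay, haplotype blocks, or
ascertainment geometry, and PCA variance fractions on synthetic mixtures
reflect the chosen F, not the (stronger, ascertainment-amplified)
structure of the real germplasm — passing tests demonstrate the
correctness of the computations and the qualitative structure
(separation, rankings, error-rate recovery), not the exact variance
decomposition of any particular real panel.

The breeding-program generator crosses founder pairs from one elite pool
into 30 bi-parental families (sizes ~Poisson(12) clipped to [1, 36],
totalling 353 lines), assigns additive effects to 200 random markers,
standardizes true breeding values to unit variance, and generates plots
for 3 trials at replication 1.2 (a p-rep layout: a random 20% of lines
get a second plot per trial).  The plot residual variance is derived
from the target accession-mean heritability (default 0.85,
flowering-time-like) given the trial structure, so the simulated
components are consistent with H² by construction.

## Problem sizes and runtime

The acceptance script runs the full workflow at the canonical sizes
(995 markers; 431/283/353-line panels; 57 F1s; 38 replicated accessions;
5-fold × 10-repeat CV over seven models) in under two minutes on one CPU
with the reduced Gibbs chains.  The test suite uses 200–300-marker panels
for unit-level checks and the full canonical scenarios in the
end-to-end tests.

## Known limitations

- The gap-filling rule is a documented stand-in; real amplicon design
  also scores primer compatibility, which is out of scope.
- EM-REML with few trial levels identifies the trial and
  replicate-within-trial components weakly (they can legitimately
  collapse to a boundary); genotype and residual components, which drive
  BLUEs and H², are well identified.
- The Bayesian samplers implement the standard conjugate hyperpriors
  (df 5, R² = 0.5 scale rule); they do not reproduce every refinement of
  the reference samplers' adaptive defaults.
- `classify_undetermined` is a two-group nearest-centroid rule in PC
  space, not a model-based ancestry estimate.
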