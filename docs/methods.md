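# Methods

`xqtl` implements an integrative proteogenomic analysis chain for brain-style
cohorts: isobaric (TMT) protein quantification, hidden-factor correction of
molecular phenotypes, cis/trans QTL mapping with permutation-calibrated
significance, Bayesian colocalization of eQTL and pQTL signals,
transcript-mediation classification of pQTLs, summary-based Mendelian
randomization (SMR) with the HEIDI linkage test against GWAS summaries, and
order-statistics aggregation of evidence for candidate-gene prioritization.
All stages run against a synthetic-data generator whose ground truth makes
every claim testable offline; this note records the models, the defaults and
why, and the numerical choices where the design was genuinely open.

## Synthetic cohort generator

**Genotypes.** Variants are grouped into LD blocks, one block per synthetic
chromosome, with `variant_spacing` (default 10 kb) between adjacent sites.
Within a block, 2n latent haplotype values follow an AR(1) Gaussian process
with correlation `ld_rho`; thresholding each latent value at the normal
quantile of the variant's population allele frequency gives an allele, and
the two haplotypes sum to a dosage in {0, 1, 2}. HWE holds by construction
(independent haplotypes), cross-block LD is exactly zero, and the realized
dosage LD is *lower* than `ld_rho` because dichotomization attenuates the
latent correlation. Population frequencies can be fixed across draws so that
two cohorts (QTL and GWAS) share a panel — without that, cohort-specific
frequencies manufacture LD heterogeneity that contaminates every two-sample
analysis downstream.

**Molecular traits.** One gene per block; the causal cis variant is the
block's middle variant, with the TSS placed at its position. mRNA is
`beta * standardized dosage + loadings @ hidden_factors + noise`. Defaults
mirror the cohort the pipeline models: n = 268 samples, standardized cis
effect `cis_effect_beta = 0.5` (the large-effect regime), 5 hidden factors,
unit noise. A `mediation_fraction` (default 0.79) of genes are
*transcript-dependent*: protein = `mediation_slope * mRNA + noise`
(default slope 0.8). The rest are *transcript-independent*: protein carries
a direct SNP effect (1.5x the cis effect — direct protein effects that
survive without transcript support tend to be larger) and its paired mRNA
carries **no** cis effect by default (`independent_mrna_beta = 0`). The
latter mirrors the empirical signature of transcript-independent regulation
— a pQTL with no eQTL support and low mRNA-protein correlation — and it is
also what makes the mediation null well-defined: if the tested mRNA itself
carries the SNP signal, conditioning on it always absorbs part of the pQTL
effect and no permutation scheme can be calibrated around that.

**GWAS summaries.** A phenotype is built in an independently drawn cohort on
the same variant panel (two-sample setting; same-cohort reuse is a flag):
under *causality* from the target gene's resimulated mRNA scaled by
`effect_ratio` (default 0.3, so the SMR ratio targets 0.3); under
*pleiotropy* directly from the causal variant; under *linkage* from an LD
partner a configurable number of variants away; under *null* from pure
noise. Marginal per-variant regressions give b/se/z/p in GCTA `.ma` layout.

**PSM tables.** Each batch carries 10 distinct sample channels plus one
internal standard equal to the mean of the 10 (pooled-reference design).
PSM intensity = protein truth x channel loading x lognormal noise, mixed
through the label impurity matrix. A configurable fraction of PSMs is scaled
below the intensity filters; missingness is missing-at-random per PSM
(the quantification chain filters rather than imputes).

## TMT quantification

Impurity correction solves `M t = observed` per PSM and clips negative
solutions at zero. PSM filtering requires per-channel minimum >= 1000 and
median >= 5000, both inclusive (the thresholds are quoted without
strictness; inclusive chosen). Channel normalization equalizes per-channel
*trimmed medians* within a batch: PSMs in the top and bottom
`trim_fraction = 0.1` by overall (row-mean) intensity are dropped, each
channel's median over the rest is scaled to the batch grand median (median
of the per-channel values), and — because rescaling moves the trim set —
the scaling is iterated to a fixed point (tolerance 1e-12, converges in a
few passes), which leaves post-normalization trimmed medians equal to
numerical precision. Summarization computes per-PSM relative intensities
(channel / row mean), averages them per protein on the linear scale, and
anchors the absolute level at the grand mean of the protein's three most
intense PSMs (all PSMs when fewer than three); output is log2. Batch
bridging subtracts the internal-standard channel in log2 space and
concatenates batches over the union of proteins.

Median normalization assumes the per-channel median of *true* sample
effects is ~0; that holds at the hundreds-to-thousands of proteins of a real
experiment but not at a handful, so exact round-trip tests bypass
normalization while statistical round-trips use realistic protein counts.

## Factor correction

Hidden confounders are estimated as leading principal components of the
per-trait centered/scaled matrix (missing values mean-imputed for the SVD
only). `n_factors="auto"` takes the smallest K reaching 99% cumulative
explained variance; fixed K mirrors common practice (e.g. 13 for a proteome,
30 for a transcriptome at these scales). Residualization fits per-trait OLS
against [intercept | known covariates | factors], dropping collinear columns
with a warning. The inverse-normal transform maps value to
`Phi^-1((rank - 0.5)/n)` with ties averaged. Re-applying the chain with the
same factors is a near no-op, not an exact one: the rank transform
reintroduces a small projection onto the factors, so adjacent ranks of
nearly-equal values may swap; the suite asserts near-idempotence (mean
absolute change < 0.02, per-trait Spearman > 0.995).

## QTL mapping

Cis windows are TSS +/- 1 Mb, strand-agnostic; trans candidates lie >= 5 Mb
outside the gene body or on another chromosome (gene start/end approximate
exon boundaries — a conservative superset). Per variant the scan is simple
linear regression on dosage with a t-test on n-2 dof; covariates are removed
upstream. Per trait, the multiplicity over the window is calibrated by
permuting sample labels R times (default 10,000), recording each
permutation's minimum nominal p, and fitting Beta(a, b) to those minima by
maximum likelihood; `adjusted_p` is the fitted Beta CDF at the observed
minimum, with `(1 + #{perm <= obs})/(R + 1)` kept alongside as the direct
estimate and used as fallback if the MLE fails. Each trait draws its own
permutation stream seeded by (global seed, trait index). The top variant is
the argmin of nominal p; ties break by smaller |TSS distance|, then lexical
variant id. The reported `beta` is oriented to the reference allele
(positive = higher expression with the reference allele); `slope` is the raw
ALT-dosage slope.

Genome-wide FDR uses Storey q-values: pi0(lambda) on the grid 0.05..0.95
(step 0.05), a cubic polynomial in lambda extrapolated to lambda = 1 and
clipped to (0, 1]; below 100 p-values pi0 is fixed at 1, making the
procedure exactly Benjamini-Hochberg. The trans threshold is Bonferroni,
alpha / (n_variants x n_traits).

## Colocalization

Per variant, the Wakefield log approximate Bayes factor is
`0.5 [log(V/(V+W)) + z^2 W/(V+W)]` with V = se^2 and prior effect variance
W = 0.15^2 (standardized quantitative traits; configurable). Hypothesis
evidence sums over single-causal-variant configurations in log space, with
priors p1 = p2 = 1e-4 and p12 = 1e-5 (the conventional defaults; unstated
in the source analysis). Where se is unavailable it is reconstructed as
`1/sqrt(2 n maf (1-maf))`. The default call threshold is PP4 > 0.8 with
0.5 available by flag. Note that adding a constant to one trait's log ABFs
is *not* posterior-invariant (it rescales the H1/H3/H4 evidence against
H0/H2); what is invariant — and tested — is the relative posterior among
the hypotheses containing that trait's causal configurations.

## Mediation

For a colocalized pGene, the variant's effect on protein is re-estimated
with the gene's mRNA as a covariate (t-test, n-3 dof). The drop statistic is
x = -log10(conditional p); its null is built by permuting only the mRNA
covariate's sample labels (1000 permutations), which preserves the
SNP-protein association under no-mediation, and z = (x_obs - mean)/sd of
the permuted statistics. Dependence is called at z <= -4.26, the one-sided
normal quantile at p = 1e-5 (0.01 Bonferroni-corrected over the 1000
tests); a moment-based z is the only reading consistent with that cutoff,
since an empirical p of 1e-5 is unreachable from 1000 permutations.
Degenerate nulls (sd = 0) yield a flagged independent call. The test is
invariant to affine rescaling of the mRNA covariate.

## SMR and HEIDI

The instrument is the trait's top QTL variant; `b_xy = b_GWAS / b_QTL`, and
`T_SMR = z_QTL^2 z_GWAS^2 / (z_QTL^2 + z_GWAS^2)` is referred to
chi-square(1). HEIDI candidates need QTL p < 1.57e-3 (|z| > 3.16, the cited
method's convention) and LD r^2 with the instrument in [0.05, 0.9], capped
at 20 by QTL significance; fewer than 3 partners leaves P_HEIDI undefined
and the trait excluded from verdicts. The heterogeneity statistic sums
squared standardized differences d_i = b_xy(i) - b_xy(top), with the null of
the correlated sum approximated by a Satterthwaite-scaled chi-square matched
to the eigenvalues of the d-correlation matrix (the exact Davies tail is
unnecessary at these scales).

The covariance of d is delta-method, with three refinements that matter at
moderate instrument strength and were each traced to measured
miscalibration under the shared-causal-variant generator: (i) second-order
ratio moments — the GWAS-error variance term carries a (1 + 3/z_QTL^2)
factor; (ii) the E[1/x] ratio bias — each b_xy is divided by
(1 + 1/z_QTL^2) before differencing; (iii) two-sample LD mismatch — both
cohorts' marginal effects track their own empirical LD, adding variance
~ b_xy^2 (1-r^2)^2 (1/n_QTL + 1/n_GWAS)/r^2 per partner, correlated across
neighboring partners (error correlation approximated by their LD). With
these, the false-rejection rate under a shared causal variant measures
0.06-0.09 across independent simulation streams (nominal 0.05), and
linkage scenarios are rejected ~80% of the time at the default desk-scale
conditions. Those conditions — QTL cohort n = 800, GWAS cohort n = 3000,
`ld_rho = 0.9`, effect ratio 0.3 — are the regime in which at least three
eligible HEIDI partners exist; at `ld_rho = 0.6` the dichotomized dosage LD
falls below the r^2 >= 0.05 band and HEIDI is undefined by design.

Verdicts: P_HEIDI < 0.05 means linkage regardless of P_SMR; otherwise
causal-or-pleiotropic requires P_SMR below alpha divided by the number of
tested traits (Bonferroni default; FDR mode available).

## Prioritization

Each gene's ranks across up to five evidence sources (pQTL p, eQTL p,
colocalization PP4, disease-relevance score, PPI connectivity to known risk
genes) become rank ratios r_i/n_i, and the aggregate score is the joint
order-statistic tail probability computed by the recursion
`V_0 = 1, V_i = sum_j (-1)^(j-1) V_{i-j} q_{i-j+1}^j / j!, Q = k! V_k`
over the gene's k *available* sources (missing sources shrink k; comparing
Q across different k is accepted because each Q is a joint tail
probability — a documented caveat). Ties in source scores get average
ranks; final ties break by more sources available, then gene id. The PPI
network keeps edges with combined score >= 700, restricted to eligible
(pGene/eGene) nodes; connectivity is the count of distinct risk-gene
neighbors. Top candidates map to GWAS loci by TSS containment, with tiers
significant (p < 5e-8) and suggestive (5e-8 < p < 1e-6).

## Pipeline driver and problem sizes

`run_pipeline` executes simulate -> quantify -> correct -> map -> coloc ->
mediate -> smr -> prioritize, writing every intermediate as a file
(dosage TSV / VCF-DS, QTLtools-style BED, GCTA `.ma`, TSV tables) plus a
JSON manifest of parameters, output checksums, and elapsed times; stages
re-read the files earlier stages wrote, a failure skips downstream stages,
and a fixed seed makes result tables byte-identical across reruns.
Coordinates are 1-based inclusive internally; BED conversion happens at the
I/O boundary. The two externally-supplied prioritization sources
(disease-relevance scores, risk-gene PPI edges) are generated as labelled
synthetic stand-ins in the demo pipeline.

Default verification sizes keep the whole suite and the acceptance script
in the tens of seconds on one core while leaving Monte-Carlo error well
inside each asserted band: 500 null traits at 1000 permutations for type-I
error, 10,000 permutations where the beta-approximation is compared with
the direct empirical p, 200-500 replicates for mediation and HEIDI
calibration, and 100 replicates for the recovery operating points.

## What passing tests do and do not show

The generator reproduces the statistical structure the methods assume —
block LD, HWE, hidden factors, transcript-mediated vs direct protein
regulation, two-sample GWAS under causality/pleiotropy/linkage, multiplexed
PSM noise — but not real-data pathologies: no population structure or
relatedness, no recombination-map LD, no imputation error, no
non-Gaussian trait tails beyond what the lognormal PSM model induces, no
shared samples between QTL and GWAS cohorts, and annotation classes are
metadata rather than functional consequences. Passing therefore shows the
statistics are implemented correctly and calibrated under their own
assumptions, not that those assumptions hold in any particular cohort.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multi-signal
decomposition); no conditional multi-signal QTL mapping; no mixed-model
relatedness correction; HEIDI requires reasonably strong instruments and
dense LD to be defined at all; the mediation test classifies but does not
decompose effects (no ACME/ADE); Q-scores across genes with different
source coverage are comparable only in the tail-probability sense noted
above.
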