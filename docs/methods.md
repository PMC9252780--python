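# Methods

This note documents the statistical models implemented in `pcphewas`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Gene regions and variant selection

Gene coordinates follow the Ensembl convention (1-based, inclusive).  Only
protein-coding and lincRNA biotypes are analyzed; other biotypes are
skipped with a logged count.  Protein-coding genes are padded by 1.5 kb
upstream and 1 kb downstream of the annotated boundaries before variant
extraction; lincRNA genes are used unpadded.  "Upstream" is interpreted
strand-aware (the 5′, transcription-start side), which is the standard
genomic reading of the term; the padded start is clamped at position 1.
Both choices are this package's own conventions where the underlying
procedure is underdetermined — they affect at most a handful of boundary
variants per gene.

Variant inclusion thresholds: MAF ≥ 0.01 and imputation info ≥ 0.6, both
inclusive.  Variants and samples with more than 2% missing dosages are
excluded (strictly greater-than).  The filters are applied in a fixed order
(info → MAF → missingness) purely for reproducible log output; the result
is order-invariant.  MAF and missingness are by default recomputed on the
analysis samples; externally supplied metadata can be used instead.

Relatedness is handled by pruning: in the graph of sample pairs with
kinship coefficient ≥ 0.0884 (the conventional third-degree cutoff), the
highest-degree node is removed repeatedly — ties broken by a seeded random
draw — until no edge remains.  Degree-peeling retains at least as many
samples as removing one member of each pair independently, and is
deterministic under a seed.

## Gene PCA

The per-gene dosage matrix is mean-imputed per variant (missing entries
replaced by the variant mean) and column-centered, but not variance-scaled
— scaling would up-weight rare variants relative to their dosage variance,
and centering-only matches the default behaviour of mainstream PCA
implementations on which this representation is modelled.  A deterministic
full SVD is used: gene regions are small (tens to a few hundred variants),
so reproducibility is worth more than the speed of randomized solvers; the
`seed` argument is accepted for interface stability only.

The number of retained components k is the smallest integer whose
cumulative explained-variance ratio reaches the retention target (default
0.95, exposed as a configuration knob; a stricter 0.99 makes little
difference to association tests, which is why the default is the cheaper
one).  A small numerical tolerance (1e−12) guards the ≥ comparison against
floating-point round-off at the boundary.  Trailing singular values below
1e−9 of the leading one are treated as rank deficiency.  Each loading
column is oriented so that its largest-magnitude entry is positive, making
serialized PCs bit-stable across runs and platforms.

## Association tests

Both tests compare nested models: null = covariates (+ intercept), full =
null + the k PC scores, on the complete cases of each phenotype (samples
missing the outcome, a covariate or a score are dropped per phenotype; the
missing-data policy is a package choice).

* Continuous outcomes: ordinary least squares for both models, and

      F = ((RSS₁ − RSS₂)/(|P₂| − |P₁|)) / (RSS₂/(n − |P₂|)),

  referred to F(k, n − |P₂|).  Parameter counts include the intercept, so
  the numerator degrees of freedom equal k exactly.  RSS₂ is clipped at
  RSS₁ to absorb round-off on null data, and RSS₂ = 0 (a saturated/perfect
  fit) yields F = ∞ with p reported as the smallest positive float.
* Binary outcomes: logistic regressions fitted by iteratively reweighted
  least squares (at most 25 iterations, relative deviance tolerance 1e−8);
  the statistic is the deviance difference, referred to χ²_k.  A fit is
  flagged non-converged — statistic retained, p set missing — when IRLS
  fails to converge, when any coefficient exceeds 30 on the logit scale, or
  when the fitter detects perfect separation.  Flagging rather than raising
  keeps a multi-phenotype scan running.
* Binary phenotypes with fewer than 50 cases (configurable) are skipped:
  below that, the χ² reference distribution is unreliable.

Sex-stratified scans drop the sex covariate and filter samples on a
user-supplied genetic-sex column; the package does not infer sex.

The null model could be shared across genes per phenotype as an
optimization; it is simply refitted, since results are identical and gene
counts at desk scale are small.

## Multiplicity control

Storey q-values: π₀ is estimated by evaluating a cubic polynomial fit of
π₀(λ) = #{p > λ}/(m(1 − λ)) over the grid λ = 0.05, 0.10, …, 0.95 at
λ = 0.95, clipped to (1/m, 1]; q-values are the step-up transform
q_(i) = min_{j ≥ i} π₀ m p_(j)/j, clipped to (0, 1].  With π₀ fixed at 1
the procedure reduces exactly to Benjamini–Hochberg, which serves as an
independent oracle in the tests.  Correction can be applied per gene
(across phenotypes) or per phenotype (across genes), mirroring the two ways
results are browsed.

The inflation factor λ is computed on 1-df χ² transforms of the p-values —
median observed over the null median (≈ 0.4549) — rather than on the raw F
or χ²_k statistics, because k varies between genes and the 1-df transform
puts all tests on a common scale.  QQ coordinates use the (i − 0.5)/m
expected-quantile convention.

## cis-Mendelian randomization

Per-PC effects on the exposure and the outcome come from marginal
covariate-adjusted regressions (one PC at a time).  This is justified
because PC scores are exactly orthogonal on the estimation sample;
covariate adjustment can break orthogonality slightly, which is accepted as
an approximation consistent with summary-statistic IVW practice.  Covariate
adjustment in these regressions is itself a package choice.

PCs with exposure p > 0.05 are excluded (relevance filter; the boundary
p = 0.05 is kept).  The IVW estimate combines the rest with weights
1/se(β̂_Yk)²; its standard error uses the fixed-effect formula
(Σ β̂_Xk² se(β̂_Yk)⁻²)^(−1/2) and the p-value the two-sided normal tail.
First-stage uncertainty (se(β̂_Xk)) is deliberately ignored — the estimator
is the plain IVW, with no weak-instrument (NOME) correction.  Exposure and
outcome are estimated on the same samples (one-sample MR) with no overlap
correction; with weak instruments this biases the estimate toward the
observational association.  Both limitations are inherent to the estimator
implemented, not implementation shortcuts.

## ATC enrichment

The gene → ATC mapping is expanded to all prefix levels (1, 3, 4, 5, 7
characters), each node's gene set being the union over its subtree.  The
2×2 table for a node counts genes by (associated at q ≤ 0.05) ×
(in the node's gene set), over a universe defaulting to all genes tested
for the phenotype; genes absent from the mapping count as out-of-class.
The test is one-sided (greater), since enrichment — not depletion — is the
question; a two-sided option exists.  Each node also reports the minimum p
over its subtree (post-order propagation), the quantity a tree
visualization colours by.  External ontology enrichment (GO/KEGG/HPO) is
supported only as an adapter that emits the significant-gene list when at
least five genes qualify; no remote calls are made.

## Synthetic data

Haplotypes are thresholded stationary Gaussian AR(1) processes: adjacent
variants share latent correlation ρ, and allele indicators are obtained by
cutting at the allele-frequency quantile.  Dosage is the sum of two
independent haplotypes.  This yields blocky, tunable LD with a single knob
and exact seed-reproducibility — which is what the association and MR
machinery needs — but it is not population-genetic realism: no
recombination maps, no demography, no allele-frequency spectrum, no
genotyping-error model.  Passing tests therefore demonstrate statistical
correctness of the estimators under LD-structured genotypes, not
performance on any particular cohort.

Imputation noise is emulated by shrinking dosages toward their expectation
2·maf by a per-variant factor; the synthetic info score is the ratio of
empirical dosage variance to the binomial expectation 2·maf(1 − maf), a
monotone analogue of release-metadata info scores, which is all the
threshold filter needs.  Phenotypes are linear in a random causal subset of
variants with noise scaled to a target heritability; binary phenotypes
threshold the liability at the (1 − prevalence) quantile.  MR scenarios
chain variants → exposure (first-stage variance share `first_stage_h2`) →
outcome (effect `causal_beta`), with an optional direct variant → outcome
path (`pleiotropy`) for exclusion-restriction violation studies.  Default
generator settings (MAF uniform on [0.01, 0.5], heritabilities of a few
percent to tens of percent, prevalence 0.1) are in the range typical of
complex-trait loci.

## Problem sizes in the test suite

The statistical suites run at sizes chosen to make their Monte-Carlo
margins meaningful while keeping the suite quick on one CPU: FDR
calibration uses 200 replicates of 2000 p-values; type-I calibration uses
1000 replicates at n = 400 with 2 PCs (99% binomial CI of the 5% rejection
rate); MR recovery uses 200 replicates at n = 5000 with 3 independent
strong instruments; λ calibration uses 10⁵ uniform p-values (tolerance
0.02).  The PC retention check runs one seeded gene at n = 2000, m = 50,
ρ = 0.6.

## Known limitations

* One-sample MR without overlap or weak-instrument correction (above).
* λ on heterogeneous-df scans is a comparability device, not a test.
* The kinship pruner optimizes greedily; it is not guaranteed to find the
  maximum independent set on adversarial graphs (it does on paths and on
  the small graphs checked against brute force).
* Phenotype coding, ancestry inference and BGEN input are out of scope;
  the package consumes pre-coded phenotypes and VCF/TSV dosages.
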