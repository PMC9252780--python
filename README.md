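# pcphewas

Gene-based phenome-wide association scans (PheWAS) built on per-gene
genotype principal components, with q-value false-discovery-rate control,
cis-Mendelian randomization using the gene's PCs as instruments, and
drug-target enrichment over the hierarchical ATC drug classification.

The package is for statistical geneticists and pharmaco-epidemiologists who
want gene-level (rather than single-variant) association results: a compact
summary of the common genetic variation at each locus, tested against many
phenotypes at once, with the downstream tooling — multiplicity control,
causal-effect estimation for drug-target validation, and drug-class
enrichment — built in.  A synthetic-data module generates LD-structured
genotypes, phenotypes and MR scenarios with known ground truth, so the whole
pipeline is testable without access to controlled biobank data.

## The method

**Gene PCs.** For each gene, common imputed variants (MAF ≥ 1%, imputation
info ≥ 0.6) in the padded gene region (protein-coding genes get 1.5 kb
upstream and 1 kb downstream padding, strand-aware; lincRNA genes are used
as annotated) form a dosage matrix `G` (n samples × m variants, entries in
[0, 2]).  After mean-imputation of missing dosages and column centering,
the PCA of `G` is truncated to the smallest k whose cumulative
explained-variance ratio reaches 95%.  The n × k score matrix `Z` is the
gene's compact genotype representation.

**Association test.** For a continuous phenotype `y`, compare the null
model `y ~ covariates` with the full model `y ~ covariates + Z` by

    F = ((RSS₁ − RSS₂) / (|P₂| − |P₁|)) / (RSS₂ / (n − |P₂|)),

which under the null follows an F distribution with
(|P₂| − |P₁|, n − |P₂|) = (k, n − |P₂|) degrees of freedom.  For a binary
phenotype the analogous nested logistic models are compared by analysis of
deviance: D₁ − D₂ ~ χ²_k (a likelihood-ratio test).

**Multiplicity.** Scan p-values are corrected along either browsing axis
(per gene across phenotypes, or per phenotype across genes) with Storey
q-values (π₀ estimated by the cubic smoother; calling q ≤ 0.05 bounds the
expected false-discovery proportion by 5%), plus Bonferroni.  Per-gene
inflation is summarized by λ — the median of the 1-df χ² transforms of the
p-values over its null expectation (≈ 0.455) — and QQ-plot coordinates.

**cis-MR.** With a gene's PCs as instruments, per-PC covariate-adjusted
regressions give effects on an exposure (β̂_Xk) and an outcome (β̂_Yk,
log-odds for binary outcomes).  PCs not associated with the exposure
(P > 0.05) are removed (relevance assumption), and the rest are combined by
the inverse-variance-weighted estimator

    β̂_IVW = Σₖ β̂_Xk β̂_Yk se(β̂_Yk)⁻² / Σₖ β̂_Xk² se(β̂_Yk)⁻²,

with se = (Σₖ β̂_Xk² se(β̂_Yk)⁻²)^(−1/2) (fixed-effect weighting).

**Enrichment.** Genes associated with a phenotype at q ≤ 0.05 are tested
for over-representation among the gene sets of each node of the five-level
ATC drug hierarchy with a one-sided Fisher exact test; each node also
reports the minimum p over its subtree.

## Worked example

```python
from pcphewas import (SimulationConfig, simulate_genotypes, simulate_phenotype,
                      compute_gene_pcs, GeneAssociation, run_cis_mr,
                      simulate_mr_scenario)

cfg = SimulationConfig(seed=7, n_samples=2000, n_variants=25, ld_rho=0.6,
                       heritability=0.02)
dm = simulate_genotypes(cfg)                       # LD-structured dosages
pcs = compute_gene_pcs(dm, variance_retained=0.95, gene_id="GENE1")
print(f"retained k={pcs.k} PCs, cumulative EVR={pcs.cumulative_variance:.3f}")

pheno, cov, truth = simulate_phenotype(dm, cfg, "continuous")
res = GeneAssociation.from_gene_pcs(pcs, pheno, cov).fit()
print(res.summary())
```

```
retained k=20 PCs, cumulative EVR=0.956
Gene-based association: GENE1 ~ sim_continuous [combined]
  test        : f_test
  F           : 3.09944  (df = (20, 1977))
  n           : 2000   PCs: 20
  p-value     : 4.451e-06
  converged   : True
```

The 25 variants (adjacent-variant LD ρ = 0.6) compress into 20 PCs holding
95.6% of the dosage variance; the planted 2%-heritability signal is
detected at p ≈ 4 × 10⁻⁶ on 20 and 1977 degrees of freedom.

```python
scen = simulate_mr_scenario(SimulationConfig(seed=11, n_samples=5000,
                                             n_variants=3, ld_rho=0.0,
                                             first_stage_h2=0.2,
                                             causal_beta=0.5))
mr_pcs = compute_gene_pcs(scen.dosages, gene_id="GENE1")
print(run_cis_mr(mr_pcs, scen.exposure, scen.outcome, scen.covariates).summary())
```

```
cis-MR (IVW): exposure -> outcome via GENE1 PCs
  beta_IVW    : 0.447221  (se 0.03575)
  95% CI      : [0.377146, 0.517295]
  p-value     : 6.694e-36
  instruments : 3/3 (excluded PCs: [])
  gene-exposure association p: 2.943e-234
```

The IVW estimate's 95% confidence interval covers the simulated causal
effect of 0.5; all three PCs pass the relevance filter.

The same pipeline is scriptable from the shell:

```sh
pcphewas simulate --seed 11 --out data/ --n-samples 600
pcphewas phewas --dosages data/dosages.tsv --meta data/variants.tsv \
    --phenotypes data/phenotypes.tsv --covariates data/covariates.tsv \
    --kinship data/kinship.tsv --gene-id GENE1 --seed 11 --out results/
pcphewas mr --dosages data/dosages.tsv --meta data/variants.tsv \
    --phenotypes data/phenotypes.tsv --covariates data/covariates.tsv \
    --gene-id GENE1 --exposure quantitative_trait --outcome disease_status \
    --out results/mr/
pcphewas qq --results results/associations.tsv --gene GENE1 --out gene1.json
```

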