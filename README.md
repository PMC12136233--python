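# gxeqtl

Discovery of **standard**, **response** (treatment-dependent) and
**dynamic** (pseudotime-dependent) *cis*-eQTLs from multi-condition
single-cell-derived pseudobulk data, with downstream regulatory-element
enrichment, gene-feature comparison, and GWAS colocalization — plus a
synthetic-data generator with planted effects so every stage of the
pipeline is verifiable without any external download.

The package is aimed at statistical geneticists studying
gene-by-environment (GxE) interactions in *in vitro* systems: panels of
donors whose cells are profiled by scRNA-seq under a control arm and one
or more chemical exposures, possibly spanning many cell types and
differentiation states.

## The models

**Per-context cis-eQTL mapping.** Cell counts are summed into pseudobulk
samples (donor × cell type × condition), TMM-normalized, log-transformed
and inverse-normal transformed across samples. For each gene, every SNP
within ±100 kb of the TSS (MAF ≥ 0.05, ≥ 2 homozygous carriers) is tested
by OLS

&nbsp;&nbsp;&nbsp;&nbsp;*y* = μ + β·G + covariates + ε,

with sex, two genotype PCs, and data-selected expression PCs as
covariates. Gene-level multiple testing uses the effective number of
independent tests M_eff from the eigenvalues of the local genotype
correlation matrix (p_gene = min(1, p_top · M_eff)), followed by
genome-wide Benjamini–Hochberg FDR.

**Multivariate empirical-Bayes shrinkage.** Effects (β̂, se) across all R
contexts are shrunk jointly under a mixture-of-multivariate-normals prior
with canonical and data-driven covariance components on a scale grid:

&nbsp;&nbsp;&nbsp;&nbsp;b ~ Σ_{k,l} π_{kl} N(0, ω_l² U_k),&nbsp;&nbsp;
β̂ | b ~ N(b, S V S).

Mixture weights are fitted by EM on LD-independent pairs; posterior means,
SDs and the local false sign rate (lfsr) are computed for the per-gene top
("strong") pairs. A pair is a significant eQTL at lfsr < 0.1; a
**response eQTL** changes effect size between control and treatment by
more than 1.5-fold (or flips sign); an eGene roll-up classifies genes.

**Dynamic eQTL mapping.** Cells on a differentiation trajectory are
grouped into 15 equal-range pseudotime bins (with cell- and donor-count
merge rules), aggregated per donor × bin, and fitted with a 28-column
interaction model whose genotype-by-pseudotime coefficient β₂₇ is the
dynamic test; covariates include 10 NIPALS cell-line PCs and their
pseudotime interactions. Significant calls are classified early / late /
switch from the predicted endpoint effects.

**Colocalization.** Two-trait Bayesian colocalization with Wakefield
approximate Bayes factors under a single causal variant per trait; priors
p1 = 1e-4 per SNP and conditional colocalization prior pc = 0.025;
a region is called colocalized when PP_regional > 0.5.

## Worked example

```python
from gxeqtl import pipeline

cfg = pipeline.RunConfig(
    seed=2, out_dir="demo_run",
    sim={"n_donors": 50, "n_genes": 60, "n_snps_per_gene": 5,
         "cells_per_donor_context": 20, "response_fraction": 0.2})
manifest = pipeline.run_pipeline(cfg)
print(manifest["stages"]["response"])
```

prints

```
{'n_response': 26, 'n_non_response': 154}
```

meaning 26 (gene × treatment) response-eQTL calls and 154 standard-eQTL
calls. On this seed the 9 planted response genes in the simulated truth
table are exactly the 9 genes called as response eGenes — the planted
condition-modulated effects are recovered with no false gene-level calls.
All stage outputs (association TSVs, posterior effects, response calls,
dynamic calls, enrichment and colocalization tables) are written to
`demo_run/` with a manifest recording the config hash and seed.

The same pipeline is scriptable from the shell:

```bash
gxeqtl run-all --seed 2 --out demo_run
gxeqtl simulate --seed 1 --out sim_data
```

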