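# Methods

This note documents the statistical procedures implemented in `gxeqtl`,
the choices made where the design was genuinely open, what the synthetic
data emulate, and the known limitations.

## Synthetic data generator (`simgen`)

The generator emulates a multi-condition single-cell eQTL study of a
donor panel (default 50 donors) whose cells are observed in one or more
cell types under a control arm and chemical treatments (default four
arms: control, nicotine, caffeine, ethanol — the design of a
heterogeneous differentiating culture exposure study).

**Genotypes.** Per SNP, an allele frequency p ~ Uniform(maf_range) is
drawn and haplotypes are generated with adjacent-SNP copying at rate
`ld_copy_prob` (default 0.3), giving geometrically decaying LD without
coalescent machinery; dosages are the sum of two haplotypes, i.e.
Binomial(2, p) in Hardy–Weinberg equilibrium marginally. SNPs are
re-drawn (up to 50 times, then dropped) until they pass the study
filters: empirical MAF ≥ 0.05 and at least two homozygous carriers
(dosage 0 or 2). Genes are spaced 1 Mb apart on one chromosome with their
SNPs uniform within ±100 kb of the TSS, so cis windows never overlap.

**Counts.** Cell-level counts are negative binomial with

log μ = a_g + (β + γ_ctx + δ·τ)·G + b_sex·sex + b_pop·pop + b_batch + u_donor,

with gene baselines a_g ~ Uniform(log 0.5, log 5) (≈ 0.5–5 UMIs per cell,
a realistic single-cell expression range), NB size 10 (variance
μ + μ²/10, moderate overdispersion), per donor-gene intercepts
u ~ N(0, 0.1²), and small sex / population / batch offsets (0.1, 0.1,
0.05 log units). Counts are generated at *cell* level deliberately so the
aggregation and cell-count filters are exercised end to end. Response
effects multiply the base effect by 3 (or flip its sign) in treated
arms; dynamic effects add a slope δ per unit pseudotime, optionally
restricted to one condition (treatment-only dynamic effects).

What the generator does **not** emulate: ambient RNA, doublets,
cell-type misassignment, realistic LD block structure, or treatment
effects on cell-type composition. Passing recovery tests therefore show
the estimators are correct under a well-specified generating model, not
that they are robust to every artifact of real scRNA-seq data.

## Pseudobulk (`pseudobulk`)

Counts are summed over cells per sample (donor × cell type × condition,
or donor × pseudotime bin). Filters for the eQTL stage: samples with < 3
cells removed; cell types with < 10 donors removed; genes kept only with
≥ 5 cells with nonzero reads in every condition and ≥ 2 donors with ≥ 3
aggregated reads.

**TMM.** The reference sample is the one whose upper quartile of
library-scaled counts is closest to the mean upper quartile; per-gene
M/A values on doubly-positive genes; 30 % of the M tails and 5 % of the
A tails trimmed; precision-weighted mean of the remaining M; factors
normalized to geometric mean 1. These are the standard published
defaults; the trim fractions are not tunable elsewhere in the package.

**Inverse normal transform.** Φ⁻¹((rank − c)/(n − 2c + 1)) with the Blom
offset c = 3/8 and average ranks for ties. Normalization spans **all
conditions of a cell type jointly**, then mapping proceeds per condition
— a single monotone transform keeps effect-size ratios between
conditions comparable, which the response-eQTL definition requires.

**Pseudotime binning.** Per condition × trajectory: donors with < 5
trajectory cells removed; 15 equal-range bins; a left-to-right sweep
merges any bin with fewer than min(100, total/15) cells into the next
bin (a deficient final bin merges backward); the same sweep then
enforces ≥ 20 donors per bin; medians are recomputed after merging. The
cell-count criterion runs before the donor criterion, and the sweep
restarts after every merge.

## Per-context cis-eQTL mapping (`cis_eqtl`)

OLS of inverse-normal expression on dosage with covariates (sex, two
genotype PCs from a centered-dosage SVD of the full panel, and expression
PCs). Estimates use the Frisch–Waugh projection, which reproduces full
OLS exactly with dof = n − p − 2. Expression PC count is chosen by
parallel analysis (30 within-gene permutations, 95th percentile,
counting stops at the first non-exceeding component) or by the
maximum-distance-to-chord elbow; covariates with R² > 0.9 against any
selected PC are dropped. The cis window is ±100 kb from the TSS,
strand-agnostic (the window is symmetric, so strand cannot change the
test set).

Gene-level correction: SNPs are split into consecutive blocks of ≤ 200;
per block the effective test count is the smallest number of descending
eigenvalues of the SNP correlation matrix reaching 99 % cumulative
share; the gene's corrected p is min(1, p_top · M_eff). Genome-wide
calls use Benjamini–Hochberg on the corrected per-gene minima.

## Multivariate shrinkage (`mash`)

The prior is a mixture of multivariate normals N(0, ω²U) over canonical
components (identity, per-context singletons, all-ones equal-effects)
and data-driven components (empirical covariance of the strong-set
z-scores and its rank-5 PCA reconstruction, both normalized to unit
maximum diagonal), on a √2-spaced grid from min(se)/10 to 2·max|β̂|,
plus a point-mass null. The residual correlation V is the correlation of
z-score rows with max |z| < 2, ridge-blended toward the identity until
its condition number is ≤ 1e6. Because only the weights are free, the
per-component likelihood matrix is computed once and EM reduces to
responsibility averaging; the log-likelihood is asserted nondecreasing,
with convergence at gain < 1e-8 or 1000 iterations.

Missing contexts are handled by marginalizing the multivariate normal
over the observed coordinates, in both the likelihood and the posterior;
the posterior for an unobserved context is the conditional given the
observed ones, so dropping a context and setting its se to infinity
agree exactly.

The lfsr of one effect is min{P(b ≥ 0 | data), P(b ≤ 0 | data)} with
posterior point mass at zero counted on both sides (so the null
component pushes lfsr toward 1). Extreme-deconvolution and matrix-
factorization components are not implemented: the empirical + PCA
data-driven set recovers planted covariance structure at this scale, and
ED adds an optimization layer the recovery tests do not need.

**Response calls.** Per cell type and treatment, a pair significant at
lfsr < 0.1 in control or treatment is a *response* eQTL when the
posterior means flip sign or their magnitude ratio exceeds 1.5, else a
standard eQTL. Sign flips count as response regardless of the ratio, and
a zero mean on one side (infinite ratio) is response. Fold change is
computed on posterior (post-shrinkage) means.

## Dynamic eQTLs (`dynamic`)

The 28-column design is: intercept, G, gPC1, gPC2, sex, τ, 10 cell-line
PCs, their 10 τ-interactions, sex·τ, and G·τ; the genotype-by-pseudotime
coefficient is the test statistic (two-sided t). τ is the bin median.
Cell-line PCs come from a NIPALS PCA of the donor × (gene ⊗ bin)
expression matrix, with missing entries skipped in every inner product
(tolerance 1e-8, ≤ 500 iterations per component, deterministic first-
column initialization). Plain OLS is used; weighting by bin cell count
is exposed but off by default. The interaction t-statistic is invariant
to affine rescaling of τ.

**Significance cutoff.** Per-gene minima of the corrected p-values enter
Benjamini–Hochberg at FDR 0.1; the cutoff is the corrected p of the
boundary gene — the largest per-gene corrected minimum whose q is still
≤ 0.1 — and *every* pair (not only gene-top pairs) at or below the
cutoff is retained.

**Classification.** Predicted endpoint effects e = β_G + β_{G×τ}·τ at
the binned τ range: same sign and shrinking magnitude → early; growing →
late (an exact tie is late); sign reversal with both |e| > 1 → switch;
a sign reversal failing the magnitude-1 threshold falls back to the
early/late magnitude rule rather than occupying a fourth class.

**π₁.** Storey's estimate on the λ grid 0.05…0.95 with a cubic
polynomial smoother evaluated at λ = 0.95, clamped to [0, 1].

## Enrichment (`enrichment`)

cCRE categories follow the distance rules (promoter-like within 200 bp
center-to-TSS, proximal enhancer within a closed 2 kb boundary, distal
beyond); a SNP overlapping several intervals takes the highest-precedence
category PLS > pELS > dELS; intervals are BED half-open 0-based against
1-based SNP positions. Enrichment is Fisher's exact test (conditional
MLE odds ratio; Haldane-corrected point estimate flagged when a cell is
zero) against the background of all tested SNPs. Across treatments, the
summary is the arithmetic mean of stratum odds ratios and Fisher's
method (χ² on −2Σlog p) for the combined p — both stated choices, since
only the summary shape is fixed by convention. Continuous gene features
(TSS counts, cumulative enhancer length) compare by two-sided rank-sum
test with seeded bootstrap SDs (1000 resamples); the pLI comparison is a
Fisher test on the pLI > 0.9 margin.

## Colocalization (`coloc`)

Single causal variant per trait; per-SNP log Wakefield ABF
0.5 log(1 − r) + 0.5 r z² with r = W/(V + W) and W = 0.15² (the standard
quantitative-trait prior variance). Configuration classes: null; trait 1
only (prior p1 per SNP); trait 2 only (p1); both at distinct SNPs
(p1²(1 − pc) per ordered pair); shared (p1·pc per SNP); defaults
p1 = 1e-4, pc = 0.025. Posteriors are normalized with log-sum-exp; the
off-diagonal "both distinct" mass uses log1p(−exp(diag − total)) to stay
finite. PP_regional is the mass on both-associated, PP_alignment the
shared share of it; the colocalization flag keys on PP_regional > 0.5
(strict), with the product PP also emitted. With matched priors the
product PP_regional × PP_alignment equals the classic 5-hypothesis H4
posterior.

## Orchestration (`pipeline`, `cli`)

Stages exchange flat text files (TSV/VCF/BED/JSON); every output carries
a header comment with the producing stage, a SHA-256 config hash and the
seed; the manifest records per-stage row counts. Unknown config keys are
rejected before any stage runs. Identical configs give bit-identical
deterministic outputs.

## Problem sizes used in tests and the acceptance script

Simulation experiments are desk-scale by design: null calibration uses
50 donors and 200 genes × 10 SNPs; response recovery uses 20 planted
response genes among 100 (50 donors, two cell types × two treatments
plus controls, 20 seeds); dynamic recovery plants 20 treatment-only
slopes of δ = 0.8 among 100 genes (100 donors, 15 bins, ~5 cells per
donor-bin, common variants with MAF ≥ 0.1, 20 seeds); colocalization
uses 100 replicates each of shared / distinct / null regions of 200
SNPs. These sizes give stable Monte-Carlo estimates while keeping the
full suite runnable on a single CPU in minutes.

Two numerical caveats discovered during development are worth recording.
First, the per-bin inverse-normal transform saturates when a genetic
effect is large relative to within-bin noise: genotype groups then map to
fixed normal-score positions and the pseudotime interaction loses
information, so recovery benchmarks plant slopes in the linear regime
(effect ≲ 2–3 within-bin SDs); real effect sizes are far below this
ceiling. Second, with few simulated genes a strongly boosted gene
inflates its own library size and attenuates its log-CPM slope by a few
percent; effect-size recovery is therefore measured on log-scale
expression at ≥ 100 genes, while significance testing uses the
inverse-normal scale throughout.

## Limitations

Trans effects, conditional secondary signals, splines or nonlinear
pseudotime effects, cell-level mixed models, multi-trait (> 2)
colocalization, and LD-aware non-independent configurations are out of
scope. The eigen-based test correction assumes the cis window's LD is
well summarized block-wise; the colocalization model assumes one causal
variant per trait.
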