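# temqtl

Genetics of gene regulation and proliferation in CD4+ effector memory
T (T_EM) cells: a tested analysis pipeline for mapping *cis*-acting
expression quantitative trait loci (eQTLs) in resting vs TCR-stimulated
cells, quantifying T_EM abundance and CFSE-measured proliferation by
mixture modelling, scanning cell traits genome-wide, and building a
proliferation-potential gene signature — together with a seeded
synthetic-cohort generator that reproduces the statistical structure
every stage assumes.

## Who this is for

Immunogenomics analysts studying how autoimmune-disease risk alleles
(rheumatoid arthritis, type 1 diabetes, celiac disease) act through
molecular phenotypes of purified T-cell subsets: per-state eQTL effects,
conditional (colocalization-style) analysis on disease SNPs, and
cell-level traits (peripheral abundance, division index DI,
proliferation index PI).

## The models at the core

**Cis-eQTL mapping.** Per gene, state and SNP within ±250 kb of the TSS:

    expression = β₀ + β₁·dosage + β₂·PC₁ + … + β₆·PC₅ + β₇·gender + ε

on the natural-log scale (so exp(β₁) is the per-allele fold change).
Within-region multiple testing is handled by permuting covariate-residual
expression (default 10,000 permutations, one stream per gene) and
comparing each SNP's statistic to the permutation distribution of the
region-wide best statistic; per-gene lead associations are controlled at
FDR 5% by Benjamini–Hochberg within each state.  Cross-state effect
differences use z = (β_stim − β_rest)/√(SE²_rest + SE²_stim), two-tailed
normal.  Conditional analysis appends a candidate SNP's dosage to the
covariates; a region is "fully explained" when no residual SNP reaches
permutation p < 0.05.

**Flow gating.** T_EM abundance is the posterior mass of the TEM
component of a template-initialized 7-component multivariate Gaussian
mixture over (CD45RA, CD45RO, CD62L), as a percentage of non-debris mass.

**CFSE deconvolution.** Stimulated-well log₁₀ intensities are a
constrained Gaussian mixture: component k (k = 0…5 divisions) has mean
μ₀ − k·d with shared σ, μ₀ anchored to the pooled resting peak and d
initialized at log₁₀2.  DI = Σ k·w_k and PI = DI/(1 − w₀).

**Proliferation signature.** Genes whose baseline expression correlates
with PI at permutation p < 0.01 form a ±1-weighted signature
(weight = sign of r); an individual's score is the signed sum of
standardized expression, validated by a count-null, split-half
cross-validation and cross-visit replication.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/05_proliferation_signature.py --seed 1
```

prints (seed 1):

```
cohort: 174 individuals, 2000 SNPs, 215 genes (seed 1)
abundance 9.45% (SD 4.99), DI 1.44 (SD 0.34), PI 2.16 (SD 0.22)
planted eQTL genes: 48; signature genes: 17
...
19 of 215 genes at p<0.01 (16 negatively, 3 positively correlated)
planted signature genes recovered: 17/17
signature score vs proliferation index: r = 0.62
permutation null of the gene count: median 2, max 13, observed 19 (p = 0.001)
split-half fold 1: held-out r = 0.60 (one-tailed p = 0.001)
split-half fold 2: held-out r = 0.61 (one-tailed p = 0.001)
```

The cohort's T_EM abundance mean/SD, its age and gender effects, and the
DI/PI moments match the generator's configured truths; the signature
stage recovers all 17 planted genes, the observed gene count far exceeds
the permutation null (median 2), and the held-out correlations confirm
the signature is not an overfitting artifact.  The remaining drivers
(`02` flow/CFSE quantification, `03` two-state eQTL scan with
conditional analysis, `04` cell-trait GWAS with genomic control,
`06` H3K4me3 peak proximity) follow the same pattern and write their
tables under `results/`.

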