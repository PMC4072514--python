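# Methods

This note documents the models implemented in `temqtl`, the synthetic
cohort that drives them, the numerical choices, and the limits of what
the test suite demonstrates.

## The synthetic cohort

The generator (`temqtl.synth`) replaces raw study data with a seeded
cohort carrying known truths.  Its defaults are the study conditions the
pipeline targets: 174 individuals (ages uniform 19–57; female fraction
134/225), 215 assayed genes, T_EM abundance mean 9.57% (SD 4.85%) rising
0.11% per year and 2.22% higher in men, division index 1.46 (SD 0.35),
proliferation index 2.16 (SD 0.21), ~22% of genes with a planted
cis-eQTL of which ~70% are active in exactly one state (mostly
stimulated-only, 29:3).

**Genotypes.** Balding–Nichols population structure: each LD block has
an ancestral allele frequency p ~ U(maf_range); subpopulation
frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F) with F = F_ST (default
0.01 across 2 subpopulations — mild, European-like stratification that
the genotype PCs must absorb).  Haplotypes within a block copy the
previous SNP's allele with probability ρ = 0.9, giving pairwise r²
decaying geometrically with SNP distance; dosages are hard calls.
Defaults: 2,000 SNPs, 10-SNP blocks, 10 kb spacing on one chromosome —
enough markers that the top-5 PCs reflect ancestry rather than
individual LD blocks (with very small panels the PCs align with single
blocks and absorb genuine cis effects; the generator does not guard
against deliberately tiny configurations).

**Expression.** Natural-log scale, per state:
y = μ_g + β_state·dosage + γ_gender·gender + Σγ_k·PC_k + N(0, σ²),
σ = 1.  Planted causal SNPs lie within ±250 kb of the gene's TSS
(MAF ≥ 0.1 so planted effects are discoverable); planted |β| has SD 0.6
with a floor of 0.2·SD to avoid vacuous truths.  PCs are standardized
before their effects are applied so the shared covariate component does
not dominate gene–gene correlation.

**Signature genes and phenotypes.** Seventeen non-eQTL genes (15
negative, 2 positive) share a latent "proliferation propensity" factor
u: signed expression loads on u with loading 1 (in units of the noise
SD).  This factor structure is deliberate — a set of individually
detectable predictor genes must be co-regulated, since 17 *independent*
genes jointly correlated with one phenotype could each carry only
r ≈ 0.55/√17 ≈ 0.13, undetectable at p < 0.01 and n = 182.  DI and PI
both load on u (coefficient solved so that the ±1 score's correlation
with the phenotype equals the configured 0.55) and negatively on
abundance (r = −0.24); their residual noises are correlated (0.7), as
for indices derived from the same CFSE fit.  Abundance is
mean + 0.11·(age − mean age) + 2.22·male + noise, the residual SD chosen
so the total SD matches 4.85.  A second visit (`simulate_second_visit`)
keeps u and abundance fixed and redraws measurement noise; it does not
re-apply eQTL effects (it emulates the signature-replication design
only).

**What the generator does not emulate:** raw NanoString counts and
their normalization, FCS binary artifacts or spillover, realistic
genome-wide LD maps or allele-frequency spectra, and any dependence of
expression noise on expression level.  Passing tests therefore show the
*methods* are correct and calibrated under the stated structure, not
that the study's real-data numbers would be reproduced.

## Cis-eQTL mapping

OLS per gene/state/SNP with intercept, dosage, 5 genotype PCs and
gender; the analytic p is the two-tailed t-test on the dosage effect
with full-model residual df.  Scans are vectorized via
Frisch–Waugh–Lovell (residualize expression and dosages on covariates
once; the residual-regression slope and t equal the full model's —
asserted to 1e-8 against statsmodels).

**Genotype PCs** are EIGENSTRAT-style: dosages centered and scaled by
√(2p(1−p)) (monomorphic SNPs dropped), top eigenvectors of the
individual covariance, sign fixed so each PC's largest-magnitude
loading is positive.

**Permutation empirical p.**  Covariate-residual expression is permuted
(default 10,000 draws; one stream per gene, derived by hashing the gene
id with the master seed so serial and parallel runs agree).  Because
residuals are orthogonal to covariates, each permutation needs only the
correlation of permuted residuals with residualized dosages (~8× faster
than refitting the full model; |r| ordering equals p ordering at fixed
df).  Each SNP's observed statistic is compared, by default, to the
permutation distribution of the *region-wide best* statistic.  This is
the reading under which the permutation actually adjusts for the number
of correlated SNPs in the window: the lead SNP's empirical p is uniform
under the regional null (which BH across genes assumes), and
conditioning on the causal variant leaves no residual SNP below 0.05.
The unadjusted per-SNP comparison (each SNP vs its own permutation
distribution) is available via `region_min=False`.  Add-one smoothing
floors the empirical p at 1/(n_perm+1); permutation counts below 100
are refused as too coarse.

**Conventions.**  Cis windows are ±250,000 bp of the TSS, inclusive at
both ends, strand ignored; coordinates are 1-based.  QC removes SNPs
with MAF < 0.01 or imputation quality < 0.4 (strict inequalities: a SNP
at a threshold is kept).  Fold change is exp(β) — the natural-log scale
is pinned down by exp(−0.805) = 0.45 matching the reference per-allele
fold for the strongest cross-state example.  LD r² is the squared
Pearson correlation of dosage vectors.  Lead-SNP ties break by smaller
analytic p, then smaller position.  Disease-locus intervals span the
furthest r² > 0.5 partners, extend to the nearest flanking
recombination hotspots, and grow a further 250 kb per side when no gene
TSS falls inside.

## Flow gating

A 7-component full-covariance 3-D Gaussian mixture is fitted by EM,
initialized at a labelled template (exactly one `TEM`, one `debris`).
The log-likelihood is asserted non-decreasing every iteration; a
collapsing component (covariance determinant < 1e-12) is re-seeded at
its template values once and marked failed on a second collapse (ascent
is not asserted on intervention iterations).  `max_iter=0` returns the
template with its posterior assignments — the pure-template gate.
After EM, fitted components are relabelled by nearest template mean
under the template covariance metric (Mahalanobis, one-to-one by
Hungarian assignment).  Abundance = 100 × TEM posterior mass / non-debris
posterior mass; the default template places 9.57% of non-debris mass in
TEM.  Event floor: 50 events per component (350 total).  The EM was
cross-checked against scikit-learn's GaussianMixture on identical data
and initialization (per-event log-likelihood agreement to 5e-3).

## CFSE deconvolution

Component k of the stimulated-well mixture has mean μ₀ − k·d, shared σ,
k ≤ 5; weights may be exactly zero.  μ₀ initializes at the pooled
resting-well estimate and is constrained to ±σ₀ of it (the resting peak
*initializes* the location; refinement is allowed); d initializes at
log₁₀2 (CFSE halves per division) and is bounded in [0.7, 1.3]·log₁₀2;
σ initializes at σ₀ with a floor of max(1e-4, 0.05·σ₀).

The fit is EM with an exact box-constrained M-step: given
responsibilities, (μ₀, d) solve a 2-parameter bounded weighted least
squares (scipy `lsq_linear` on the component means), weights and σ are
closed-form.  Each M-step block is an exact constrained minimizer, so
the ascent property holds and is asserted at every iteration — the
reason this EM was chosen over a generic quasi-Newton on the penalized
likelihood, which satisfies no such invariant.  Three restarts
(Dirichlet weight draws, uniform d draws) guard against local optima;
the best log-likelihood is kept.  Convergence: gain < 1e-6 or 500
iterations, flagged either way.  DI = Σ k·w_k; PI = DI/(1 − w₀),
undefined (flagged, not an error) when the divided mass is below 1e-6.
Event floors: 100 resting, 200 stimulated.  Replicate stimulated wells
are fitted separately and their DI/PI averaged.

## Cell-trait GWAS and enrichment

Per-SNP OLS of the trait on dosage plus covariates — gender, age and 5
genotype PCs for abundance; additionally the measured abundance for
proliferation.  Thresholds: 5×10⁻⁸ genome-wide, 5×10⁻⁵ suggestive.
λ_GC is the median χ²₁ quantile of the p-values over 0.4549; QQ bands
come from order-statistic Beta quantiles (the i-th of n uniform p's is
Beta(i, n−i+1)).  Disease-SNP enrichment uses the *exact* one-tailed
binomial tail P(X ≥ k | n, α) — no normal approximation — reporting the
expected count n·α alongside.

## Proliferation signature

Per-gene Pearson r of baseline expression vs PI; two-tailed permutation
p with one shared stream across genes and add-one smoothing; constant
genes are skipped.  Selection at p < 0.01; weights are sign(r); scores
are signed sums of expression standardized across the scored
individuals (raw assay scales differ by orders of magnitude, making
unstandardized sums degenerate; `standardize=False` is deliberately not
offered — the standardized sum *is* the signature).  The count null
permutes PI 1,000 times and counts genes below threshold using the
analytic t-based p inside the loop (a permutation-within-permutation
would cost O(10⁶) fits per gene; at n = 182 the analytic and
permutation p agree closely).  Split-half validation uses a single
random unstratified split per seed, signatures trained per half and
evaluated on the other with one-tailed permutation p.  Cross-visit
replication trains on each visit's shared individuals and scores the
other; DI is scored but never used for selection.

## H3K4me3 proximity

Peaks are BED-style 0-based half-open with a height (score) and optional
summit offset; SNP positions arrive 1-based and are converted centrally.
Distance is 0 inside a peak, otherwise the number of bases strictly
between SNP and peak edge; summit distance is reported alongside since
either convention is defensible.  Lead SNPs are expanded by LD
(r² ≥ 0.8) and the set minimum distance kept, ties broken by taller
peak.  Set comparisons use one-sided Mann–Whitney: exact when both
groups have ≤ 10 values, otherwise the normal approximation with tie and
continuity corrections.  A chromosome without peaks yields an
infinite-distance sentinel, not an error.

## Problem sizes and determinism

The shipped drivers and checks use a 174 × 2,000 × 215 cohort with
1,000 permutations per gene region, 10,000–20,000 events per
flow/CFSE sample, and 50–100 replicates for the recovery rates —
sizes at which every calibration and recovery property is measurable
with comfortable margins while a full run stays in the minutes range on
one CPU.  All randomness flows from explicit seeds through
`numpy.random.default_rng`; per-stage streams are derived from the
master seed with fixed salts, and identical configuration plus seed
reproduces byte-identical outputs.

## Known limitations

- The per-SNP (non-region-adjusted) empirical p is available but not
  default; its regional minimum is anticonservative by construction.
- The gating EM relabels by Mahalanobis distance between means only; a
  fitted component that drifts far from every template component can in
  principle be mislabelled (not observed under template-consistent data).
- The CFSE spacing bound [0.7, 1.3]·log₁₀2 assumes reasonably calibrated
  dye halving; strongly autofluorescent data would need a wider bound.
- `simulate_second_visit` refreshes all gene noise, so visit-2 data
  carry no eQTL signal; it supports signature replication only.
- Exact Mann–Whitney is limited to groups of ≤ 10 (beyond that the
  corrected normal approximation is used, as is standard).
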