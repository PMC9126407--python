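# Methods

This note records the statistical models, the generative model behind the
synthetic cohorts, the numerical choices, and the limits of what the test
suite demonstrates.

## Models and procedures

### Cis association scans

A molecular trait y (protein or transcript level) is regressed on allele
dosage g per variant: `y = α + β·g + Cδ + ε`, with covariates C (age, sex
by default). The scan residualizes y and all dosage columns on `[1, C]`
once (Frisch–Waugh–Lovell) and recovers per-variant β, SE and the
two-sided t-test with the full model's degrees of freedom — numerically
identical to fitting each variant's full OLS model, verified against
statsmodels to 1e-8. Variants with empirical MAF < 0.01 in the analyzed
samples are dropped. Traits are analyzed in raw units; a rank-based
inverse-normal transform is available behind a flag (off by default, since
semi-quantitative log-scale protein units are already near-Gaussian).
Missing trait values are dropped listwise; a mean-imputation flag exists
for compatibility with cohorts that impute isolated values. Coordinates
are 1-based inclusive. For sex-stratified scans the caller passes sex
labels and must drop sex from the covariates — a constant column inside a
stratum is reported as collinear by name.

Binary outcomes use one logistic GLM per variant (Wald z). This is only
ever applied to a handful of instrument variants, so the per-variant fit
cost is irrelevant.

### Hierarchical FDR and pruning

Discovery across m gene regions uses the two-level scheme: BH within each
region; the region summary is the Simes p (the minimum BH-adjusted p);
BH across the m Simes values at α₁ = 0.05 selects k regions; within
selected regions, variants with within-region BH-adjusted p ≤ α₂ = α₁·k/m
are significant (Benjamini–Bogomolov). α₂ always uses the k from the same
dataset — no plug-in variant is offered. Lead variants break p ties by
larger |β|, then lexicographic id, so pruning is deterministic. Priority
pruning walks significant variants by ascending p and keeps each one iff
its dosage-correlation r² with every kept variant is below 0.1; the
pairwise bound is re-asserted on the output. Pruning is per-region by
default (pooling regions across chromosomes would only add r²≈0 pairs).

### Co-localization

Per-variant evidence is the Wakefield approximate Bayes factor from β and
SE; the prior effect SD defaults to 0.15 (quantitative traits), priors
p1 = p2 = 1e-4, p12 = 1e-5 — the conventional defaults, all exposed in
`ColocPriors`. Hypothesis sums run in log space: H4 is the diagonal sum of
paired ABFs, H3 the off-diagonal sum computed stably as
`log(S1·S2 − S12)` via `log1p(−exp(·))`, so no posterior underflows to 0
unless it is analytically 0 (e.g. PP3 with one shared variant). Posteriors
are invariant to a global sign flip of either trait and to a constant
shift of all log-ABFs; agreement with an exhaustive configuration
enumeration is at machine precision on small regions. Verdicts use
PP4 ≥ 0.75 (shared) and PP3 ≥ 0.75 (independent). Effect alleles are
harmonized by sign-flip when the allele pair is swapped; variants whose
alleles cannot be reconciled are dropped and counted.

### Summary-statistics TWAS

With per-gene weights w (effect-allele oriented), LD-panel dosage
variances σ_l² and covariance Γ: `z = Σ_l w_l (σ_l/σ_g)(β_l/se_l)`,
`σ_g² = wᵀΓw`, and the reported effect is per unit of predicted
expression, `Σ_l w_l σ_l² β_l / σ_g²`. Mismatched effect alleles
re-orient the statistics (β sign), never the weight — flipping the weight
would wrongly perturb σ_g. The formula replaces each variant's residual
variance with the trait variance; this approximation is tight when every
variant explains a small trait fraction. Measured agreement with the
individual-level regression at n = 2000: max |Δz| ≈ 0.02 when per-variant
R² ≤ 2%, ≈ 0.1 at 5%, and up to ≈ 0.3 when one variant explains 10% of
the trait. The equivalence experiment therefore simulates per-variant
R² ≤ 2% — the regime in which summary-based TWAS is actually deployed —
and the strong-single-QTL breakdown is a documented limit of the method,
not of the implementation. Weight training (elastic net on reference
transcriptomes) is out of scope: weights are inputs, and the generator
emits true-model weights.

### Mendelian randomization and mediation

Single-instrument ratio estimator only: `β_IV = β_y/β_x`, SE from the
first two delta-method terms, p from the standard normal. Instruments are
lead variants at p < 5×10⁻⁸; exposures whose lead misses the threshold
are excluded rather than estimated. The protein→disease battery is
Bonferroni-corrected over the number of testable proteins; the GE→protein
battery uses the hierarchical scheme with tissues nested in genes. For a
chain GE→PE→disease, the indirect effect is β₁·β₂ with the product
delta-method SE `√(β₁²se₂² + β₂²se₁²)`; the difference test
`(total − indirect)/√(se_tot² + se_ind²)` treats the two estimates as
independent, which is conservative when they share the disease-leg
statistics. *Complete mediation* requires a significant total effect, a
significant indirect effect and a non-significant difference. Disease
legs are on the log-odds scale.

A design point worth stating: with a single shared instrument and one set
of PE statistics, the indirect estimate `(β_PE/β_GE)·(β_dis/β_PE)`
cancels algebraically to the total `β_dis/β_GE`, making the difference
test vacuous. The pipeline therefore computes the two PE legs on two
disjoint sample subsets, splitting each cohort four ways (GE stats, PE
discovery + GE→PE outcome leg, PE→disease exposure leg, disease stats).
This emulates the multi-source reality of such studies, where each leg
comes from a different dataset.

### Concordance and overlap

A tissue counts as discordant when the sign of its eQTL β at the pQTL
lead variant opposes the pQTL β, among tissues significant at p ≤ 0.05
(configurable). The *predominantly discordant* verdict requires the
discordant fraction to exceed 0.75 strictly: 17/18 qualifies, 3/4 (exactly
0.75) does not. Sex differences are tested with
`t = (β_f − β_m)/√(se_f² + se_m²)` against the standard normal. Partial
correlation residualizes both variables on the covariates and tests the
residual Pearson r with n − k − 2 degrees of freedom; it matches the
precision-matrix formula to 1e-10 and pingouin to numerical precision.
The overlap report enumerates all seven exclusive cells of the three gene
sets (TWAS-negative, MR-negative, QTL-discordant); the central cell is the
set of genes negative by every strategy.

## The synthetic-data generator

Genotypes: per region, each haplotype's latent Gaussian series follows
`z_j = ρ·z_{j−1} + √(1−ρ²)·e_j` (ρ = `ld_decay`) and is thresholded at
Φ⁻¹(MAF_j), so allele frequencies hit their targets exactly in
expectation and LD decays geometrically with variant distance; two
haplotypes sum to the dosage. MAFs are uniform in `maf_range`
(default 0.05–0.5). Regions sit on separate chromosome labels with 2-kb
variant spacing. Adjacent-pair dosage r² matches an independent
latent-Gaussian Monte-Carlo oracle within 0.02.

Molecular layers: GE in tissue t is `β_t·G_causal + N(0,1)` with β chosen
from the empirical dosage variance so the causal variant explains exactly
the target cis-h² (default 0.1 — a typical strong cis signal); PE adds a
direct genetic effect γ (sign flipped for discordant regions), an optional
coupling δ on blood GE (tissue 0), age and sex covariate effects, and
unit noise. Male genetic effects are scaled by `sex_interaction`. In
`shared` regions GE and PE reuse one causal variant; in `independent`
regions the PE variant is drawn among those with empirical r² < 0.05 to
the GE variant; `null` regions carry no effects. PE is a single blood
compartment; tissue GE matrices are parallel draws. Age is uniform 40–80,
sex Bernoulli(0.5) — the covariate roles, not any cohort's demographics.

Outcome: `logit P(Y=1) = α + Σ_r (θ_PE·PE_r + θ_direct·GE_r,blood)` over
non-null regions, with the intercept solved by root finding so the
sample-average risk equals the configured prevalence (default 0.3, a
case-enriched design). `mediation_fraction` f fixes
`θ_direct = θ_PE·δ·(1/f − 1)` (0 at f = 1, so full mediation means no
direct term); at f = 0 a free `theta_ge_direct` applies.

Two-sample designs are emulated by disjoint index splits of one simulated
cohort rather than by two cohorts with different LD panels; LD-panel
mismatch is out of scope. What the generator does **not** emulate:
realistic human LD maps and allele-frequency spectra, imputation error,
assay batch effects and detection limits, population stratification,
relatedness, polygenic trans backgrounds. Passing tests therefore show
that each procedure is correct and calibrated under its own model
assumptions — not that those assumptions hold in any particular cohort.

## Validation experiment sizes

Chosen so the full suite runs in well under a minute per experiment on
one CPU while keeping Monte-Carlo error small against each check:

- multiplicity: exhaustive grid to length 4 plus 500 random vectors to
  length 8, against a quadratic-time reference and statsmodels;
- hierarchical FDR: 500 datasets of 92 regions × 200 variants, 20%
  non-null (5 causal variants at 5 SD); empirical region FDR ≈ 0.04–0.05
  against the 0.05 + 2·MC-SE bound;
- MR: 500 two-sample replicates (n = 2000/2000, cis-h² 0.1 instrument,
  true effect 0.4); observed |bias| < 2 MC-SE, coverage ≈ 0.95;
  delta-method SE vs a 10⁶-draw parametric bootstrap within 5%;
- coloc: 200 replicates per architecture at n = 2000, 40 variants,
  h² 0.15; PP4 ≥ 0.75 in ~100% of shared regions, PP3 ≥ 0.75 in ~100% of
  low-LD independent regions; enumeration agreement < 1e-9;
- TWAS: 100 genes at n = 2000 with 3-variant weight models and
  per-variant R² ≤ 2%; max |Δz| ≈ 0.02–0.04;
- mediation: 200 fully mediated replicates with four-way sample splits;
  difference test non-significant in ≥ 95% (the independence assumption
  makes it conservative), indirect sign recovered in ~100%;
- end-to-end: 5 pipeline runs, 5 discordant-mediated genes among 60
  nulls; the central overlap equals the planted set in every run.

## Numerical choices and degenerate inputs

Log-sum-exp for all coloc sums; p-values clipped to the smallest positive
float rather than 0; BH implemented as the vectorized step-up with a
mergesort for stable tie order; lead ties broken by |β| then id
everywhere; `mr_ratio` refuses β_x = 0 (degenerate instrument) and
`ld_r2` refuses zero-variance columns; collinear covariates are rejected
with the offending column named; empty variant intersections and empty
regions raise instead of returning silent neutral values. All randomness
flows through `numpy` Generators keyed by (seed, stage), so every output
is bit-reproducible given a config.

## Known limitations

Single-instrument MR only — no IVW/Egger, no pleiotropy diagnostics, no
reverse-causation probes. One causal variant per trait per region, so the
coloc single-causal-variant assumption is satisfied by construction;
multi-causal fine-mapping (SuSiE-style) is out of scope. The difference
test's independence assumption over-covers when legs share statistics.
The GE–PE residual coupling δ has no empirical calibration and defaults
to 0 except where an experiment needs a causal GE→PE path.
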