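# omicschain

Tools for tracing causal chains from genetic variants through tissue gene
expression (GE) and blood protein levels (PE) to a binary disease outcome,
with a synthetic-data generator that makes the whole chain testable end to
end against known ground truth.

The package targets the standard multi-omics QTL workflow used in
population cohorts with proteomic panels: map cis protein QTLs around each
protein's gene, control discovery across many gene regions hierarchically,
ask whether protein and expression signals share a causal variant, test
whether genetically predicted expression tracks protein levels, and estimate
causal effects and mediation with Mendelian randomization.

## What it computes

- **Cis association scans** (`qtlscan`) — per-variant OLS of a molecular
  trait on allele dosage with covariate adjustment inside a gene ± 500 kb
  window, combined or sex-stratified; logistic scans for binary outcomes.
- **Hierarchical FDR + LD pruning** (`hfdr_ld`) — Benjamini–Hochberg within
  each region, the region-level Simes p-value
  `min_i m·p_(i)/i`, BH across the m regions at α₁, then the
  Benjamini–Bogomolov within-region threshold α₂ = α₁·k/m for the k
  selected regions; greedy priority pruning of significant variants to
  pairwise LD r² < 0.1.
- **Bayesian co-localization** (`coloc`) — Wakefield approximate Bayes
  factors `log ABF = ½·log(1−r) + ½·z²·r` with `r = W/(se² + W)`,
  hypothesis posteriors PP0–PP4 accumulated in log space; two signals are
  called *shared* at PP4 ≥ 0.75 and *independent* at PP3 ≥ 0.75.
- **Summary-statistics TWAS** (`twas`) — association of genetically
  predicted expression with a trait from per-variant summary statistics,
  weights and an LD reference: `z = Σ_l w_l (σ_l/σ_g)(β_l/se_l)` with
  `σ_g² = wᵀΓw`, plus the individual-level equivalent for validation.
- **Mendelian randomization & mediation** (`mr_mediation`) — single-
  instrument ratio estimator `β_IV = β_y/β_x` with the two-term delta-method
  SE `√(se_y²/β_x² + β_y²·se_x²/β_x⁴)`, instruments at p < 5×10⁻⁸,
  Bonferroni or hierarchical multiplicity control, and GE→PE→disease chains
  with indirect effect β₁·β₂ and a total-vs-indirect difference test.
- **Concordance & overlap** (`concordance`) — pQTL/eQTL effect-direction
  classification across tissues (strict >75% rule), sex-difference t-tests
  of stratified betas, Pearson partial correlation, and the three-way
  overlap of negative-relation gene sets.
- **Synthetic cohorts** (`simdata`) — AR(1) latent-Gaussian haplotypes with
  configurable MAF range and LD decay; per-region causal architectures
  (shared / independent / null), concordant or discordant GE/PE effect
  signs, sex-specific effect scaling, and a logistic disease outcome whose
  genetic risk is routed through PE by a configurable mediated fraction.
- **Pipeline** (`pipeline.run_all`) — the full chain from one YAML config
  to a machine-readable report, on disjoint sample subsets per summary
  statistic so all MR legs are two-sample.

## Worked example

Run the demo study — two genes whose shared causal variant raises
expression but lowers the protein (discordant), the protein raising disease
risk, among four null genes:

```bash
omicschain run --config examples/demo.yaml --out results/demo
```

Equivalent in Python:

```python
from omicschain.pipeline import PipelineConfig, run_all
report = run_all(PipelineConfig.from_yaml("examples/demo.yaml"))
```

The run selects exactly the two causal regions (`k = 2`, so the
within-region threshold becomes α₂ = 0.05·2/6 ≈ 0.0167):

```
simes: {'gene000': '1.1e-21', 'gene001': '1.35e-20', 'gene002': '0.921', ...}
shared: ['gene000', 'gene001']   independent: []
mx_neg: ['gene000', 'gene001']   mr_neg: ['gene000', 'gene001']   discordant: ['gene000', 'gene001']
center: ['gene000', 'gene001']
```

Both genes co-localize (shared causal variant), show negative predicted-
expression association and negative causal GE→PE effects, and are
predominantly discordant — so they land in the central overlap. The
mediation table shows the chain estimates:

```
gene_id tissue  beta_ge_pe  beta_pe_outcome  indirect  total  diff_p  complete
gene000     t0      -1.049            0.655    -0.688 -0.522   0.634      True
gene000     t1      -1.126            0.655    -0.738 -0.560   0.635      True
gene001     t0      -1.034            0.541    -0.559 -0.675   0.685      True
gene001     t1      -1.425            0.541    -0.770 -0.930   0.700      True
```

Each row multiplies a negative GE→PE leg into the positive PE→disease leg,
giving a negative mediated (indirect) disease effect of expression that is
statistically indistinguishable from the total effect (`diff_p` large,
`complete = True`): the simulated full mediation is recovered.

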