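# Methods

## The nested count model

Each candidate regulatory sequence contributes two observation vectors: DNA
counts `d` (construct abundance per barcode × batch, and per condition in
paired designs) and RNA counts `r` (transcript abundance per barcode × batch
× condition). The generative assumptions are a Gamma-distributed latent
construct abundance and conditionally Poisson transcripts,

    d̂ ~ Gamma(k, b),        r̂ | d̂ ~ Poisson(α · d̂),

whose marginal is negative binomial with mean `α·k/b` and size `ψ = k`. The
mean–variance law `Var = μ + μ²/ψ` matches the quadratic overdispersion seen
in both MPRA libraries, so the observation model for *both* layers is NB with
a single per-sequence dispersion `k` shared between DNA and RNA. Treating the
DNA counts as NB (rather than putting a Gamma density directly on them)
handles zero DNA counts naturally; zeros enter the pmf directly and no
pseudocounts are ever added to data.

Structured experiments enter through log-additive GLMs:

    log μ_D = X_D β + log S_D
    log μ_R = X_D β (mapped to RNA observations) + X_R γ + log S_R

- `X_D` (DNA design) encodes barcode identity plus nuisance structure
  (batch; condition in paired multi-condition designs). Per-barcode
  construct abundance is the point of the barcode terms.
- `X_R` (RNA design) encodes only the conditions of interest. It never
  contains barcode identity — barcodes are replicates sharing one
  transcription rate — and the container layer enforces this.
- `S_D`, `S_R` are strictly positive correction factors entering as offsets;
  by default upper-quartile library-size factors (75th percentile of the
  nonzero counts per library, centred to geometric mean 1, DNA and RNA
  normalized separately). Factors may be computed on a different sequence
  subset than the one analysed, and external factors can be supplied.
- Un-paired designs (DNA sequenced once, pre-transduction) are represented
  by a many-to-one map from RNA observation columns to the shared DNA
  column; conditions then appear only in `X_R`.

Design matrices use treatment (reference-level) coding with the lexically
first level as reference, intercept first, then factors in declaration order
with levels in lexical order; interactions are products of the non-reference
indicator columns. Rank deficiency is detected at construction and reported
with the names of the collinear columns.

The per-condition transcription rate is read off the RNA coefficients:
`α(level) = exp(γ₀ + γ_level)`, with `exp(γ₀)` at the reference level.

## Estimation

Each sequence is fitted independently (no pooling across sequences — the
curated nature of MPRA libraries makes population-level shrinkage
assumptions unsafe). The joint likelihood over `(β, γ, log k)` is maximised
by L-BFGS-B with analytic gradients. Numerical choices:

- Initialisation: `β` from least squares on `log(d + 0.5)` against `X_D`
  (offsets removed); `γ` intercept from the log aggregated ratio of
  normalized counts; `log k = 0`.
- Convergence: relative log-likelihood improvement below `tol = 1e-6`
  within `max_iter = 200` iterations; fits report a convergence flag and
  iteration count, and an optional debug trace exposes the monotone
  objective path.
- Linear predictors are clipped at ±500 before exponentiation; `log k` is
  bounded in [−12, 16].
- All-zero DNA counts make the construct abundance unidentifiable: the fit
  is flagged unconverged and the rate is NaN; batch analyses record such
  failures and continue.
- **Dispersion**: after the joint fit, `k` is re-estimated by Cox–Reid
  adjusted profile likelihood — maximising `ℓ(k) − ½ log det(Zᵀ W Z)` with
  the mean parameters held fixed, `Z` the stacked DNA+RNA mean design and
  `W = kμ/(k+μ)` the working weights — and the mean parameters are then
  re-maximised at that `k` (two passes). The plain MLE of `k` is biased
  upward when the mean design is wide (≈35 parameters for a 30-barcode,
  3-batch, 2-condition sequence), which propagates into anti-conservative
  tests; the CR adjustment is the standard remedy in NB count models.
  The RNA layer uses the fitted DNA coefficients as plug-in estimates
  (shared `β` in both linear predictors) rather than propagating DNA
  uncertainty.

## Quantification and ratio baselines

Alongside α the package computes the two classical summaries over the set
`S = {i : R_i ≠ 0 and D_i ≠ 0}` of barcodes with nonzero counts on both
sides: the mean ratio `(1/|S|) Σ R_i/D_i` and the aggregated ratio
`Σ R_i / Σ D_j`. Ratios are computed on library-size-normalized counts
(counts divided by the factor); the GLM consumes the same factors as
offsets. Ratios pool all (barcode, replicate) columns of a condition.
Barcode down-sampling draws one barcode subset per (rate, replicate),
applied to all sequences, and combined analyses include the original data so
library-size correction is shared.

## Classification

Activity is tested on `log α` (the model is log-additive, so the null is a
location/scale family on the log scale):

- **Controls-based null** (≥3 negative controls): location = median of
  control `log α`; scale = 1.4826 × MAD (the consistency constant for the
  normal).
- **Mode-based null** (no controls, ≥20 sequences): the mode of a Gaussian
  KDE (Silverman bandwidth) of all `log α` is taken as the null centre;
  sub-mode values are assumed null-generated and reflected about the mode,
  and the scaled MAD of that symmetric sample gives the spread. Near-ties
  between density peaks resolve to the smaller rate (the more conservative,
  lower null) with a warning.

Each sequence's MAD score `z = (log α − location)/scale` is referred to a
standard normal — one-sided (greater) by default for inducers, one-sided
(less) for repressors, or two-sided — and p-values are Benjamini–Hochberg
adjusted, with NaN rates excluded from the denominator. A degenerate
(zero) null scale is an error rather than a silent infinite statistic.

## Comparative analysis

Any nested pair of RNA term sets defines a hypothesis; per sequence the full
and reduced models are fitted and `Λ = 2(ℓ_full − ℓ_reduced)` is referred to
χ²(df), df = difference in coefficient count. The dispersion is estimated
once, from the full model (CR-adjusted), and both models are fitted at that
common fixed `k`: re-estimating `k` separately under each model breaks the
nesting of the pair and produces negative statistics. If the full model
still ends below the reduced one, it is refitted from the reduced optimum;
a residual shortfall is clipped to 0 with a warning. Single RNA coefficients
can instead be tested by a Wald statistic with standard errors from the
inverse observed Fisher information (finite differences of the analytic
gradient at the optimum).

Temporal activity is the LRT of `~batch + time` against `~batch`
(df = timepoints − 1; with two timepoints this is exactly a two-condition
comparison). Allelic comparisons run either per condition (`~allele` vs
intercept) or as an allele × cell-type interaction
(`~allele + celltype + allele:celltype` vs `~allele + celltype`, the
interaction model being the alternative); the two alleles may carry
different barcode sets, and with a single shared pre-transduction DNA
replicate the DNA model encodes barcode effects only.

Library-size correction cannot remove a global condition bias when most
sequences are differential, so an optional negative-control correction fits
a joint model over the controls — each control keeps its own DNA model and
dispersion, all share one RNA coefficient vector (basal behaviour per
condition), optimised by block coordinate ascent (plain ML; the shared
vector averages over controls and is insensitive to the small dispersion
bias) — and injects the shared coefficients (intercept excluded; it is
absorbed by each candidate's own rate) as fixed offsets into every
candidate's RNA linear predictor in both models. Tested effects are then
relative to basal condition behaviour.

Effect sizes are reported in log2 (fitting is in natural log): for single-df
hypotheses the extra coefficient itself; for multi-df hypotheses the range
of the extra effects including the reference level's implicit zero. BH
adjustment runs within each analysis over converged candidates only.

## Simulators

The **log-normal generator** draws per-sequence GLM coefficients
`β₀ ~ N(K, σ₀²)`, `β_batch ~ N(0, σ_batch²)`, `β_BC ~ N(0, σ_BC²)`, builds
latent counts `D_true = nint(exp(X_d β))`, `R_true = nint(exp(α · X_d β))`
and adds multiplicative log-normal observation noise with medians at the
latent values: `log D_obs ~ N(X_d β, σ_D²)` and likewise for RNA with
`σ_R`; `nint` rounds half to even. The benchmark setting is three batches,
`K = 5`, all five σ's at 0.5, and 281 rates on the grid 0.2…3.0 (step 0.01).
Two deliberate properties: the noise family is *not* the NB the estimator
assumes, so benchmark results are not biased toward the model; and the rate
multiplies the linear predictor inside the exponent, making the effective
RNA/DNA ratio barcode-dependent — a config switch
(`alpha_placement="multiplier"`) provides the conventional
`α · exp(X_d β)` form instead. Multi-condition designs add a per-condition
log effect to the RNA log-mean (a vector shared by all sequences, or a
per-sequence matrix) and by default share one DNA library across conditions
(un-paired); negative controls are appended at basal rate α = 1.

The **model-matched generator** draws `D ~ NB(exp(X_d β), k)` and
`R ~ NB(α · exp(X_d β), k)` — the fitted model's own observation layer,
with α always multiplicative — for exact parameter-recovery and
test-calibration studies. Its default dispersion `k = 10` represents the
moderate overdispersion of deeply sequenced libraries; recovery degrades
gracefully at smaller `k` (noisier libraries).

What the generators do *not* emulate: barcode dropout and recombination,
GC/length-dependent amplification bias, correlated errors between the DNA
and RNA libraries of a sample, and integration-site effects in lentiviral
protocols. Passing simulation benchmarks therefore demonstrates correctness
of the estimator and tests under the stated noise families, not robustness
to every artefact of real libraries.

## Validation studies and problem sizes

`mpraglm.validation` runs the package's self-checks end to end; the
acceptance script reports their numbers and `tests/test_acceptance.py`
asserts them. Sizes were chosen to make each check statistically meaningful
while keeping the full suite to a few minutes on one CPU:

- closed-form NB identity vs quadrature over a 48-point parameter grid
  (tolerance 1e−8 on the log scale);
- LRT null calibration: 1000 sequences, two un-paired conditions, 30
  barcodes × 3 batches, KS uniformity at the 1% level;
- rate recovery: 200 sequences, rates uniform on [0.2, 3], Spearman ≥ 0.95
  and median relative error ≤ 5%;
- estimator precision: SD(estimate − truth) across the 281-sequence grid at
  5/15/30/60 barcodes; the model estimate must not exceed the mean ratio at
  any count;
- classification false positives: 1000 basal sequences, 200 controls,
  flagged fraction ≤ 5% + 3 binomial SEs at BH-FDR 0.05;
- down-sampling bias: 60 sequences × 90 barcodes, rates 15/30/45/60/75 × 3
  replicates; |mean bias| < 2 SE per rate and estimator, with sequences as
  the independent units (replicate draws of one sequence are correlated, so
  deviations are averaged within sequence before the SE);
- control-offset correction: a global 2× condition shift on 150 candidates
  + 40 controls; corrected p-values uniform, uncorrected analysis calls
  ≈100% differential.

## Known limitations

- DNA coefficients are plug-in in the RNA layer; rate uncertainty is
  slightly understated for very shallow DNA libraries.
- The mode-based null assumes the majority-null, sub-mode-is-null heuristic;
  with mostly-active libraries it under-calls activity by design
  (conservative), and its spread estimator relies on the reflection
  construction.
- No empirical-Bayes shrinkage of dispersions across sequences, no
  zero-inflated variants, and no TMM/median-of-ratios normalization
  alternatives.
- Per-sequence LRTs are asymptotic; with very few barcodes (<5) and shallow
  counts the χ² reference degrades.
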