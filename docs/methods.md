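# Methods

This note records the models, estimators, parameter defaults and numerical
choices implemented in `sdmnstates`, plus the known limitations of each.

## 1. Study design

| object | default |
|---|---|
| treatments | `control`, `mirror`, `winner`, `loser` |
| group sizes | 10 / 12 / 12 / 11 (one staged dyad loses its loser: 12 dyads staged, 11 complete) |
| nuclei | `Dm`, `Dl`, `Vv`, `Vs`, `POA` |
| target genes | `bdnf`, `npas4`, `nlgn1`, `nlgn2`, `wnt3`, `neurod` |
| reference gene | `eef1a1l1` |
| interaction session | 30 min (1800 s) |

Winners and losers come in real dyads and share a dyad identifier; mirror
fish get a one-fish "dyad" (mirror tank), controls an isolation tank. Group
sizes, dropout and session length are configurable through `StudyDesign`
and `PipelineConfig`.

## 2. Synthetic-data generator

The generator is a forward model of the whole measurement chain with known
ground truth.

**Latent expression.** For fish *i*, nucleus *k*, gene *g* under treatment
*t*:

```
log y_ikg = mu_kg + delta_tkg + b_i + b_d(i) + e_ikg
```

with fish intercept `b_i ~ N(0, sigma_subject^2)` (default 0.3), dyad
intercept `b_d ~ N(0, sigma_dyad^2)` (default 0.2; shared within a real
dyad, zero for mirror/control) and residual vector
`e_ik. = sigma_resid * L_tk z` (default sigma_resid 0.5), where `L_tk` is
the Cholesky factor of the treatment × nucleus co-expression target matrix.
All target matrices are validated (symmetric, unit diagonal, positive
semidefinite) before sampling. The default effect specification gives each
treatment × nucleus cell either an identity matrix or one of two
block-correlation patterns (rho = 0.8), plus modest treatment shifts on a
few genes. `EffectSpec.null()` gives the zero-effect configuration used for
calibration.

**Amplification curves.** Each reaction is a logistic in cycle number:

```
F(c) = baseline + plateau / (1 + exp(-k (c - m))),   k = ln(1 + E)
```

with `m = ln(plateau / F0) / k` and `F0 = template_scale * quantity`, i.e.
the exact discrete amplification law `F0 (1+E)^c` in its continuous
saturating form. Defaults: efficiency E = 0.9, plateau 3.0, baseline 0.5,
Gaussian noise SD 0.01 (fluorescence units), 45 cycles, template_scale
2e-5 per unit quantity. Zero quantity yields a flat baseline.

**Behavior and cortisol.** Event logs (bite, chase, strike / freeze, flee)
follow the treatment phenotype: mirror fights never resolve and contain no
submissive acts; after resolution (log-normal around 420 s) losers only
freeze/flee and winners only attack; controls have no events. Cortisol is
log-normal per treatment (control 4, loser 5, winner 10, mirror 11 ng/ml,
sigma_log 0.35).

**What is emulated / what is not.** Emulated: dyadic sharing of random
effects, treatment-specific co-expression, reference-gene stability (latent
SD 0.05), CT spacing of dilutions, curve noise, unresolved-fight censoring,
dyad dropout. Not emulated: pipetting/plate effects, inter-run calibration,
primer-dimer artefacts, RNA-quality covariates, circadian or body-size
confounds, and behavioral time-series dependence beyond the resolution
split.

**Reproducibility.** Every stochastic stream derives from
`SeedSequence((seed, stream, *indices))`, so draws for one fish/reaction do
not shift when other parts of the design change, and a given seed yields
byte-identical CSVs (`float_format="%.10g"`, no timestamps).

## 3. qPCR quantification

Curves are fitted by nonlinear least squares to the four-parameter
logistic. Reactions with dynamic range < 0.2 fluorescence units are flagged
`no_amplification`. The cycle threshold is the cycle of maximum second
derivative of the fitted curve, which for a logistic is

```
CT = m - ln(2 + sqrt(3)) / k .
```

**Efficiency estimation.** E is estimated by regressing
`logit(F) = log((F - baseline) / (plateau - F))` on cycle over the window
where the fitted signal lies between 5% and 50% of plateau; the slope of
this regression equals `ln(1 + E)` *exactly* for a logistic curve. The more
common plain `log(F - baseline)` regression over the same window is biased
low (it recovers E ≈ 0.74 when the true E = 1.0) because the logistic
already deviates from pure exponential growth at 5% of plateau; the
logit form removes that bias by construction. Windows with fewer than
3 cycles flag `unreliable_efficiency`; estimates above 1.1 are capped and
flagged.

Input quantity is `R0 = exp(-CT * ln(1 + E))`, computed in the log domain
to avoid overflow/underflow. Relative expression is the target/reference
`R0` ratio per fish × nucleus; cells whose reference reaction is flagged
are dropped with a logged warning.

On noiseless curves the estimator chain is exact: E recovered to machine
precision for E ∈ {0.8, 0.9, 1.0}, 10× dilution ratios exact, CT spacing at
E = 1 equal to log2(10).

## 4. Outlier screening (gESD)

Rosner's generalized extreme studentized deviate test is applied per
treatment × nucleus × gene cell with alpha = 0.05 and at most
⌊0.2 n⌋ removals per cell (floor, so n = 10 allows 2). Cells with n < 5
are skipped and logged, never screened. The critical values are

```
lambda_i = (n - i) t_{p, n-i-1} / sqrt((n-i-1+t^2)(n-i+1)),
p = 1 - alpha / (2 (n - i + 1)),
```

and the declared outlier count is the *largest* i whose statistic exceeds
lambda_i (not the first failure). The implementation is verified against an
independently coded sequential-Grubbs brute force on 1000 random vectors.

Caveat: screening is performed on raw relative-expression values, which are
approximately log-normal; a normal-theory test on skewed data removes more
upper-tail points than the nominal rate suggests (≈ 6% of values in the
default simulation). The cap bounds the damage; users who prefer
log-scale screening can pass a transformed `value_col`.

## 5. Mixed-model contrasts

Per gene, `ExpressionLMM` fits (statsmodels `MixedLM`, REML)

```
log y ~ C(treatment) * C(nucleus) + (1 | fish) + (1 | dyad)
```

where the dyad variance component is built from explicit dummy columns
that are zero for mirror and control rows, so only real winner–loser pairs
share it. Variance components estimated at the boundary
(< 1e-8 × residual scale) are dropped and the model refitted.

`contrasts()` reports all 6 treatment pairs × 5 nuclei as linear
combinations of fixed-effect cell means with normal-theory z tests,
*unadjusted* p-values (they are planned comparisons), and Cohen's d: `d_z`
on dyad-paired differences for winner–loser, pooled `d_s` otherwise, with
magnitude labels at 0.2 / 0.5 / 0.8.

`omnibus()` reports Wald F statistics with containment denominator degrees
of freedom: the treatment term is tested against dyads
(`df2 = n_complete_dyads - 4`), within-subject terms against
`n_obs - rank(X) - n_subjects`. This is the classical split-plot
convention; with 11 complete dyads the treatment test has F(3, 7).

Calibration (500 zero-effect replicates at the default group sizes): every
per-contrast type-I rate at alpha = 0.05 falls in [0.03, 0.08]; a
1-residual-SD winner-vs-control shift is recovered with the correct sign in
≈ 98% of replicates.

## 6. Neurogenomic states

**Matrices.** Per treatment × nucleus, pairwise-complete Pearson
correlations over fish for all 15 gene pairs; per-pair two-sided p-values
BH-adjusted within the matrix. Genes with fewer than 3 observations are
marked missing (NaN row/column) and rendered grey in heatmaps. Pairwise
deletion means different cells of one matrix can rest on different fish
subsets.

**QAP.** The similarity of two matrices is the Pearson r over their upper
off-diagonal cells; the null distribution permutes rows and columns of one
matrix simultaneously (gene identity is broken, structure is kept). For
g ≤ 8 genes when g! ≤ n_perm all permutations are enumerated (720 for the
default 6 genes — the p-value is exact); otherwise Monte Carlo with the
add-one estimator `p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`, which never
returns 0. Default tail is `greater` (similarity); matrices with constant
off-diagonals are reported `undefined`, not tested.

**Partition.** Units (treatments within a nucleus, or nuclei within a
treatment) are joined by an edge when their QAP p < alpha; letter classes
are the connected components. Two caveats are deliberate properties of the
source decision rule, not of this implementation:

* *Absence of evidence*: a non-significant QAP does **not** demonstrate
  that two matrices differ; with n = 12 fish the test has modest power, so
  distinct letters should be read as "not shown similar", and intransitive
  triads (a ~ b, b ~ c, a ≁ c) are logged and reported.
* *Automorphism blind spot*: a gene permutation that maps a correlation
  pattern onto itself reproduces the observed statistic under the null.
  A pattern of two blocks of three genes has 3!·3!·2 = 72 such symmetries
  among 720 permutations, so its attainable p is ≈ 0.1 × Uniform and QAP
  can never call two such matrices similar at alpha = 0.05 — regardless of
  how strong the blocks are. This applies to the package's own default
  block-structured simulation truths; heterogeneous (automorphism-free)
  patterns do not suffer from it. Calibration of state recovery therefore
  uses a fixed two-factor-model truth (recovery ≈ 0.89 at n = 12/group).

Per-pair permutation seeds derive from one `SeedSequence`, making
partitions reproducible; the pipeline derives per-axis seeds from the
master seed via a SHA-256-based stable hash.

## 7. Auxiliary statistics

Behavior summaries: latency to first bite (censored at session length),
resolution time (mirror censored), aggressive/submissive act counts in the
last 300 s. Tests: pooled-variance t (dyad-level latency), resolution-time
comparison vs censored mirror values, Welch one-way ANOVA (closed form;
two-group Welch F equals the squared Welch t) with Tukey HSD post-hoc for
cortisol, and BH-adjusted Pearson screens linking behavior, cortisol and
expression, adjusted within each of the three screen families.

## 8. Problem sizes and runtime

Defaults are desk scale: 45 fish × 5 nuclei × 7 genes = 1575 reactions
(70 875 curve rows), one LMM fit ≈ 50–60 ms, exhaustive QAP for 6 genes
≈ 0.6 ms, the full pipeline ≈ 15 s, the full test suite (including the
calibration-scale acceptance tests) ≈ 4 min on one CPU.

## 9. Limitations

* The LMM contrasts use normal-theory z tests; with ~11 dyads the
  small-sample coverage relies on the calibration evidence above rather
  than on Satterthwaite/Kenward-Roger corrections (not implemented).
* gESD assumes normality; see the screening caveat.
* The co-expression matrices treat fish as independent; the winner–loser
  dyad dependence is ignored at this stage (as in the source analysis).
* Monte-Carlo QAP p-values have binomial noise sqrt(p(1-p)/n_perm);
  comparisons near alpha should raise `n_perm`.
* The generator's phenotype rules are deterministic archetypes (e.g.
  losers never attack post-resolution); real behavior is noisier.
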