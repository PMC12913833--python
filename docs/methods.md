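# Methods

## Design

The package implements a two-sample summary-statistics MR workflow with
three extensions: a three-step mediation decomposition, single-variant
colocalization, and a cross-omics prioritization rule. The causal
claims rest on the usual instrumental-variable assumptions — instruments
associated with the exposure, independent of confounders, and affecting
the outcome only through the exposure — and each module either enforces
a proxy for one of these (instrument QC), estimates under weaker
versions of them (Egger/median/mode), or quantifies the evidence that a
shared variant drives two signals (colocalization).

## Instrument quality control

Selection uses strict genome-wide significance (p < 5×10⁻⁸ by
default), greedy LD clumping in a 10,000 kb window at r² < 0.001, and a
per-SNP strength screen F = (β/se)² > 10. The clumping algorithm is the
de-facto standard greedy rule: the lowest-p unclaimed variant indexes a
clump and claims every unclaimed same-chromosome variant within the
window at r² above threshold; ties on p break by (chromosome, position,
identifier) so results are order-independent. Distances are
center-to-center; different chromosomes never clump.

F uses the (β/se)² approximation rather than an R²-based form — both
appear in practice and the choice is documented rather than silently
assumed. Per-SNP variance explained uses the standardized-trait
approximation R² = 2·maf(1−maf)·β², summed for the power hand-off; it
requires allele frequency and fails loudly when it is missing (nothing
is imputed).

Harmonization aligns outcome to exposure effect alleles, flipping betas
for swapped allele pairs, and drops palindromic (A/T, C/G) variants
unconditionally — no frequency-based rescue, because strand cannot be
resolved from alleles alone and the ambiguity is not worth one
instrument. Confounder-associated variants arrive as a caller-supplied
exclusion list; the package never queries external trait catalogs.
Every dropped variant is tallied in exactly one provenance category.

## Estimators

* **IVW** is reported in both fixed-effect and multiplicative
  random-effects form (SE scaled by max(1, √(Q/(k−1)))). The headline
  convention is random-effects when overdispersed (Q/(k−1) > 1), else
  fixed-effect; both rows are always emitted and the choice is a
  configuration, not a hidden default.
* **MR-Egger** orients instruments to positive exposure effects and
  fits WLS with an intercept, weights 1/se²_Y. Inference uses the t
  reference with k−2 df and the estimated residual variance directly —
  no flooring — so the intercept test is exactly calibrated under the
  null when outcome SEs are correct (verified by simulation in the test
  suite).
* **Weighted median** interpolates the sorted per-SNP ratios at
  standardized cumulative weight 0.5 with first-order inverse-variance
  weights β²_X/se²_Y.
* **Simple/weighted mode** maximize a Gaussian-kernel density of the
  ratios on a 512-point grid, bandwidth 0.9·min(sd, MAD)·k^(−1/5)
  scaled by φ (default 1). All ratios identical is a degenerate but
  valid input: the common ratio is returned.
* Bootstrap SEs (median and modes) use a seeded parametric bootstrap,
  default 1,000 draws of (β̂_X, β̂_Y) from their normal sampling
  distributions; the seed is threaded from the caller so results are
  reproducible.
* Wald/IVW/median/mode p-values use the normal reference; CIs are
  β ± 1.96·se throughout.

A single-instrument exposure dispatches to the Wald ratio (se_Y/|β_X|,
first-order delta); batch estimation records per-method failures rather
than aborting.

## Diagnostics

Cochran's Q uses the per-SNP ratios around the fixed-effect IVW
estimate with weights β²_X/se²_Y, chi-square with k−1 df. Leave-one-out
re-fits fixed-effect IVW (deterministic and fast) and flags a variant
when its exclusion moves the point estimate outside the full-set 95%
CI — a numeric rule chosen here, since influence plots alone carry no
threshold. The HEIDI heterogeneity test is not implemented.

## Mediation

The three-step decomposition multiplies the exposure→mediator and
mediator→outcome path coefficients; the indirect-effect SE is the
first-order Sobel delta √(β₁²se₂² + β₂²se₁²) without the se₁²se₂² term.
The proportion mediated is reported unclipped with a flag when outside
[0, 100]: sign-inconsistent paths are a finding, not a formatting
problem. When a path estimate is only available as an odds ratio with a
CI, β = ln(OR) and se = (ln hi − ln lo)/(2·1.96).

One published worked example this package reproduces prints a step-3
effect of "β = 0.008" alongside "OR = 1.082"; these are mutually
inconsistent (ln 1.082 ≈ 0.079), so the OR-derived coefficient is used
and the discrepancy is surfaced rather than resolved. With inputs
β_total = −0.030, β₁ = ln 1.082, β₂ = −0.086 the computed share is
22.59%, matching the printed 22.92% within rounding of the printed
inputs.

## Colocalization

Wakefield log-ABFs use prior effect variances 0.15² (quantitative) and
0.2² (binary, log-odds) — the field-standard defaults. The five
hypothesis sums are accumulated in log space with max-subtraction;
naive likelihood sums overflow once |z| ≳ 40. H3 uses the ordered-pair
identity (ΣABF₁)(ΣABF₂) − Σ(ABF₁ABF₂), computed via log1p for
stability. Multi-causal-variant (SuSiE-style) colocalization is out of
scope.

## Power

Two-sided power for a binary outcome uses the noncentrality
N·R²·ln(OR)²·φ(1−φ). This form is validated against a direct simulation
oracle (Wald tests at the implied SE) to within 2 percentage points;
agreement with any specific web calculator is approximate by nature.
Bonferroni-corrected power is the same formula at α/m. At the studied
design (N = 66,756, φ = 0.1689, OR = 0.97/SD, R² ∈ [0.03, 0.05]) power
is 8–10% at α = 0.05 and ≈ 0 after transcriptome-wide correction —
severely underpowered, which is the substantive conclusion.

## Prioritization

Stage-wise significance is the nominal p < 0.05 screen, with Bonferroni
and Benjamini-Hochberg adjusted values (via statsmodels) carried
alongside for transparency rather than used as the gate. DE thresholds
are strict inequalities (|log2FC| > 1, q < 0.05) as printed sources
state them. A triple-intersection gene is suppressive when both MR
betas are negative and the gene is down-regulated, oncogenic in the
mirrored case, discordant on mixed signs; direction concordance across
the eQTL and pQTL stages is required for a non-discordant call. Gene
ids match exactly after case folding — no identifier-mapping service is
consulted.

## Synthetic data

The generator works at the summary-statistic level: true per-SNP
effects plus normal noise at the analytic SE 1/√(2·maf(1−maf)·N),
inflated by 1/√(φ(1−φ)) for the binary outcome. This reproduces exactly
the sampling distribution the estimators assume, at a cost of seconds —
which is also its limitation: it cannot expose finite-sample genotype
artefacts, winner's curse from instrument discovery in the same sample,
or real LD-panel mismatch. Passing recovery tests therefore validate
the estimators' statistics, not robustness to those real-data effects.

Two disjoint 30-SNP panels instrument the exposure and the mediator;
MAFs are U(0.1, 0.4) and per-allele instrument effects U(0.1, 0.25) SD,
giving total instrument R² ≈ 0.35 — a strongly cis-heritable gene —
so recovery tests isolate estimator behavior from weak-instrument
bias (per-SNP F ≫ 10). Defaults mirror the studied regime: outcome
N = 66,756 with case fraction 0.1689, exposure panel N = 31,684,
mediator panel N = 3,757, b = −0.086, a = ln 1.082, and c′ chosen so
the total is −0.030 (mediated share 22.6%). Within-panel LD is AR(1)
with ρ configurable (default 0, the post-clumping regime; nonzero ρ
exercises the clumping stage). Directional pleiotropy adds
N(μ, σ²) shifts to the exposure-panel outcome effects. All draws flow
from one integer seed; identical seeds give byte-identical outputs.

The DE generator gives signal genes log2FC centered at ±effect_sd with
p-values 10^−U(5, 80) and null genes log2FC ~ N(0, 0.2²) with uniform
p, then one BH pass over the combined p-values.

## Calibration checks and problem sizes

The suite's heavier checks use: 200 replicates for mediation parameter
recovery (mean total-effect bias below 10% of truth; median mediated
share within 5 points), 500 null replicates for type-I error
(0.05 ± 0.02), 250 replicates for delta-CI coverage ([90%, 98%] at
nominal 95%), and 2,000 replicates for Egger intercept calibration.
The type-I check evaluates the fixed-effect IVW p-value: under the null
design the instruments are homogeneous, where the FE normal reference
is exact; the RE variant is conservative by construction (its SE is
floored at the FE value) and is the headline only under observed
overdispersion.

## Known limitations

- No proxy-SNP search, reference-panel LD computation, Steiger
  filtering, MR-PRESSO, or multivariable MR; the direct effect is
  total-minus-indirect arithmetic, not a multivariable estimate.
- Positions are assumed to share one genome build; no liftover.
- Binary-trait betas are taken to be log-odds per effect allele — a
  convention the data cannot verify.
- The colocalization module assumes at most one causal variant per
  trait in the region.
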