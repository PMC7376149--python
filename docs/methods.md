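# Methods

This note documents the statistical models implemented in `mrnet`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical details that matter for
reproducing results.

## Two-sample MR model

The data are per-SNP association summaries from two non-overlapping GWAS:
exposure effects β̂ᵢˣ ~ N(ξᵢ, (σᵢˣ)²) and outcome effects
β̂ᵢʸ ~ N(θξᵢ + αᵢ, (σᵢʸ)²), where ξᵢ is the true SNP–exposure effect, θ the
causal effect of interest, and αᵢ a horizontal-pleiotropy term that is zero
for a valid instrument. All estimators assume independent instruments
(post-clumping index SNPs) unless an LD matrix is supplied to the GSMR
routine.

### Harmonization and orientation

Exposure and outcome records are inner-joined on rsID; when the outcome
file reports the opposite effect allele the outcome beta sign is flipped,
and SNPs with irreconcilable allele pairs are dropped with a warning.
Palindromic (A/T, C/G) SNPs cannot be strand-checked without allele
frequencies, which summary tables often omit; the default keeps them under
a same-strand assumption with a warning, and a strict mode drops them.

Orientation to "per SD decrease" of the exposure handles the common
telomere-length convention where the tabulated effect allele is the
exposure-*lowering* allele (all exposure betas negative): those records get
β̂ˣ ← |β̂ˣ| with the outcome effect untouched, while records entered per the
exposure-raising allele get their outcome beta negated. The operation is
idempotent and exactly negates every Wald ratio relative to the
per-SD-increase convention.

### Instrument QC

Selection follows the conservative recipe used in summary-data MR studies:
genome-wide significance (p < 5×10⁻⁸, strict inequality), exclusion of
candidates within 1 Mb (inclusive) of any known outcome-associated locus,
and removal of candidates whose own outcome association is
Bonferroni-significant at 0.05 across the *candidate set* (multiplicity =
number of candidates, not genome-wide SNP count — the reading under which
the bundled 7-instrument set is self-consistent).

Per-instrument strength: PVE = β̂²/(β̂² + σ²N) and
F = PVE·(N−1−k)/(k(1−PVE)). The F formula takes k = number of instruments
in the fitted model; the package defaults to the single-instrument form
k = 1 because that is how per-row F columns in published instrument tables
are computed (the k = 7 form does not reproduce them). k is an exposed
parameter. One bundled row (rs10936599) carries published PVE/F values
that are arithmetically inconsistent with its own published beta/se/N —
the source GWAS presumably had a smaller unrounded SE; the fixture stores
the published numbers verbatim and the tests document the discrepancy.

### Estimators

* **Wald ratio** rᵢ = β̂ᵢʸ/β̂ᵢˣ. Default SE is first-order (σᵢʸ/|β̂ᵢˣ|);
  the second-order form adds the exposure-noise term and is never smaller.
  First-order is the default because it is the variant whose pooled results
  bracket published IVW tables most tightly; the choice is surfaced in the
  config and recorded in estimator diagnostics.
* **IVW**: inverse-variance weighted mean of the ratios. Fixed-effects
  SE = (Σwᵢ)^(−1/2); the random-effects variant is multiplicative,
  inflating the SE by max(1, √(Q/(k−1))) so the point estimate is identical
  and intervals never shrink below fixed-effects.
* **MR-Egger**: weighted least squares of β̂ʸ on β̂ˣ with a free intercept,
  weights 1/(σʸ)², requiring consistently oriented β̂ˣ. The slope is the
  causal estimate under InSIDE; the intercept estimates mean directional
  pleiotropy. SEs carry a multiplicative residual scale floored at 1
  (underdispersion is never allowed to narrow intervals). p-values use the
  normal reference by default; t(k−2) is available by flag. The WLS fit
  itself is delegated to statsmodels.
* **Weighted median**: ratios sorted, standardized cumulative weights
  sᵢ = (cumᵢ − wᵢ/2)/Σw, linear interpolation at s = 0.5. The SE is a
  parametric bootstrap (default 10,000 replicates, mandatory seed):
  resample (β̂ˣ, β̂ʸ) from their sampling normals, recompute the weighted
  median, take the SD.
* **Maximum likelihood**: the joint normal model above with αᵢ ≡ 0. The
  nuisance ξᵢ are profiled out analytically — for fixed θ the maximizer is
  ξᵢ(θ) = (β̂ᵢˣ/(σᵢˣ)² + θβ̂ᵢʸ/(σᵢʸ)²)/((σᵢˣ)⁻² + θ²(σᵢʸ)⁻²) — leaving a
  one-dimensional profile likelihood minimized by Brent's method bracketed
  at the IVW estimate (tolerance 10⁻¹⁰ on θ, max 200 iterations). A
  quasi-Newton step was tried first but loses precision on near-degenerate
  inputs (SEs near zero); Brent on the profiled objective is robust there.
  The SE is the inverse square root of the numerical profile curvature,
  which equals the observed information for θ.
* CIs use the normal quantile 1.959964 at the default 0.95 level;
  odds-ratio conversion exponentiates the estimate and both endpoints.

### Sensitivity suite

* **Cochran's Q** about any candidate effect, with χ²(k−1) upper tail.
* **Leave-one-out**: k refits; a refit is flagged if it flips the sign of
  the estimate or moves it by more than one full-sample SE.
* **MR-PRESSO**: observed statistic = weighted leave-one-out residual sum
  of squares about the IVW slope; the null distribution is simulated
  (default 10,000 draws, seeded) by regenerating both betas from their
  sampling normals under the leave-one-out slopes. The global p uses the
  (r+1)/(n+1) permutation convention, so it is never exactly zero.
  Per-SNP outlier p-values compare each observed residual to its own
  simulated distribution, Bonferroni-corrected over the k instruments
  (flag when corrected p < 0.05). The distortion test is not implemented.
* **GSMR / HEIDI**: HEIDI-outlier first removes instruments whose ratio
  deviates from the reference instrument's ratio with p below the
  threshold (default 0.01, GSMR convention); the reference is the
  strongest instrument by |β̂ˣ|/σˣ (the smallest-exposure-p convention) and
  is exposed as a parameter. The survivors are combined by GLS with ratio
  covariance Σᵢⱼ = ρᵢⱼ·seᵢ·seⱼ induced by the LD correlation matrix ρ. The
  LD matrix is an input artifact (TSV with an rsID header; identity by
  default) — deriving it from a genotype reference panel is out of scope.
  With identity LD and no removals GSMR reproduces fixed-effects IVW to
  machine precision, a tested invariant. At threshold 1 everything but the
  reference is removed and the estimate falls back to its Wald ratio.

### Mediation (network MR)

Paths a (exposure→mediator), b (mediator→outcome) and c (exposure→outcome)
are each estimated by *univariable* IVW from their own harmonized set —
b deliberately is not a multivariable estimate adjusted for the exposure,
matching how published three-path tables are constructed; this makes a·b
an approximation that is exact only for linear, non-interacting paths, and
the caveat is stated here rather than patched over. The mediation effect
is ab with first-order Sobel SE S_ab = √(a²SE(b)² + b²SE(a)²); the
second-order (Aroian) variant adding SE(a)²SE(b)² sits behind a flag.
First-order is the default because it reproduces published S_ab values at
3-decimal rounding. Z = ab/S_ab with a two-sided normal p; rows with
p < 0.1 are labelled "suggestive". The direct effect c′ = c − ab is
computed as derived output. The degenerate a = b = 0 case returns Z = 0,
p = 1 with a warning. Mediator units across populations are aligned by a
generic rescaling (β and SE multiplied by a positive factor); the specific
lipid conversion constants are inputs, not package data.

Published Z statistics are not exactly recovered from rounded printed path
coefficients (e.g. 1.70 vs a published 1.754 for the LDL path, p 0.106 vs
0.092 for TC): the source analyses used unrounded estimates. Tests
therefore assert ab and S_ab at the printed 3-decimal rounding and treat
borderline suggestive flags accordingly.

### Power

Analytic two-sided power for a binary outcome uses the non-centrality
approximation λ = log(OR)·√(n·R²·K(1−K)) with power
Φ(−z_{1−α/2}+λ) + Φ(−z_{1−α/2}−λ); at OR = 1 this returns α exactly, it
is symmetric in OR ↔ 1/OR, monotone in n, R² and |log OR|, and maximized
at case fraction K = 0.5. Effects are entered as OR per SD of exposure
and converted to log odds internally.

## Synthetic-data generator

`mrnet.simulate` draws the exact structure the estimators assume: true
effects ξᵢ ~ N(μ_ξ, σ_ξ²), observed β̂ˣ and β̂ʸ with sampling noise, optional
balanced or directional pleiotropy (αᵢ ~ N(μ_α, σ_α²)), optional
ratio-SE-scaled outlier shifts, and an optional mediator layer in which
the total exposure→outcome effect is direct + a·b by construction. SEs
follow the simplest model consistent with the power formula:
σˣ = 1/√n_exp and σʸ = 1/√(n_out·K(1−K)).

Defaults emulate the telomere→ALS design the package was validated on:
k = 7 instruments, ξ ~ N(0.066, 0.011²) (the bundled instruments'
oriented-effect moments), n_exp = 37,684, n_out = 80,610, K = 0.258.
One global seed spawns independent child streams for true effects,
exposure noise, outcome noise, pleiotropy and the mediator layer, so
enabling one feature never perturbs the draws of another.

What the generator does **not** emulate: LD between instruments, allele
frequencies and strand ambiguity, winner's-curse selection of instruments,
sample overlap between the two GWAS, and non-normal effect distributions.
Passing simulation tests therefore validate the estimators under their own
assumptions; they do not certify behaviour under selection bias or overlap.

A consequence worth knowing: with study-scale exposure SEs the instrument
reliability σ_ξ²/(σ_ξ²+σˣ²) is ≈ 0.82, so MR-Egger's slope attenuates by
that factor (the NOME condition fails). The Egger recovery tests
accordingly use a large exposure GWAS (n_exp = 10⁶) where NOME holds;
IVW-family estimators are insensitive to this at these noise levels.

## Monte-Carlo test scales

Parameter recovery: 500 replicates at k = 50, θ = 0.1. Null coverage:
500 replicates at k = 20. MR-PRESSO calibration: 200 replicates at the
1,000-simulation floor. Egger intercept calibration under balanced
pleiotropy: 500 replicates at k = 30, σ_α = 0.002. These sizes put
2 Monte-Carlo SEs well inside the asserted bands while keeping the whole
suite in the tens of seconds.

## Known limitations

* No multivariable MR, MR-RAPS, mode-based estimation, Steiger filtering
  or bidirectional analysis.
* The MR-PRESSO distortion test is omitted.
* LD matrices are consumed, never estimated.
* Published results computed from unrounded source data are reproduced
  only to input-rounding tolerance (documented per quantity in the tests).
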