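# mrnet

Two-sample and network Mendelian randomization (MR) from GWAS summary
statistics, built around a concrete epidemiological question: does shorter
leukocyte telomere length (LTL) causally affect the risk of amyotrophic
lateral sclerosis (ALS) or frontotemporal dementia (FTD), directly or
through blood lipids?

The package is aimed at analysts who have per-SNP association tables
(effect sizes, standard errors, p-values, sample sizes) from two
non-overlapping GWAS and want a complete, reproducible MR workflow:
instrument selection and strength QC, six causal estimators, outlier and
pleiotropy sensitivity analyses, product-of-coefficients mediation with
Sobel inference, and analytic power calculation.

## The model

Each instrument *i* is a SNP with estimated exposure effect
β̂ᵢˣ (SE σᵢˣ) and outcome effect β̂ᵢʸ (SE σᵢʸ). Under the instrumental
variable assumptions the per-SNP Wald ratio rᵢ = β̂ᵢʸ / β̂ᵢˣ estimates the
causal effect θ, and the fixed-effects inverse-variance weighted (IVW)
estimate pools them:

    θ̂ = Σ wᵢ rᵢ / Σ wᵢ,   wᵢ = 1/se(rᵢ)²,   se(rᵢ) = σᵢʸ/|β̂ᵢˣ|

For a binary outcome θ is a log odds ratio per SD of exposure; effects can
be re-signed so the contrast is per SD *decrease* (the effect allele
becomes the exposure-lowering allele). Alongside IVW the package fits
MR-Egger (free pleiotropy intercept), the weighted median, a profile
maximum-likelihood model, and a GSMR-style generalized least squares
estimator with HEIDI outlier screening; Cochran's Q, leave-one-out and
MR-PRESSO complete the sensitivity suite. Network MR decomposes a total
effect c into an indirect path a·b through a mediator, with the Sobel
standard error S_ab = √(a²SE(b)² + b²SE(a)²).

Instrument strength is screened by the per-SNP variance explained
PVE = β̂²/(β̂² + σ²N) and F = PVE(N−2)/(1−PVE), with F > 10 the
conventional weak-instrument bar.

## Worked example

The package bundles the seven European LTL instruments with their ALS
effects, exactly as published:

```python
from mrnet import load_fixture, orient_to_decrease, ivw, to_odds_ratio

hs = orient_to_decrease(load_fixture("eur_ltl_als"))
est = ivw(hs, mode="fixed", order="first")
print(f"beta = {est.beta:.4f}, se = {est.se:.4f}")
or_, lo, hi = to_odds_ratio(est)
print(f"OR per SD decrease of LTL = {or_:.2f} (95% CI {lo:.2f}-{hi:.2f}, "
      f"p = {est.p:.3f})")
```

prints

```
beta = 0.1093, se = 0.0928
OR per SD decrease of LTL = 1.12 (95% CI 0.93-1.34, p = 0.239)
```

i.e. each SD of telomere shortening multiplies the odds of ALS by about
1.1, with a confidence interval comfortably spanning 1 — no significant
causal effect. (Computed from the published, rounded instrument table;
the source analysis on unrounded effects reports 1.10, 0.93–1.31.)

The same workflow runs from the shell on any pair of summary files:

```sh
mr run --config study.yaml        # full pipeline + markdown report
mr mediate --config study.yaml    # network-MR mediation table
mr qc exposure.tsv                # per-instrument PVE / F
mr power --n 37684 --case-fraction 0.258 --odds-ratio 1.1 --r2 0.0126
mr simulate --k 50 --theta 0.1 --seed 1 --out sim.tsv
```

## Layout

- `mrnet.sumstats` — reading, validation, harmonization, orientation, fixtures
- `mrnet.qc` — instrument selection rules, PVE and F statistics
- `mrnet.estimators` — Wald ratio, IVW, MR-Egger, weighted median, ML
- `mrnet.sensitivity` — Cochran's Q, leave-one-out, MR-PRESSO, GSMR/HEIDI
- `mrnet.mediation` — path estimation, Sobel test, unit rescaling
- `mrnet.power` — analytic power for binary-outcome MR
- `mrnet.simulate` — synthetic summary statistics with known ground truth
- `mrnet.pipeline` / `mrnet.cli` — configured end-to-end runs, `mr` command

See `docs/methods.md` for the statistical details and design choices.
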