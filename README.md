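# ivmr

Mendelian randomization (MR) toolkit for estimating the causal effect of a
modifiable exposure — the motivating application is body-mass index (BMI) and
cardiometabolic traits in a Japanese population — from genetic instruments,
in two complementary designs:

* **Individual-level MR**: a weighted genetic risk score (GRS) built from
  exposure-associated variants instruments the exposure; causal effects on
  quantitative outcomes come from two-stage least squares (2SLS) and on
  disease outcomes from a two-stage logistic estimator, with
  instrument-validity diagnostics (first-stage F, GRS-confounder checks,
  observational contrast).
* **Two-sample MR**: per-variant summary associations from separate exposure
  and outcome GWAS are harmonized to a shared effect allele, and the causal
  effect θ is estimated by Wald ratios, inverse-variance weighting (IVW),
  MR-Egger regression, the weighted median, MR-PRESSO outlier correction and
  multivariable MR (MVMR).

For harmonized instruments j = 1..m with exposure effects γ̂_j (SE σ_xj) and
outcome effects Γ̂_j (SE σ_yj), the core estimators are

* Wald ratio: θ̂_j = Γ̂_j / γ̂_j, se = σ_yj / |γ̂_j|;
* IVW: θ̂ = Σ w_j γ̂_j Γ̂_j / Σ w_j γ̂_j², w_j = σ_yj⁻² (zero-intercept
  weighted regression of Γ̂ on γ̂), fixed-effect or multiplicative
  random-effects SEs, heterogeneity by Cochran's Q;
* MR-Egger: weighted regression with a free intercept after orienting all
  γ̂_j ≥ 0 — the intercept estimates average directional pleiotropy under
  the InSIDE assumption, the slope is the pleiotropy-corrected effect;
* weighted median: the 50% weighted quantile of the ordered ratio estimates,
  consistent when at least half the weight comes from valid instruments;
* MR-PRESSO: a simulation-based global test on leave-one-out residual sums
  of squares, a per-variant outlier test, and an iterative exclusion loop
  with an outlier-corrected IVW estimate;
* MVMR: weighted multivariable regression of Γ̂ on several exposures'
  effect columns, estimating each exposure's direct effect.

A seeded synthetic-data module generates cohorts and two-sample summary
statistics with known ground truth (causal effect, per-variant pleiotropy,
confounding), so every estimator is verified by parameter recovery.

## Worked example

```python
from ivmr.simulate import SimConfig, gen_summary_stats
from ivmr.sumstats import harmonize
from ivmr.estimators import ivw, egger, weighted_median
from ivmr.presso import presso_loop

exposure, outcome, truth = gen_summary_stats(SimConfig(seed=7, true_theta=0.2))
instruments, report = harmonize(exposure, outcome)

est = ivw(instruments)
eg = egger(instruments)
wm = weighted_median(instruments, n_boot=1000, seed=1)
pr = presso_loop(instruments, n_sim=5000, seed=2)
```

prints (via the obvious format calls):

```
harmonized 85 instruments (dropped: 0)
IVW      beta=0.206 (95% CI 0.161-0.251), p=2.92e-19, Q=67.2 (df=84)
Egger    beta=0.180, intercept=0.0007 (p=0.67)
W-median beta=0.200 (se 0.034)
PRESSO   global_p=0.905, outliers removed: []
```

The generator planted a true causal effect of 0.2 with no pleiotropy: all
four estimators recover it (IVW 0.206, weighted median 0.200), the Egger
intercept is indistinguishable from zero (no directional pleiotropy), Q
shows no excess heterogeneity over its 84 degrees of freedom, and the
MR-PRESSO global test finds no outlying variants.

A command-line interface wraps the same pipeline:

```bash
ivmr simulate --kind summary --seed 5 --out-dir sim/
ivmr harmonize --exposure sim/exposure.tsv --outcome sim/outcome.tsv --out instruments.tsv
ivmr mr-twosample --instruments SBP=instruments.tsv --seed 3 --out forest.tsv
```

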