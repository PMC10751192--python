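# Methods

## Design

Mendelian randomization treats genetic variants as instrumental variables
for a modifiable exposure: because alleles are assigned at conception, a
variant that (i) associates with the exposure, (ii) shares no unmeasured
cause with the outcome, and (iii) affects the outcome only through the
exposure identifies the causal effect of the exposure free of the reverse
causation and confounding that contaminate observational estimates. The
package implements both standard designs around BMI and cardiometabolic
traits: an individual-level arm (genotypes, phenotypes and covariates on
one cohort) and a two-sample arm (per-variant summary statistics from
separate exposure and outcome GWAS).

## Individual-level arm

**Genotype QC.** Variants are excluded on call rate < 0.98, Hardy-Weinberg
equilibrium exact-test P < 1e-6, or minor allele frequency < 0.01 (all
comparisons strict, as configured); samples are retained at call rate
≥ 0.99 (inclusive). MAF uses mean dosage / 2 over non-missing entries. The
HWE exact test conditions on the observed allele counts and sums the
probabilities of all heterozygote counts no more probable than the observed
one (the Wigginton/Cutler/Abecasis two-sided convention). Because the exact
test is defined on genotype counts, it runs on hard-callable dosages only
(|dosage − round(dosage)| < 0.1); fractional imputed dosages contribute to
MAF and call rate but not HWE. Each filter is evaluated on the input
matrix, so the retained set is independent of rule order.

**Phenotype derivations.** LDL cholesterol follows Friedewald
(TC − HDL − TG/5 mg/dL), missing when TG ≥ 400 mg/dL. eGFR uses the
Japanese-population creatinine equation
194 · creatinine^−1.094 · age^−0.287 (× 0.739 for women), which is strictly
decreasing in both arguments. Type 2 diabetes is a composite of
self-report, glucose-lowering medication, or HbA1c ≥ 6.5% (inclusive;
missing HbA1c contributes false). Right-skewed traits (TG, LDL) are
natural-log transformed; non-positive values are set missing and counted
rather than propagated.

**GRS and estimators.** Per-variant weights are the age/sex-adjusted OLS
slopes of the exposure on dosage, complete-case per variant; constant or
under-observed variants are excluded with a warning. The score is the
weight-dosage dot product over non-missing variants; a sample missing more
than 5% of the weighted variants gets a missing score (an implementation
safeguard — a silently deflated score would bias the first stage). Weights
are fit in-sample, as cohort analyses of this kind usually do; this carries
a winner's-curse caveat (in-sample weights overstate instrument strength),
and externally estimated weights can be supplied instead.

2SLS regresses the exposure on the GRS plus age/sex (first stage), then the
outcome on the fitted exposure plus age/sex. Standard errors are the proper
instrumental-variable ones: residuals use the *observed* exposure in the
structural equation, variance σ̂²(X̂'X̂)⁻¹ (homoskedastic IV sandwich),
matching normal-theory confidence intervals. The first-stage partial F for
the GRS is reported; F < 1 raises a weak-instrument flag. With one
instrument, 2SLS equals the covariate-adjusted ratio of reduced-form to
first-stage slopes (verified to 1e-8 against an algebraic identity and
cross-checked against the statsmodels IV routine).

For binary outcomes the two-stage estimator feeds the genetically predicted
exposure into a logistic second stage, returning log-odds per exposure
unit. The default SE is the unadjusted second-stage logistic SE — the
two-stage literature notes this is approximate because it ignores
first-stage uncertainty — with a seeded nonparametric bootstrap (default
B = 500) available. Stage one can instrument on the GRS (default) or on the
full variant set; both are exposed because published descriptions of this
estimator are ambiguous between them.

Diagnostics: the GRS is regressed against behavioural confounders
(Brinkman index, alcohol g/day, METs/day) with age/sex adjustment — a valid
instrument should show nothing — and plain covariate-adjusted
observational associations are provided for the MR-versus-observational
contrast.

## Two-sample arm

**Harmonization.** Variants are matched by rsID (positions optional).
Outcome effects are aligned to the exposure effect allele: swapped alleles
negate the outcome beta; strand complements are resolved by complementing
outcome alleles first. Palindromic (A/T, C/G) variants cannot be resolved
from alleles alone; the policy is configurable: `drop`,
`infer-by-frequency` (default: orient so the effect-allele frequencies
agree within 0.2, usable only when both EAFs are present and outside
[0.42, 0.58]), or `keep-as-is`. The 0.42–0.58 ambiguity window and the 0.2
matching tolerance are the conventional safeguards for frequency-based
strand inference. Every dropped row or variant is counted with a reason —
silent data loss is disallowed throughout the I/O layer.

Proxy substitution resolves an instrument manifest (available leads kept,
unavailable leads replaced by their listed proxy, leads with no proxy
dropped with accounting). LD metrics of proxies are carried into the report
but not thresholded at runtime: accepting a proxy is the manifest author's
decision.

**Estimators.** Formulas as in the README. Numerical conventions:

* p-values are two-sided normal-theory; CIs use ±1.96·SE, matching how such
  estimates are conventionally printed.
* IVW defaults to the multiplicative random-effects model — SE inflated by
  max(1, √(Q/(m−1))) — which is conservative under heterogeneity and equals
  the fixed-effect model otherwise. The floor at 1 means the model never
  *anti*-inflates; as a consequence it is slightly conservative even under
  a clean null, so the calibration studies (bias, coverage, type-I error)
  are run under the fixed-effect model, whose nominal SE is exact under the
  generating null.
* Egger orients instruments to γ̂_j ≥ 0 before fitting (estimates must not
  depend on arbitrary allele coding; verified by a random-preflip
  invariance test). Identical γ̂ after orientation is a collinearity error.
* The weighted median uses first-order ratio SEs σ_yj/|γ̂_j| for its
  weights (the standard simplification; a second-order option adds the
  exposure-side term), midpoint cumulative weights with linear
  interpolation, and a seeded parametric bootstrap (default B = 1000) for
  its SE. Results are bit-reproducible given the seed.
* Finite-sample behaviour under one-sided contamination: with a fraction π
  of invalid instruments all displaced in one direction, the weighted
  median sits near the 0.5/(1−π) weighted quantile of the valid ratio
  distribution, a shift proportional to the ratio-noise scale that
  saturates once the invalid ratios separate — while IVW's displacement
  grows linearly with the pleiotropic effect. The robustness study uses
  40% invalid instruments with direct effects of mean 0.05 (≈10× the
  median causal path per variant, i.e. gross directional pleiotropy): IVW
  is displaced by ≈11 Monte-Carlo SEs, the weighted median stays within 3.

**MR-PRESSO.** The observed statistic is the weighted residual sum of
squares Σ σ_yj⁻² (Γ̂_j − γ̂_j θ̂_(−j))² with θ̂_(−j) the leave-one-out IVW
estimate; the null distribution comes from parametric simulation
Γ*_j ~ N(γ̂_j θ̂_(−j), σ_yj), recomputing leave-one-out residuals per
replicate (default 1000 draws; the planted-outlier studies use 5000). The
per-variant outlier test refers each variant's observed residual
contribution to its own simulated distribution, Bonferroni-adjusted over
the variant count. The exclusion loop removes, per iteration, the variant
with the smallest outlier p (ties towards the larger residual, adjusted
p below 0.05) until the global test clears 1e-6, no variant is removable,
or fewer than four remain; one-variant-at-a-time removal keeps the loop
deterministic. Empirical p-values are reported with the add-one estimator
(1+#)/(n_sim+1), which is never zero but consequently has resolution
1/(n_sim+1); the loop's *decision* therefore uses the plug-in exceedance
proportion #/n_sim, which reaches zero when the observed RSS exceeds every
simulated one — otherwise a 1e-6 stopping rule would be unreachable at any
practical simulation count. The distortion diagnostic (relative difference
between raw and corrected estimates) is available but off by default.

**MVMR** is weighted least squares of Γ̂ on the k exposure-effect columns,
no intercept, weights σ_yj⁻², with the same random-effects floor on the
residual scale; with k = 1 it reduces exactly to univariable IVW.
Conditional instrument-strength statistics are out of scope.

## Synthetic data

The generators encode the data-generating process the estimators assume,
with every draw recorded in a `SimTruth`.

*Cohort*: m independent biallelic loci, dosages Binomial(2, MAF),
MAF ~ U(0.05, 0.5); exposure = mean + Σ γ_j (g_j − 2·MAF_j) + λ₁U + ε with
a standard-normal latent confounder U; outcomes linear (or logistic with a
prevalence-calibrated intercept) in the centred exposure and U.
Behavioural covariates are generated independent of genotype — the world in
which the instrument is valid. Defaults emulate a middle-aged Japanese
cohort: age ~ N(54.7, 9), 57.2% female, BMI mean 23.0 kg/m², SD 3.3
(the SD is a package choice of a realistic cohort value). Per-allele
effects are N(0.025, 0.008) exposure-SD units, rescaled to BMI units; over
85 loci this puts ≈2% of exposure variance on the score (what BMI
instruments achieve in large cohorts) and yields first-stage F in the
hundreds at n = 10,000. Confounder loadings default to (0.5, 0.5).

*Summary statistics*: γ̂_j ~ N(γ_j, σ_xj), Γ̂_j ~ N(θγ_j + α_j, σ_yj) with
σ ≈ (2n·MAF(1−MAF))^(−1/2), the standard per-allele SE for a standardized
trait; exposure and outcome draws are independent (a true two-sample
design; sample overlap is deliberately not modelled). Defaults: 85
instruments, exposure GWAS n = 173,430, outcome GWAS n = 100,000 (the
scale of large Japanese biobank GWAS). Direct effects α_j are zero for
valid instruments; an invalid fraction draws α_j ~ N(mean, sd), optionally
correlated with γ_j to violate InSIDE. A winner's-curse flag restricts
export to exposure p < 5e-8.

What the generators do **not** emulate — and hence what passing recovery
tests cannot certify on real data: linkage disequilibrium between
instruments (loci are independent, as in a pruned instrument set),
population stratification and relatedness, exposure-SE heteroskedasticity
beyond the MAF term, assortative mating, sample overlap between the two
GWAS, and selection effects other than the optional significance filter.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit seed (numpy `default_rng`;
the PRESSO loop derives per-iteration streams from a `SeedSequence`), and
identical seeds reproduce results bit-for-bit. The simulation studies use
500 replicates for IVW bias/coverage, 2000 for type-I error, 60 for the
contamination study, 5000 PRESSO draws with 20 null replicates, and one
n = 10,000 cohort for the individual-level arm — sizes at which the
Monte-Carlo error of each check is several times smaller than the margin
it is judged against. The exhaustive HWE validation covers every genotype
table of up to 200 individuals against an exact integer-arithmetic
enumeration (agreement to 1e-12; the implementation evaluates the same
distribution in log-space with a 1e-9 relative tie tolerance absorbing
floating-point round-off at exactly tied probabilities).

## Known limitations

* The IVW recovery studies show the expected ≈2% regression-dilution
  attenuation from exposure-side estimation noise (mean estimate ≈0.195
  for θ = 0.2 at the default GWAS sizes); no NOME/weak-instrument
  correction (e.g. I²_GX-based) is applied.
* Two-stage logistic SEs ignore first-stage uncertainty unless the
  bootstrap is enabled, and log-odds estimates are non-collapsible across
  covariate sets.
* The weighted median retains a finite-sample shift under one-sided
  contamination (quantified above); its bootstrap SE is parametric in the
  observed summary statistics.
* MR-PRESSO's simulated null matches the published description of the
  method rather than any specific software's internals; exact numerical
  agreement with other implementations is not a goal.
* In-sample GRS weights overstate instrument strength (winner's curse);
  the generator's selection flag exists precisely to quantify this.
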