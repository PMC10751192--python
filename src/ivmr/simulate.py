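"""Seeded generators for cohorts and two-sample GWAS summary statistics.

The generators emulate the statistical structure the MR analysis assumes:

* **Individual cohort** — biallelic SNP dosages at independent loci
  (Binomial(2, MAF)), an exposure (BMI, kg/m²) built from additive per-allele
  genetic effects plus an unmeasured standard-normal confounder and noise,
  and outcomes that are linear (or logistic, for disease flags) in the
  exposure and confounder.  Age, sex and behavioural covariates (Brinkman
  index, alcohol, METs) are drawn to match a middle-aged Japanese cohort
  (mean age ≈ 54.7 y, 57.2% female, mean BMI ≈ 23.0, SD ≈ 3.3) and are
  independent of genotype by default, as instrument validity requires.

* **Two-sample summary statistics** — true per-allele exposure effects γ_j,
  estimated with noise σ_xj ≈ (2 n_x MAF(1−MAF))^(−1/2); outcome effects
  Γ_j = θγ_j + α_j estimated with σ_yj from the outcome GWAS size.  Direct
  (pleiotropic) effects α_j are zero for valid instruments; a configurable
  fraction of invalid instruments draws α_j from a normal distribution,
  optionally correlated with γ_j to violate the InSIDE assumption.  Exposure
  and outcome draws are independent (a true two-sample design).

Every generated artifact carries a :class:`SimTruth` recording the
generating parameters, so estimator recovery can be scored exactly.
Defaults follow the instrument count (85 loci) and GWAS sizes
(exposure n = 173,430; outcome n = 100,000) of a large Japanese BMI MR
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import InputDataError
from .qc import GenotypeMatrix
from .sumstats import HarmonizedInstrument, SummaryStatRecord

__all__ = [
    "PleiotropyConfig",
    "SimConfig",
    "SimTruth",
    "gen_individual_cohort",
    "gen_summary_stats",
    "gen_instruments",
    "sumstats_frame",
]


@dataclass(frozen=True)
class PleiotropyConfig:
    """Horizontal-pleiotropy regime for the summary-statistic generator."""

    proportion_invalid: float = 0.0
    direct_effect_mean: float = 0.0
    direct_effect_sd: float = 0.0
    inside_violation: bool = False
    correlation: float = 0.0  # Corr(alpha_j, gamma_j) when InSIDE is violated

    def __post_init__(self):
        if not (0.0 <= self.proportion_invalid <= 1.0):
            raise InputDataError("proportion_invalid must be in [0, 1]")
        if not (-1.0 <= self.correlation <= 1.0):
            raise InputDataError("correlation must be in [-1, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for both simulation arms.

    ``snp_effect_dist`` is the (mean, sd) of the true per-allele exposure
    effects in exposure-SD units; the cohort generator rescales them to
    BMI units through ``exposure_sd``.  Effects of this size (~0.025 SD per
    allele across 85 loci) put roughly 2% of exposure variance on the score,
    matching what BMI instruments achieve in large cohorts.
    """

    n_individuals: int = 10_000
    m_snps: int = 85
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_theta: float = 0.2
    snp_effect_dist: tuple[float, float] = (0.025, 0.008)
    confounder_effect: tuple[float, float] = (0.5, 0.5)  # (on exposure, on outcome)
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    outcome_type: Literal["quantitative", "binary"] = "quantitative"
    baseline_prevalence: float = 0.05
    outcome_noise_sd: float = 1.0
    gwas_n_exposure: int = 173_430
    gwas_n_outcome: int = 100_000
    exposure_mean: float = 23.0   # BMI marginals of a middle-aged Japanese cohort
    exposure_sd: float = 3.3
    age_mean: float = 54.7
    age_sd: float = 9.0
    prop_female: float = 0.572
    select_genomewide: bool = False  # winner's-curse emulation: export only p<5e-8
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InputDataError("maf_range must lie within (0, 0.5]")
        if self.n_individuals < 1 or self.m_snps < 1:
            raise InputDataError("n_individuals and m_snps must be positive")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise InputDataError("baseline_prevalence must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth stored alongside every generated dataset."""

    theta: float
    gamma: np.ndarray          # per-allele exposure effects (generator units)
    alpha: np.ndarray          # direct (pleiotropic) effects on the outcome
    invalid: np.ndarray        # boolean mask of invalid instruments
    maf: np.ndarray
    confounder_effect: tuple[float, float]
    seed: int
    extra: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {
            "theta": self.theta,
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "invalid": self.invalid.astype(bool).tolist(),
            "maf": self.maf.tolist(),
            "confounder_effect": list(self.confounder_effect),
            "seed": self.seed,
            "extra": self.extra,
        }
        return d


def _snp_ids(m: int) -> list[str]:
    return [f"rs{1000 + j}" for j in range(m)]


def gen_individual_cohort(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Generate a cohort: dosage matrix, phenotype table and ground truth.

    Exposure model (BMI units):
    ``bmi = μ + Σ_j γ_j (g_j − 2·MAF_j) + λ₁ U + ε`` with U ~ N(0,1) latent
    and ε scaled so Var(bmi) matches ``exposure_sd²``.  Quantitative outcome:
    ``y = θ·(bmi − μ) + λ₂ U + ε′``; binary outcome: logistic in the same
    linear predictor with intercept set to the configured baseline
    prevalence.  Behavioural confounders are generated independent of
    genotype (a valid-instrument world); the IV-confounder check should find
    nothing.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.m_snps
    maf = rng.uniform(*cfg.maf_range, size=m)
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)

    mean, sd = cfg.snp_effect_dist
    gamma = rng.normal(mean, sd, size=m) * cfg.exposure_sd  # BMI units
    lam1, lam2 = cfg.confounder_effect
    U = rng.standard_normal(n)
    genetic = (dosages - 2 * maf) @ gamma
    var_gen = float(np.sum(2 * maf * (1 - maf) * gamma**2))
    var_eps = max(cfg.exposure_sd**2 - var_gen - lam1**2, 0.25)
    bmi = cfg.exposure_mean + genetic + lam1 * U + rng.normal(0, np.sqrt(var_eps), n)

    theta = cfg.true_theta
    linpred = theta * (bmi - cfg.exposure_mean) + lam2 * U
    if cfg.outcome_type == "binary":
        b0 = np.log(cfg.baseline_prevalence / (1 - cfg.baseline_prevalence))
        p = 1.0 / (1.0 + np.exp(-(b0 + linpred)))
        outcome = rng.binomial(1, p).astype(float)
        if outcome.sum() == 0:
            import warnings

            warnings.warn("no events generated at this prevalence and n")
    else:
        outcome = linpred + rng.normal(0, cfg.outcome_noise_sd, n)

    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 35.0, 79.0)
    sex = np.where(rng.random(n) < cfg.prop_female, "female", "male")
    # behavioural covariates: independent of genotype by construction
    smoker = rng.random(n) < 0.25
    brinkman = np.where(smoker, rng.gamma(2.0, 200.0, n), 0.0)
    drinker = rng.random(n) < 0.5
    alcohol = np.where(drinker, rng.gamma(1.5, 15.0, n), 0.0)
    mets = np.clip(rng.normal(15.0, 6.0, n), 0.0, None)

    sample_ids = [f"S{i:06d}" for i in range(n)]
    G = GenotypeMatrix(
        pd.DataFrame(dosages, index=sample_ids, columns=_snp_ids(m))
    )
    pheno = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "outcome": outcome,
            "brinkman": brinkman,
            "alcohol": alcohol,
            "mets": mets,
        },
        index=sample_ids,
    )
    truth = SimTruth(
        theta=theta,
        gamma=gamma,
        alpha=np.zeros(m),
        invalid=np.zeros(m, dtype=bool),
        maf=maf,
        confounder_effect=cfg.confounder_effect,
        seed=cfg.seed,
        extra={
            "units": "exposure in BMI kg/m^2",
            "var_genetic": var_gen,
            "var_eps": var_eps,
            "outcome_type": cfg.outcome_type,
        },
    )
    return G, pheno, truth


def _per_allele_se(n: int, maf: np.ndarray) -> np.ndarray:
    # standard approximation for a standardized trait: Var(beta_hat) ≈ 1/(2 n p q)
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def gen_summary_stats(
    config: SimConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SimTruth]:
    """Generate exposure and outcome summary statistics plus ground truth.

    Estimated effects are drawn around their true values with the
    per-allele SE implied by the configured GWAS sample sizes; the invalid
    fraction of instruments receives direct effects per the pleiotropy
    config.  With ``select_genomewide`` the exposure records are filtered at
    p < 5e-8 before export, emulating winner's-curse instrument selection.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_snps
    maf = rng.uniform(*cfg.maf_range, size=m)
    mean, sd = cfg.snp_effect_dist
    gamma = rng.normal(mean, sd, size=m)

    pl = cfg.pleiotropy
    n_invalid = int(round(pl.proportion_invalid * m))
    invalid = np.zeros(m, dtype=bool)
    invalid[rng.choice(m, size=n_invalid, replace=False)] = True
    alpha = np.zeros(m)
    if n_invalid:
        if pl.inside_violation and sd > 0:
            z_gamma = (gamma[invalid] - mean) / sd
            z = rng.standard_normal(n_invalid)
            mix = pl.correlation * z_gamma + np.sqrt(1 - pl.correlation**2) * z
            alpha[invalid] = pl.direct_effect_mean + pl.direct_effect_sd * mix
        else:
            alpha[invalid] = rng.normal(
                pl.direct_effect_mean, pl.direct_effect_sd, n_invalid
            )

    se_x = _per_allele_se(cfg.gwas_n_exposure, maf)
    se_y = _per_allele_se(cfg.gwas_n_outcome, maf)
    gamma_hat = rng.normal(gamma, se_x)
    Gamma_hat = rng.normal(cfg.true_theta * gamma + alpha, se_y)

    from scipy import stats as _st

    ids = _snp_ids(m)
    keep = np.ones(m, dtype=bool)
    p_x = 2.0 * _st.norm.sf(np.abs(gamma_hat / se_x))
    if cfg.select_genomewide:
        keep = p_x < 5e-8
    p_y = 2.0 * _st.norm.sf(np.abs(Gamma_hat / se_y))

    exposure, outcome = [], []
    for j in range(m):
        if not keep[j]:
            continue
        common = dict(
            snp_id=ids[j],
            effect_allele="A",
            other_allele="G",
            chrom=str(1 + j % 22),
            pos=10_000 + 1_000 * j,
            eaf=float(maf[j]),
        )
        exposure.append(
            SummaryStatRecord(
                beta=float(gamma_hat[j]), se=float(se_x[j]),
                pval=float(max(p_x[j], np.finfo(float).tiny)),
                n=cfg.gwas_n_exposure, **common,
            )
        )
        outcome.append(
            SummaryStatRecord(
                beta=float(Gamma_hat[j]), se=float(se_y[j]),
                pval=float(max(p_y[j], np.finfo(float).tiny)),
                n=cfg.gwas_n_outcome, **common,
            )
        )
    truth = SimTruth(
        theta=cfg.true_theta,
        gamma=gamma,
        alpha=alpha,
        invalid=invalid,
        maf=maf,
        confounder_effect=cfg.confounder_effect,
        seed=cfg.seed,
        extra={
            "units": "exposure-SD per allele",
            "mean_direct_effect": float(alpha.mean()),
            "n_exported": int(keep.sum()),
        },
    )
    return exposure, outcome, truth


def gen_instruments(
    config: SimConfig,
) -> tuple[list[HarmonizedInstrument], SimTruth]:
    """Generate already-harmonized instruments (both panels share alleles).

    Convenience wrapper around :func:`gen_summary_stats` for estimator
    studies that do not exercise the harmonization path.
    """
    exposure, outcome, truth = gen_summary_stats(config)
    instruments = [
        HarmonizedInstrument(e.snp_id, e.beta, e.se, o.beta, o.se)
        for e, o in zip(exposure, outcome)
    ]
    return instruments, truth


def sumstats_frame(records: list[SummaryStatRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the canonical column layout."""
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "POS": [r.pos for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "P": [r.pval for r in records],
            "N": [r.n for r in records],
        }
    )
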