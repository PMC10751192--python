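"""Genotype quality control and phenotype derivation.

Genotypes are held as a samples x SNPs dosage matrix (values in [0, 2],
``NaN`` for missing).  QC follows the conventional array pipeline: per-SNP
call rate, Hardy-Weinberg equilibrium exact test and minor-allele-frequency
filters, plus a per-sample call-rate filter.  Threshold comparisons are
strict as configured (SNP exclusion on call rate < 0.98, HWE exact P <
1e-6, MAF < 0.01; sample retention on call rate >= 0.99).

Phenotype derivations: Friedewald LDL (missing when TG >= 400 mg/dL), the
Japanese-population creatinine eGFR equation, a composite type 2 diabetes
definition, and natural-log transformation of right-skewed traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exceptions import ConfigurationError, InputDataError

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "read_dosages",
    "read_vcf_dosages",
    "read_phenotypes",
    "hwe_exact_test",
    "apply_snp_filters",
    "apply_sample_filter",
    "derive_ldl",
    "derive_egfr",
    "classify_t2d",
    "log_transform_skewed",
    "PHENOTYPE_COLUMNS",
]

#: Canonical phenotype/covariate columns ("NA" encodes missing on disk).
PHENOTYPE_COLUMNS = (
    "age", "sex", "bmi", "sbp", "dbp", "tg", "tc", "hdl", "ldl",
    "ua", "creatinine", "hba1c", "egfr",
    "cad", "is", "t2d_selfreport", "glucose_med", "t2d",
    "brinkman", "alcohol", "mets",
)


@dataclass
class GenotypeMatrix:
    """Dosage matrix wrapper: rows = samples, columns = SNPs, NaN = missing."""

    dosages: pd.DataFrame

    def __post_init__(self):
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 2))
        if bad:
            raise InputDataError(f"{int(bad)} dosage entries outside [0, 2]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape


@dataclass(frozen=True)
class QCThresholds:
    sample_call_rate_min: float = 0.99
    snp_call_rate_min: float = 0.98
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01

    def __post_init__(self):
        for name in ("sample_call_rate_min", "snp_call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if not (0.0 < self.hwe_p_min < 1.0):
            raise ConfigurationError("hwe_p_min must be in (0, 1)")


def read_dosages(path: str | Path) -> GenotypeMatrix:
    """Read a dosage TSV (first column sample id, header = SNP ids, NA missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0)
    return GenotypeMatrix(df.astype(float))


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read diploid unphased GTs from a (plain-text) VCF into dosages.

    Dosage counts ALT alleles; a missing GT becomes a missing dosage.
    """
    from cyvcf2 import VCF

    snp_ids, columns = [], []
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        columns.append(dos)
    if not snp_ids:
        raise InputDataError(f"no variants in {path}")
    df = pd.DataFrame(np.column_stack(columns), index=samples, columns=snp_ids)
    return GenotypeMatrix(df)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV (first column sample id, NA missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0)
    if "sex" in df.columns:
        df["sex"] = df["sex"].astype("string")
    return df


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg equilibrium exact test p-value.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of matching parity, the probabilities of configurations no more
    probable than the observed one (the Wigginton/Cutler/Abecasis
    convention).  Monomorphic tables admit a single configuration and return
    p = 1.

    Probabilities are evaluated through log-gamma and renormalized, so the
    result matches exact rational enumeration to ~1e-14 for the table sizes
    seen in array QC.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise InputDataError(f"genotype counts must be non-negative integers: {counts}")
    n = int(n_AA + n_Aa + n_aa)
    if n == 0:
        raise InputDataError("all genotype counts are zero")
    nA = 2 * int(n_AA) + int(n_Aa)  # count of allele A
    n_minor = min(nA, 2 * n - nA)
    if n_minor == 0:
        return 1.0

    # attainable heterozygote counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = n - hets - homs_minor
    # log P(h) ∝ h*log 2 − log h! − log homs_minor! − log homs_major!
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homs_minor + 1)
        - gammaln(homs_major + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = int(n_Aa)
    p_obs = probs[hets == obs]
    if p_obs.size == 0:
        raise InputDataError(
            f"heterozygote count {obs} unattainable for allele counts ({nA}, {2*n-nA})"
        )
    # relative tolerance absorbs round-off at exact probability ties
    p = probs[probs <= p_obs[0] * (1.0 + 1e-9)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

#: Fractional dosages within this distance of an integer count as hard calls.
HARD_CALL_TOL = 0.1


def _hard_call_counts(col: np.ndarray) -> tuple[int, int, int] | None:
    """Genotype counts (hom-alt, het, hom-ref) from hard-callable dosages."""
    col = col[~np.isnan(col)]
    rounded = np.round(col)
    hard = col[np.abs(col - rounded) < HARD_CALL_TOL]
    if hard.size == 0:
        return None
    g = np.round(hard).astype(int)
    return int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())


@dataclass
class SNPFilterReport:
    counts: dict[str, int] = field(default_factory=dict)  # rule -> #violations
    excluded: dict[str, list[str]] = field(default_factory=dict)  # snp -> rules


def apply_snp_filters(
    G: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, SNPFilterReport]:
    """Remove SNPs failing call-rate, HWE-exact or MAF thresholds.

    MAF is min(f, 1-f) with f = mean(dosage)/2 over non-missing entries; the
    HWE test runs on hard-called entries only, since the exact test is
    defined on genotype counts.  Rules are evaluated independently, so the
    retained set does not depend on rule order; a SNP violating several rules
    is counted once under each.
    """
    thresholds = thresholds or QCThresholds()
    vals = G.dosages.to_numpy(dtype=float)
    n = vals.shape[0]
    report = SNPFilterReport(counts={"call_rate": 0, "hwe": 0, "maf": 0})
    keep = []
    for j, snp in enumerate(G.snp_ids):
        col = vals[:, j]
        rules = []
        call_rate = 1.0 - np.isnan(col).mean() if n else 0.0
        if call_rate < thresholds.snp_call_rate_min:
            rules.append("call_rate")
        counts = _hard_call_counts(col)
        if counts is not None and sum(counts) > 0:
            if hwe_exact_test(*counts) < thresholds.hwe_p_min:
                rules.append("hwe")
        nonmiss = col[~np.isnan(col)]
        if nonmiss.size:
            f = float(nonmiss.mean()) / 2.0
            if min(f, 1.0 - f) < thresholds.maf_min:
                rules.append("maf")
        if rules:
            report.excluded[snp] = rules
            for r in rules:
                report.counts[r] += 1
        else:
            keep.append(snp)
    return GenotypeMatrix(G.dosages[keep]), report


@dataclass
class SampleFilterReport:
    n_removed: int = 0
    removed: list[str] = field(default_factory=list)
    call_rates: dict[str, float] = field(default_factory=dict)


def apply_sample_filter(
    G: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, SampleFilterReport]:
    """Remove samples whose genotype call rate falls below the retention bar."""
    thresholds = thresholds or QCThresholds()
    vals = G.dosages.to_numpy(dtype=float)
    call = 1.0 - np.isnan(vals).mean(axis=1)
    keep_mask = call >= thresholds.sample_call_rate_min
    report = SampleFilterReport()
    for sid, cr, kept in zip(G.sample_ids, call, keep_mask):
        if not kept:
            report.removed.append(sid)
            report.call_rates[sid] = float(cr)
    report.n_removed = len(report.removed)
    return GenotypeMatrix(G.dosages.loc[keep_mask]), report


# ---------------------------------------------------------------------------
# Phenotype derivations
# ---------------------------------------------------------------------------


def derive_ldl(tc: float, hdl: float, tg: float) -> float:
    """Friedewald LDL (mg/dL): TC − HDL − TG/5, missing when TG ≥ 400 mg/dL."""
    if any(pd.isna(v) for v in (tc, hdl, tg)):
        return np.nan
    if tg >= 400.0:
        return np.nan
    return float(tc - hdl - 0.2 * tg)


def derive_egfr(creatinine: float, age: float, sex: str) -> float:
    """Japanese creatinine-based eGFR (mL/min/1.73 m²).

    194 × creatinine^−1.094 × age^−0.287, × 0.739 for females.
    """
    if not (creatinine > 0 and age > 0):
        raise InputDataError("creatinine and age must be positive")
    sex = str(sex).lower()
    if sex not in ("male", "female"):
        raise InputDataError(f"sex must be 'male' or 'female', got {sex!r}")
    egfr = 194.0 * creatinine ** -1.094 * age ** -0.287
    if sex == "female":
        egfr *= 0.739
    return float(egfr)


def classify_t2d(selfreport: bool, glucose_med: bool, hba1c: float | None) -> bool:
    """Type 2 diabetes: self-report, glucose-lowering medication, or HbA1c ≥ 6.5%."""
    hba1c_high = hba1c is not None and not pd.isna(hba1c) and hba1c >= 6.5
    return bool(selfreport) or bool(glucose_med) or hba1c_high


@dataclass
class TransformReport:
    n_set_missing: dict[str, int] = field(default_factory=dict)


def log_transform_skewed(
    table: pd.DataFrame, traits: list[str]
) -> tuple[pd.DataFrame, TransformReport]:
    """Replace named right-skewed traits by their natural log.

    Non-positive values cannot be log-transformed; they are set missing and
    counted in the report rather than silently propagated.
    """
    out = table.copy()
    report = TransformReport()
    for trait in traits:
        if trait not in out.columns:
            raise ConfigurationError(f"trait {trait!r} not in phenotype table")
        col = out[trait].astype(float)
        bad = col.notna() & (col <= 0)
        report.n_set_missing[trait] = int(bad.sum())
        col = col.where(~bad)
        out[trait] = np.log(col)
    return out, report
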