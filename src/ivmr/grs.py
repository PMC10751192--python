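"""Weighted genetic risk scores and individual-level Mendelian randomization.

The individual-level arm instruments the exposure with a weighted genetic
risk score (GRS): per-SNP weights are the age/sex-adjusted per-allele
regression coefficients of the exposure, and the score is the weight-dosage
dot product.  Causal effects on quantitative outcomes come from two-stage
least squares (2SLS) with proper instrumental-variable standard errors; for
binary outcomes the two-stage estimator regresses the exposure on the
instrument and feeds the genetically predicted exposure into a logistic
model, yielding log-odds per exposure unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputDataError
from .qc import GenotypeMatrix

__all__ = [
    "GRSWeights",
    "TSLSResult",
    "fit_grs_weights",
    "compute_weighted_grs",
    "tsls_continuous",
    "two_stage_binary",
    "iv_confounder_check",
    "phenotypic_association",
]

Z95 = 1.96


@dataclass
class GRSWeights:
    """Per-SNP exposure weights (per-allele effect) with standard errors."""

    weights: pd.Series  # index = snp_id
    se: pd.Series
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.weights.index.has_duplicates:
            raise InputDataError("duplicate snp_ids in GRS weights")
        if not np.isfinite(self.weights.to_numpy()).all():
            raise InputDataError("non-finite GRS weights")


@dataclass
class TSLSResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_used: int
    first_stage_beta: float | None = None
    first_stage_F: float | None = None
    weak_instrument: bool = False


def _sex_numeric(sex: pd.Series) -> pd.Series:
    if sex.dtype.kind in "ifb":
        return sex.astype(float)
    return sex.map({"male": 0.0, "female": 1.0}).astype(float)


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    cov = covariates.copy()
    if "sex" in cov.columns:
        cov["sex"] = _sex_numeric(cov["sex"])
    return cov.astype(float)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS coefficients, standard errors and two-sided t-test p-values."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, p


def fit_grs_weights(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    exposure_trait: str = "bmi",
    min_samples: int = 30,
) -> GRSWeights:
    """Fit per-SNP exposure weights by age/sex-adjusted OLS, one SNP at a time.

    For each SNP the weight is the slope of ``exposure ~ dosage + age + sex``
    on that SNP's complete cases.  Constant-dosage SNPs (or SNPs with too few
    complete cases) are excluded with a warning: they carry no information
    and would make the regression singular.

    In-sample weight fitting mirrors the cohort design this emulates; note
    the winner's-curse caveat — weights estimated and applied in the same
    sample overstate instrument strength.  Externally estimated weights can
    be supplied directly via :class:`GRSWeights`.
    """
    pheno = pheno.loc[G.sample_ids]
    y_all = pheno[exposure_trait].astype(float).to_numpy()
    cov = _design(pheno[["age", "sex"]]).to_numpy()
    dos = G.dosages.to_numpy(dtype=float)

    weights, ses, excluded = {}, {}, []
    for j, snp in enumerate(G.snp_ids):
        col = dos[:, j]
        mask = ~(np.isnan(col) | np.isnan(y_all) | np.isnan(cov).any(axis=1))
        if mask.sum() < min_samples:
            excluded.append(snp)
            warnings.warn(f"{snp}: fewer than {min_samples} complete cases; excluded")
            continue
        x = col[mask]
        if np.ptp(x) == 0:
            excluded.append(snp)
            warnings.warn(f"{snp}: constant dosage; excluded from GRS")
            continue
        X = np.column_stack([np.ones(mask.sum()), x, cov[mask]])
        beta, se, _ = _ols(y_all[mask], X)
        weights[snp] = beta[1]
        ses[snp] = se[1]
    if not weights:
        raise InputDataError("no SNP yielded a usable GRS weight")
    return GRSWeights(pd.Series(weights), pd.Series(ses), excluded)


#: Samples missing more than this fraction of weighted SNPs get a missing score.
MAX_MISSING_FRACTION = 0.05


def compute_weighted_grs(G: GenotypeMatrix, w: GRSWeights) -> pd.Series:
    """Weighted allele score per sample: Σ_j w_j · dosage_ij over non-missing SNPs.

    Samples missing more than :data:`MAX_MISSING_FRACTION` of the weighted
    SNPs receive a missing score rather than a silently deflated one.
    """
    snps = list(w.weights.index)
    if not snps:
        raise InputDataError("empty GRS weight set")
    missing_cols = set(snps) - set(G.snp_ids)
    if missing_cols:
        raise InputDataError(f"weights reference SNPs absent from genotypes: {sorted(missing_cols)[:5]}")
    dos = G.dosages[snps].to_numpy(dtype=float)
    wv = w.weights.to_numpy(dtype=float)
    filled = np.nan_to_num(dos, nan=0.0)
    score = filled @ wv
    frac_missing = np.isnan(dos).mean(axis=1)
    score = np.where(frac_missing > MAX_MISSING_FRACTION, np.nan, score)
    return pd.Series(score, index=G.sample_ids, name="grs")


def _complete(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a.ndim == 1:
            mask &= ~np.isnan(a)
        else:
            mask &= ~np.isnan(a).any(axis=1)
    return mask


def tsls_continuous(
    grs: pd.Series,
    exposure: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    min_cases: int = 100,
) -> TSLSResult:
    """Two-stage least squares of a quantitative outcome on the exposure.

    Instruments: the GRS (plus exogenous age/sex covariates).  The reported
    standard error is the instrumental-variable one — residuals from the
    structural equation with the *observed* exposure, not the naive
    second-stage OLS error — under the homoskedastic sandwich
    ``σ̂² (X̂'X̂)⁻¹``.  The first-stage partial F statistic for the GRS is
    returned; F < 1 sets a weak-instrument flag.
    """
    z = grs.to_numpy(dtype=float)
    x = exposure.to_numpy(dtype=float)
    y = outcome.to_numpy(dtype=float)
    C = _design(covariates).to_numpy()
    mask = _complete(z, x, y, C)
    n = int(mask.sum())
    if n < min_cases:
        raise InputDataError(f"only {n} complete cases (need >= {min_cases})")
    z, x, y, C = z[mask], x[mask], y[mask], C[mask]

    ones = np.ones(n)
    W = np.column_stack([ones, C])          # exogenous regressors
    Z = np.column_stack([W, z])             # instruments
    X = np.column_stack([W, x])             # structural regressors

    # first stage: exposure on instruments; partial F for the GRS term
    b1, se1, _ = _ols(x, Z)
    fs_beta = float(b1[-1])
    fs_t = fs_beta / se1[-1]
    first_F = float(fs_t**2)

    xhat = Z @ b1
    Xhat = np.column_stack([W, xhat])
    beta_all, *_ = np.linalg.lstsq(Xhat, y, rcond=None)
    resid = y - X @ beta_all                # IV residuals use observed exposure
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(Xhat.T @ Xhat)
    beta = float(beta_all[-1])
    se = float(np.sqrt(cov[-1, -1]))
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return TSLSResult(
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=float(p),
        n_used=n,
        first_stage_beta=fs_beta,
        first_stage_F=first_F,
        weak_instrument=first_F < 1.0,
    )


def two_stage_binary(
    instrument: pd.Series | pd.DataFrame,
    exposure: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    min_events: int = 20,
    bootstrap: bool = False,
    n_boot: int = 500,
    seed: int | None = None,
) -> TSLSResult:
    """Two-stage estimator for a binary outcome (log-odds per exposure unit).

    Stage 1: OLS of exposure on the instrument(s) plus age/sex.  Stage 2:
    logistic regression of the outcome on the genetically predicted exposure
    plus age/sex.  The default standard error is the unadjusted second-stage
    logistic SE — a recognized approximation that ignores first-stage
    uncertainty; set ``bootstrap=True`` (seeded) for resampled SEs.

    ``instrument`` may be a single GRS series or a DataFrame of per-SNP
    dosages (instrumenting on the full SNP set).
    """
    import statsmodels.api as sm

    inst = instrument.to_frame() if isinstance(instrument, pd.Series) else instrument
    Zraw = inst.to_numpy(dtype=float)
    x = exposure.to_numpy(dtype=float)
    y = outcome.to_numpy(dtype=float)
    C = _design(covariates).to_numpy()
    mask = _complete(Zraw, x, y, C)
    n = int(mask.sum())
    Zraw, x, y, C = Zraw[mask], x[mask], y[mask], C[mask]

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputDataError("binary outcome has a single class")
    if counts.min() < min_events:
        raise InputDataError(
            f"need >= {min_events} observations in each outcome class, got {counts.min()}"
        )

    ones = np.ones(n)
    W = np.column_stack([ones, C])

    def _fit(z_mat, xv, yv, Wm):
        Zfull = np.column_stack([Wm, z_mat])
        b1, *_ = np.linalg.lstsq(Zfull, xv, rcond=None)
        xhat = Zfull @ b1
        X2 = np.column_stack([Wm, xhat])
        model = sm.Logit(yv, X2).fit(disp=0)
        return float(model.params[-1]), float(model.bse[-1]), b1

    beta, se, b1 = _fit(Zraw, x, y, W)
    fs_beta = float(b1[-1]) if Zraw.shape[1] == 1 else None

    if bootstrap:
        if seed is None:
            raise InputDataError("bootstrap SEs require a seed")
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                b, _, _ = _fit(Zraw[idx], x[idx], y[idx], W[idx])
            except Exception:
                continue
            boots.append(b)
        se = float(np.std(boots, ddof=1))

    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return TSLSResult(
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=float(p),
        n_used=n,
        first_stage_beta=fs_beta,
    )


def iv_confounder_check(
    grs: pd.Series,
    confounders: pd.DataFrame,
    covariates: pd.DataFrame,
    min_cases: int = 100,
) -> pd.DataFrame:
    """Test the GRS against putative confounders (instrument validity check).

    A valid instrument should be unrelated to behavioural confounders such as
    smoking (Brinkman index), alcohol intake and physical activity.  Each
    confounder is regressed on the GRS with age/sex adjustment; returns a
    table of (slope, se, p) per confounder.
    """
    z = grs.to_numpy(dtype=float)
    C = _design(covariates).to_numpy()
    rows = []
    for name in confounders.columns:
        c = confounders[name].to_numpy(dtype=float)
        mask = _complete(z, c, C)
        n = int(mask.sum())
        if n < min_cases:
            raise InputDataError(f"{name}: only {n} complete cases")
        X = np.column_stack([np.ones(n), z[mask], C[mask]])
        if np.ptp(c[mask]) == 0:
            rows.append({"confounder": name, "slope": 0.0, "se": np.nan, "p": 1.0, "n": n})
            continue
        beta, se, p = _ols(c[mask], X)
        rows.append(
            {"confounder": name, "slope": beta[1], "se": se[1], "p": p[1], "n": n}
        )
    return pd.DataFrame(rows).set_index("confounder")


def phenotypic_association(
    exposure: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    binary: bool | None = None,
) -> tuple[float, float, float]:
    """Observational exposure-outcome association (covariate-adjusted).

    Plain OLS for quantitative outcomes, logistic regression for flags
    (auto-detected when ``binary`` is None).  Provided for the
    observational-versus-MR contrast.
    """
    import statsmodels.api as sm

    x = exposure.to_numpy(dtype=float)
    y = outcome.to_numpy(dtype=float)
    C = _design(covariates).to_numpy()
    mask = _complete(x, y, C)
    x, y, C = x[mask], y[mask], C[mask]
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    X = np.column_stack([np.ones(len(x)), x, C])
    if binary:
        model = sm.Logit(y, X).fit(disp=0)
        return float(model.params[1]), float(model.bse[1]), float(model.pvalues[1])
    beta, se, p = _ols(y, X)
    return float(beta[1]), float(se[1]), float(p[1])
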