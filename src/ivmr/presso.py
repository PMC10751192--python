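"""MR-PRESSO pleiotropy tests and multivariable MR.

MR-PRESSO detects horizontal pleiotropy through simulation: the observed
residual sum of squares (each SNP's outcome effect against its
leave-one-out IVW prediction) is compared with the RSS distribution under a
no-pleiotropy parametric null.  A per-SNP outlier test localizes the signal,
and an iterative loop removes the worst outlier until the global test is no
longer significant, reporting the outlier-corrected IVW estimate.

Multivariable MR (MVMR) regresses the outcome effects on several exposures'
effect columns jointly (weighted, no intercept), estimating each exposure's
direct effect conditional on the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, Z95, ivw
from .exceptions import CollinearityError, InputDataError
from .sumstats import HarmonizedInstrument

__all__ = [
    "PressoResult",
    "MVMRResult",
    "presso_global",
    "presso_outlier_test",
    "presso_loop",
    "mvmr_ivw",
]

#: Global-test significance threshold driving the outlier-exclusion loop.
GLOBAL_ALPHA = 1e-6


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    outlier_p: pd.Series  # Bonferroni-adjusted, indexed by snp_id (final iteration)
    outliers_removed: list[str]
    n_iterations: int
    corrected: MREstimate
    n_sim: int
    seed: int
    distortion: float | None = None
    history: list[dict] = field(default_factory=list)


def _loo_theta(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates θ̂_(−j), vectorized over j."""
    Sgg = np.sum(w * g * g)
    SgG = np.sum(w * g * G)
    denom = Sgg - w * g * g
    if np.any(denom <= 0):
        raise InputDataError("leave-one-out IVW undefined (single informative SNP)")
    return (SgG - w * g * G) / denom


def _presso_sim(
    g: np.ndarray,
    G: np.ndarray,
    sG: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Observed and simulated residual statistics.

    Returns (rss_obs, per-SNP observed weighted squared residuals,
    simulated RSS vector, simulated per-SNP weighted squared residuals).
    The parametric null draws Γ*_j ~ Normal(γ_j θ̂_(−j), σ_yj) and
    recomputes the leave-one-out residuals on each replicate.
    """
    w = sG**-2
    theta_loo = _loo_theta(g, G, w)
    d_obs = w * (G - g * theta_loo) ** 2
    rss_obs = float(d_obs.sum())

    G_star = rng.normal(g * theta_loo, sG, size=(n_sim, len(g)))
    Sgg = np.sum(w * g * g)
    SgG_star = G_star @ (w * g)
    denom = Sgg - w * g * g
    theta_star = (SgG_star[:, None] - (w * g) * G_star) / denom
    d_star = w * (G_star - g * theta_star) ** 2
    rss_star = d_star.sum(axis=1)
    return rss_obs, d_obs, rss_star, d_star


def _check(instruments: Sequence[HarmonizedInstrument], n_sim: int, seed: int | None):
    if len(instruments) < 4:
        raise InputDataError("MR-PRESSO requires at least 4 instruments")
    if n_sim < 1:
        raise InputDataError("n_sim must be positive")
    if seed is None:
        raise InputDataError("MR-PRESSO simulations require a seed")
    g = np.array([i.gamma for i in instruments])
    G = np.array([i.Gamma for i in instruments])
    sG = np.array([i.se_Gamma for i in instruments])
    if np.any(sG <= 0):
        raise InputDataError("outcome standard errors must be positive")
    return g, G, sG


def presso_global(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """MR-PRESSO global test: (observed RSS, empirical p-value).

    The p-value uses the add-one estimator (1 + #{RSS* ≥ RSS_obs})/(n_sim+1),
    so it is never exactly zero; its resolution is 1/(n_sim + 1).
    """
    g, G, sG = _check(instruments, n_sim, seed)
    rng = np.random.default_rng(seed)
    rss_obs, _, rss_star, _ = _presso_sim(g, G, sG, n_sim, rng)
    global_p = (1.0 + np.sum(rss_star >= rss_obs)) / (n_sim + 1.0)
    return rss_obs, float(global_p)


def presso_outlier_test(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
) -> pd.Series:
    """Per-SNP outlier p-values, Bonferroni-adjusted over the instrument count.

    Each SNP's observed weighted squared residual is referred to its own
    simulated distribution under the no-pleiotropy null; raw empirical
    p-values are multiplied by the number of instruments and capped at 1.
    """
    g, G, sG = _check(instruments, n_sim, seed)
    rng = np.random.default_rng(seed)
    _, d_obs, _, d_star = _presso_sim(g, G, sG, n_sim, rng)
    m = len(g)
    raw = (1.0 + np.sum(d_star >= d_obs[None, :], axis=0)) / (n_sim + 1.0)
    adj = np.minimum(1.0, raw * m)
    return pd.Series(adj, index=[i.snp_id for i in instruments], name="outlier_p")


def presso_loop(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
    global_alpha: float = GLOBAL_ALPHA,
    ivw_model: str = "random",
    distortion: bool = False,
) -> PressoResult:
    """Iterative outlier exclusion until the global test is non-significant.

    Each iteration runs the global and outlier tests on the retained set; if
    the global test is significant, the SNP with the smallest outlier
    p-value (ties broken towards the larger observed residual) and adjusted
    p below ``alpha_outlier`` is removed.  The loop stops when the global
    test clears ``global_alpha``, no SNP is removable, or fewer than 4
    instruments remain; the corrected estimate is IVW on the retained set.

    Significance against ``global_alpha`` is judged on the plug-in
    exceedance proportion #{RSS* ≥ RSS_obs}/n_sim, which reaches zero when
    the observed RSS exceeds every simulated one; the add-one estimate
    reported as ``global_p`` is floored at 1/(n_sim+1) and cannot cross
    thresholds below that resolution.

    The optional distortion diagnostic reports the relative difference
    between raw and corrected estimates.
    """
    _check(instruments, n_sim, seed)
    retained = list(instruments)
    removed: list[str] = []
    history: list[dict] = []
    seedseq = np.random.SeedSequence(seed)
    rss_obs, global_p = np.nan, 1.0
    outlier_p = pd.Series(dtype=float)
    it = 0
    while True:
        it += 1
        rng = np.random.default_rng(seedseq.spawn(1)[0])
        g = np.array([i.gamma for i in retained])
        G = np.array([i.Gamma for i in retained])
        sG = np.array([i.se_Gamma for i in retained])
        rss_obs, d_obs, rss_star, d_star = _presso_sim(g, G, sG, n_sim, rng)
        exceed = int(np.sum(rss_star >= rss_obs))
        global_p = (1.0 + exceed) / (n_sim + 1.0)
        m = len(retained)
        raw = (1.0 + np.sum(d_star >= d_obs[None, :], axis=0)) / (n_sim + 1.0)
        adj = np.minimum(1.0, raw * m)
        outlier_p = pd.Series(adj, index=[i.snp_id for i in retained], name="outlier_p")
        history.append(
            {"iteration": it, "n_snps": m, "rss_obs": rss_obs, "global_p": global_p}
        )
        significant = (exceed / n_sim) < global_alpha
        if not significant or m <= 4:
            break
        candidates = np.flatnonzero(adj < alpha_outlier)
        if candidates.size == 0:
            break
        # smallest adjusted p; ties towards the larger observed residual
        order = np.lexsort((-d_obs[candidates], adj[candidates]))
        worst = candidates[order[0]]
        removed.append(retained[worst].snp_id)
        retained.pop(worst)

    corrected = ivw(retained, model=ivw_model)
    dist = None
    if distortion:
        raw_est = ivw(list(instruments), model=ivw_model)
        if corrected.beta != 0:
            dist = (raw_est.beta - corrected.beta) / abs(corrected.beta)
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers_removed=removed,
        n_iterations=it,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
        distortion=dist,
        history=history,
    )


# ---------------------------------------------------------------------------
# Multivariable MR
# ---------------------------------------------------------------------------


@dataclass
class MVMRResult:
    exposures: list[str]
    beta: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pval: pd.Series
    n_snps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.pval,
            }
        )


def mvmr_ivw(
    Gamma: np.ndarray | pd.Series,
    se_Gamma: np.ndarray | pd.Series,
    exposure_betas: pd.DataFrame,
) -> MVMRResult:
    """Multivariable IVW: direct effects of k exposures estimated jointly.

    Weighted least squares of the outcome effects Γ on the k per-SNP
    exposure-effect columns, no intercept, weights σ_yj⁻²; SEs carry the
    multiplicative residual scale floored at 1 (as in univariable IVW, to
    which this reduces for k = 1).
    """
    X = exposure_betas.to_numpy(dtype=float)
    y = np.asarray(Gamma, dtype=float)
    sG = np.asarray(se_Gamma, dtype=float)
    m, k = X.shape
    if m < k + 2:
        raise InputDataError(f"MVMR needs more than k+1 instruments (m={m}, k={k})")
    if np.any(sG <= 0):
        raise InputDataError("outcome standard errors must be positive")
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError("exposure-effect matrix is rank deficient")
    w = sG**-2
    XtWX = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(XtWX, X.T @ (w * y))
    resid = y - X @ coef
    phi = float(np.sum(w * resid**2)) / (m - k)
    cov = np.linalg.inv(XtWX) * max(1.0, phi)
    se = np.sqrt(np.diag(cov))
    names = list(exposure_betas.columns)
    beta = pd.Series(coef, index=names)
    se_s = pd.Series(se, index=names)
    p = pd.Series(2.0 * stats.norm.sf(np.abs(coef) / se), index=names)
    return MVMRResult(
        exposures=names,
        beta=beta,
        se=se_s,
        ci_low=beta - Z95 * se_s,
        ci_high=beta + Z95 * se_s,
        pval=p,
        n_snps=m,
    )
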