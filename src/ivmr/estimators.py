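"""Two-sample Mendelian randomization estimators.

Given harmonized instruments (γ_j, σ_xj) for the exposure and (Γ_j, σ_yj)
for the outcome, the suite provides:

* the single-SNP Wald ratio Γ_j / γ_j with its first-order delta SE;
* inverse-variance-weighted (IVW) meta-analysis, i.e. weighted regression of
  Γ on γ through the origin with weights σ_yj⁻², with fixed-effect or
  multiplicative random-effects (default) standard errors and Cochran's Q;
* MR-Egger regression, whose unconstrained intercept estimates average
  directional pleiotropy and whose slope is the pleiotropy-corrected effect,
  assuming InSIDE (instrument strength independent of direct effects);
* the weighted median, consistent when at least half the weight comes from
  valid instruments, with a seeded parametric-bootstrap SE;
* log-odds → odds-ratio conversion for binary-outcome reporting.

p-values are two-sided normal-theory; 95% CIs use the 1.96 multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import CollinearityError, InputDataError
from .sumstats import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "weighted_median",
    "or_from_logodds",
]

Z95 = 1.96


@dataclass
class MREstimate:
    """A causal-effect estimate from one MR method."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    model: str | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    Q: float | None = None
    Q_df: int | None = None
    Q_p: float | None = None


def _arrays(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = np.array([i.gamma for i in instruments], dtype=float)
    sg = np.array([i.se_gamma for i in instruments], dtype=float)
    G = np.array([i.Gamma for i in instruments], dtype=float)
    sG = np.array([i.se_Gamma for i in instruments], dtype=float)
    if np.any(sg <= 0) or np.any(sG <= 0):
        raise InputDataError("instrument standard errors must be positive")
    return g, sg, G, sG


def _estimate(method, beta, se, n_snps, model=None, **extra) -> MREstimate:
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(p),
        n_snps=int(n_snps),
        model=model,
        **extra,
    )


def wald_ratio(inst: HarmonizedInstrument) -> tuple[float, float]:
    """Single-instrument causal estimate Γ/γ with first-order SE σ_y/|γ|."""
    if inst.gamma == 0:
        raise InputDataError(f"{inst.snp_id}: zero exposure effect")
    return inst.Gamma / inst.gamma, inst.se_Gamma / abs(inst.gamma)


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    model: str = "random",
    allow_single: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    θ̂ = Σ w_j γ_j Γ_j / Σ w_j γ_j² with w_j = σ_yj⁻² — the slope of the
    zero-intercept weighted regression of Γ on γ.  ``model='fixed'`` uses
    se = (Σ w_j γ_j²)^(−1/2); the default multiplicative random-effects model
    inflates it by max(1, √(Q/(n−1))), which is conservative when instruments
    are heterogeneous and identical to fixed effects otherwise.
    """
    if model not in ("fixed", "random"):
        raise InputDataError(f"unknown IVW model {model!r}")
    n = len(instruments)
    if n < (1 if allow_single else 2):
        raise InputDataError("IVW requires at least 2 instruments")
    g, _, G, sG = _arrays(instruments)
    w = sG**-2
    denom = float(np.sum(w * g * g))
    if denom == 0:
        raise InputDataError("all exposure effects are zero")
    theta = float(np.sum(w * g * G)) / denom
    se_fixed = denom**-0.5
    Q = float(np.sum(w * (G - theta * g) ** 2))
    Q_df = max(n - 1, 0)
    Q_p = float(stats.chi2.sf(Q, Q_df)) if Q_df > 0 else 1.0
    se = se_fixed
    if model == "random" and Q_df > 0:
        se = se_fixed * max(1.0, np.sqrt(Q / Q_df))
    return _estimate("ivw", theta, se, n, model=model, Q=Q, Q_df=Q_df, Q_p=Q_p)


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], theta: float
) -> tuple[float, int, float]:
    """Cochran's heterogeneity statistic Σ σ_yj⁻² (Γ_j − θγ_j)², df = n − 1."""
    if len(instruments) < 2:
        raise InputDataError("Cochran's Q requires at least 2 instruments")
    g, _, G, sG = _arrays(instruments)
    Q = float(np.sum(sG**-2 * (G - theta * g) ** 2))
    df = len(instruments) - 1
    return Q, df, float(stats.chi2.sf(Q, df))


def egger(instruments: Sequence[HarmonizedInstrument]) -> MREstimate:
    """MR-Egger regression: weighted fit of Γ on γ with a free intercept.

    Instruments are first oriented so every γ_j ≥ 0 (the estimate must not
    depend on arbitrary allele coding).  The slope is the
    pleiotropy-corrected causal estimate; the intercept is the average
    directional pleiotropic effect, and its test against zero is the usual
    pleiotropy diagnostic.  SEs carry the multiplicative residual scale
    floored at 1 (random-effects convention).
    """
    n = len(instruments)
    if n < 3:
        raise InputDataError("MR-Egger requires at least 3 instruments")
    g, _, G, sG = _arrays(instruments)
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    if np.ptp(g) == 0:
        raise CollinearityError("exposure effects identical after orientation")
    w = sG**-2
    X = np.column_stack([np.ones(n), g])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * G)
    coef = np.linalg.solve(XtWX, XtWy)
    resid = G - X @ coef
    phi = float(np.sum(w * resid**2)) / (n - 2)
    cov = np.linalg.inv(XtWX) * max(1.0, phi)
    alpha, slope = float(coef[0]), float(coef[1])
    se_alpha, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    intercept_p = float(2.0 * stats.norm.sf(abs(alpha) / se_alpha))
    Q = float(np.sum(w * resid**2))
    return _estimate(
        "egger",
        slope,
        se_slope,
        n,
        model="random",
        intercept=alpha,
        intercept_se=se_alpha,
        intercept_p=intercept_p,
        Q=Q,
        Q_df=n - 2,
        Q_p=float(stats.chi2.sf(Q, n - 2)),
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation (Bowden convention)."""
    order = np.argsort(theta)
    th, wt = theta[order], w[order]
    wt = wt / wt.sum()
    cum = np.cumsum(wt) - 0.5 * wt  # midpoint cumulative weight
    if cum[0] >= 0.5:
        return float(th[0])
    if cum[-1] < 0.5:
        return float(th[-1])
    k = int(np.searchsorted(cum, 0.5, side="left"))
    # cum[k-1] < 0.5 <= cum[k]
    frac = (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
    return float(th[k - 1] + frac * (th[k] - th[k - 1]))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
    weighting: str = "first-order",
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Per-SNP ratio estimates θ_j = Γ_j/γ_j are ordered and the estimate is
    the weighted 50th percentile (linear interpolation between bracketing
    order statistics of the midpoint cumulative weight).  Weights are
    inverse-variance on se(θ_j); ``first-order`` (default) uses
    se(θ_j) = σ_yj/|γ_j|, ``second-order`` adds the exposure-side term
    Γ_j²σ_xj²/γ_j⁴.  The SE comes from resampling (γ_j, Γ_j) from normal
    distributions at their observed means and SEs, ``n_boot`` draws,
    reproducible given ``seed``.
    """
    if len(instruments) < 3:
        raise InputDataError("weighted median requires at least 3 instruments")
    if seed is None:
        raise InputDataError("weighted median bootstrap requires a seed")
    if weighting not in ("first-order", "second-order"):
        raise InputDataError(f"unknown weighting {weighting!r}")
    g, sg, G, sG = _arrays(instruments)
    if np.any(g == 0):
        raise InputDataError("zero exposure effect among instruments")

    def _wm(gv, Gv):
        theta = Gv / gv
        var = (sG / np.abs(gv)) ** 2
        if weighting == "second-order":
            var = var + Gv**2 * sg**2 / gv**4
        return _weighted_median(theta, 1.0 / var)

    est = _wm(g, G)
    rng = np.random.default_rng(seed)
    m = len(g)
    g_star = rng.normal(g, sg, size=(n_boot, m))
    G_star = rng.normal(G, sG, size=(n_boot, m))
    g_star = np.where(g_star == 0, np.finfo(float).tiny, g_star)
    boots = np.array([_wm(g_star[b], G_star[b]) for b in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    return _estimate("wmedian", est, se, m)


def or_from_logodds(
    beta: float,
    ci_low: float | None = None,
    ci_high: float | None = None,
    decimals: int = 3,
) -> tuple[float, tuple[float, float] | None]:
    """Convert a log-odds estimate (and optionally its CI) to an odds ratio."""
    orr = round(float(np.exp(beta)), decimals)
    if ci_low is None or ci_high is None:
        return orr, None
    return orr, (
        round(float(np.exp(ci_low)), decimals),
        round(float(np.exp(ci_high)), decimals),
    )
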