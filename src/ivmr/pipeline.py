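"""Analysis orchestration: run the estimator suites and build forest tables.

Both analysis arms are driven by an :class:`AnalysisConfig`; results come
back as "forest" tables (one row per outcome x method) carrying the
estimate, CI, p-value, odds-ratio columns for binary outcomes, and
nominal/Bonferroni significance flags.  A failing estimator marks its row
rather than aborting the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import estimators, grs, presso
from .exceptions import ConfigurationError, InputDataError
from .qc import GenotypeMatrix
from .sumstats import HarmonizedInstrument

__all__ = [
    "DEFAULT_OUTCOMES",
    "AnalysisConfig",
    "bonferroni_threshold",
    "run_two_sample_suite",
    "run_individual_suite",
]

#: The twelve cardiometabolic phenotypes of the default analysis panel.
DEFAULT_OUTCOMES = (
    "CAD", "IS", "T2D", "SBP", "DBP", "TG", "TC", "HDL", "LDL", "UA", "eGFR", "HbA1c",
)
BINARY_OUTCOMES = frozenset({"CAD", "IS", "T2D"})

TWO_SAMPLE_METHODS = ("ivw", "egger", "wmedian", "presso")


@dataclass
class AnalysisConfig:
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    methods: tuple[str, ...] = TWO_SAMPLE_METHODS
    ivw_model: str = "random"
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int | None = None
    alpha: float = 0.05
    rounding: int = 3

    def __post_init__(self):
        if not self.outcomes:
            raise ConfigurationError("outcome list must be non-empty")
        unknown = set(self.methods) - set(TWO_SAMPLE_METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
        stochastic = {"wmedian", "presso"} & set(self.methods)
        if stochastic and self.seed is None:
            raise ConfigurationError(
                f"methods {sorted(stochastic)} are stochastic; a seed is required"
            )


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Per-test significance threshold alpha/k, reported to 5 decimals."""
    if k < 1:
        raise InputDataError("number of phenotypes must be >= 1")
    return round(alpha / k, 5)


def _row(outcome, method, seed=None):
    return {
        "outcome": outcome,
        "method": method,
        "n_snps": np.nan,
        "beta": np.nan,
        "se": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "p": np.nan,
        "intercept": np.nan,
        "intercept_p": np.nan,
        "Q": np.nan,
        "Q_p": np.nan,
        "OR": np.nan,
        "OR_ci_low": np.nan,
        "OR_ci_high": np.nan,
        "failed": False,
        "error": "",
        "seed": seed,
    }


def _flag_significance(table: pd.DataFrame, alpha: float, k: int) -> pd.DataFrame:
    table = table.copy()
    thresh = bonferroni_threshold(alpha, k)
    table["significant_nominal"] = table["p"] < alpha
    table["significant_bonferroni"] = table["p"] < thresh
    table.loc[table["failed"], ["significant_nominal", "significant_bonferroni"]] = False
    return table


def run_two_sample_suite(
    instruments_by_outcome: Mapping[str, Sequence[HarmonizedInstrument]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Run the enabled two-sample estimators for every outcome.

    Binary outcomes (CAD, IS, T2D) additionally get odds-ratio columns from
    the log-odds scale.  Significance flags compare each p-value with alpha
    and with the Bonferroni threshold alpha / #outcomes.
    """
    config = config or AnalysisConfig(seed=0)
    rows = []
    for outcome in config.outcomes:
        if outcome not in instruments_by_outcome:
            raise InputDataError(f"no instruments supplied for outcome {outcome!r}")
        instr = list(instruments_by_outcome[outcome])
        for method in config.methods:
            row = _row(outcome, method, seed=config.seed)
            try:
                if method == "ivw":
                    est = estimators.ivw(instr, model=config.ivw_model)
                elif method == "egger":
                    est = estimators.egger(instr)
                elif method == "wmedian":
                    est = estimators.weighted_median(
                        instr, n_boot=config.n_boot, seed=config.seed
                    )
                elif method == "presso":
                    res = presso.presso_loop(
                        instr,
                        n_sim=config.n_sim,
                        seed=config.seed,
                        ivw_model=config.ivw_model,
                    )
                    est = res.corrected
                    row["n_outliers_removed"] = len(res.outliers_removed)
                    row["global_p"] = res.global_p
            except Exception as exc:  # noqa: BLE001 - rows must not abort the run
                row["failed"] = True
                row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
                continue
            row.update(
                n_snps=est.n_snps,
                beta=est.beta,
                se=est.se,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                p=est.pval,
            )
            if est.intercept is not None:
                row["intercept"] = est.intercept
                row["intercept_p"] = est.intercept_p
            if est.Q is not None:
                row["Q"] = est.Q
                row["Q_p"] = est.Q_p
            if outcome in BINARY_OUTCOMES:
                orr, ci = estimators.or_from_logodds(
                    est.beta, est.ci_low, est.ci_high, decimals=config.rounding
                )
                row["OR"], (row["OR_ci_low"], row["OR_ci_high"]) = orr, ci
            rows.append(row)
    table = pd.DataFrame(rows)
    return _flag_significance(table, config.alpha, len(config.outcomes))


def run_individual_suite(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    outcomes: Mapping[str, str],
    exposure_trait: str = "bmi",
    covariate_cols: Sequence[str] = ("age", "sex"),
    confounder_cols: Sequence[str] = ("brinkman", "alcohol", "mets"),
    config: AnalysisConfig | None = None,
    weights: grs.GRSWeights | None = None,
) -> dict:
    """Individual-level arm: GRS, 2SLS / two-stage logistic, diagnostics.

    ``outcomes`` maps phenotype column name -> {"quantitative", "binary"}.
    Returns a dict with the forest table, the GRS weights, the IV-confounder
    check and the observational (phenotypic) association table.
    """
    config = config or AnalysisConfig(methods=("ivw",), seed=0)
    if weights is None:
        weights = grs.fit_grs_weights(G, pheno, exposure_trait=exposure_trait)
    score = grs.compute_weighted_grs(G, weights)
    cov = pheno[list(covariate_cols)]
    exposure = pheno[exposure_trait]

    rows = []
    pheno_rows = []
    for outcome, kind in outcomes.items():
        row = _row(outcome, "2sls" if kind == "quantitative" else "two-stage-logistic")
        try:
            y = pheno[outcome]
            if y.isna().all():
                raise InputDataError(f"outcome {outcome!r} is entirely missing")
            if kind == "quantitative":
                res = grs.tsls_continuous(score, exposure, y, cov)
            else:
                res = grs.two_stage_binary(score, exposure, y, cov)
        except Exception as exc:  # noqa: BLE001
            row["failed"] = True
            row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
            continue
        row.update(
            beta=res.beta,
            se=res.se,
            ci_low=res.ci_low,
            ci_high=res.ci_high,
            p=res.pval,
            n_snps=len(weights.weights),
        )
        row["n_used"] = res.n_used
        row["first_stage_F"] = res.first_stage_F
        if kind == "binary":
            orr, ci = estimators.or_from_logodds(
                res.beta, res.ci_low, res.ci_high, decimals=config.rounding
            )
            row["OR"], (row["OR_ci_low"], row["OR_ci_high"]) = orr, ci
        rows.append(row)
        try:
            slope, se, p = grs.phenotypic_association(
                exposure, pheno[outcome], cov, binary=(kind == "binary")
            )
            pheno_rows.append({"outcome": outcome, "slope": slope, "se": se, "p": p})
        except Exception:  # noqa: BLE001
            pheno_rows.append(
                {"outcome": outcome, "slope": np.nan, "se": np.nan, "p": np.nan}
            )

    forest = _flag_significance(pd.DataFrame(rows), config.alpha, len(outcomes))
    present = [c for c in confounder_cols if c in pheno.columns]
    confounder_table = (
        grs.iv_confounder_check(score, pheno[present], cov) if present else None
    )
    return {
        "forest": forest,
        "weights": weights,
        "grs": score,
        "confounder_check": confounder_table,
        "phenotypic": pd.DataFrame(pheno_rows),
    }
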