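"""Weighted GRS construction and individual-level MR estimators."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivmr.exceptions import InputDataError
from ivmr.grs import (
    GRSWeights,
    compute_weighted_grs,
    fit_grs_weights,
    iv_confounder_check,
    phenotypic_association,
    tsls_continuous,
    two_stage_binary,
)
from ivmr.qc import GenotypeMatrix
from ivmr.simulate import SimConfig, gen_individual_cohort


def _cohort(**kw):
    defaults = dict(n_individuals=4000, seed=5)
    defaults.update(kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gen_individual_cohort(SimConfig(**defaults))


def _matrix(arr, snps=None):
    arr = np.asarray(arr, dtype=float)
    snps = snps or [f"rs{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=snps, index=[f"S{i}" for i in range(arr.shape[0])])
    return GenotypeMatrix(df)


class TestFitGRSWeights:
    def test_recovers_generating_effect(self):
        """Age/sex-adjusted per-SNP slope lands within 3 SE of the planted
        per-allele effect in an unconfounded cohort."""
        G, pheno, truth = _cohort(
            n_individuals=5000, m_snps=5, confounder_effect=(0.0, 0.0),
            snp_effect_dist=(0.09, 0.0), seed=21,
        )
        w = fit_grs_weights(G, pheno)
        for j, snp in enumerate(G.snp_ids):
            assert abs(w.weights[snp] - truth.gamma[j]) < 3 * w.se[snp]

    def test_constant_dosage_excluded_with_warning(self):
        rng = np.random.default_rng(0)
        arr = np.column_stack([np.zeros(200), rng.binomial(2, 0.3, 200)])
        G = _matrix(arr)
        pheno = pd.DataFrame(
            {
                "bmi": rng.normal(23, 3, 200),
                "age": rng.normal(55, 9, 200),
                "sex": rng.choice(["male", "female"], 200),
            },
            index=G.sample_ids,
        )
        with pytest.warns(UserWarning, match="constant dosage"):
            w = fit_grs_weights(G, pheno)
        assert w.excluded == ["rs0"]
        assert list(w.weights.index) == ["rs1"]

    def test_sample_order_invariance(self):
        G, pheno, _ = _cohort(n_individuals=800, m_snps=4, seed=3)
        w1 = fit_grs_weights(G, pheno)
        perm = np.random.default_rng(1).permutation(len(pheno))
        G2 = GenotypeMatrix(G.dosages.iloc[perm])
        w2 = fit_grs_weights(G2, pheno.iloc[perm])
        pd.testing.assert_series_equal(w1.weights, w2.weights, atol=1e-10, rtol=0)


class TestWeightedGRS:
    def test_hand_computed_dot_product(self):
        G = _matrix([[2.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        w = GRSWeights(
            pd.Series({"rs0": 0.5, "rs1": -0.2, "rs2": 1.0}),
            pd.Series({"rs0": 0.1, "rs1": 0.1, "rs2": 0.1}),
        )
        score = compute_weighted_grs(G, w)
        assert score.iloc[0] == pytest.approx(2 * 0.5 + 0 * -0.2 + 1 * 1.0)
        assert score.iloc[1] == pytest.approx(1 * 0.5 + 1 * -0.2)

    def test_single_snp_identity_and_null_weights(self):
        G = _matrix([[2.0], [0.0]])
        w = GRSWeights(pd.Series({"rs0": 1.0}), pd.Series({"rs0": 0.1}))
        assert compute_weighted_grs(G, w).tolist() == [2.0, 0.0]
        w0 = GRSWeights(pd.Series({"rs0": 0.0}), pd.Series({"rs0": 0.1}))
        assert compute_weighted_grs(G, w0).tolist() == [0.0, 0.0]

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(2)
        G = _matrix(rng.binomial(2, 0.3, (50, 6)).astype(float))
        se = pd.Series(0.1, index=G.snp_ids)
        w1 = GRSWeights(pd.Series(rng.normal(0, 1, 6), index=G.snp_ids), se)
        w2 = GRSWeights(pd.Series(rng.normal(0, 1, 6), index=G.snp_ids), se)
        w12 = GRSWeights(w1.weights + w2.weights, se)
        np.testing.assert_allclose(
            compute_weighted_grs(G, w12),
            compute_weighted_grs(G, w1) + compute_weighted_grs(G, w2),
            atol=1e-12,
        )

    def test_excess_missingness_gives_missing_score(self):
        arr = np.ones((2, 20))
        arr[0, :2] = np.nan  # 10% of weighted SNPs missing
        G = _matrix(arr)
        w = GRSWeights(
            pd.Series(1.0, index=G.snp_ids), pd.Series(0.1, index=G.snp_ids)
        )
        score = compute_weighted_grs(G, w)
        assert np.isnan(score.iloc[0]) and score.iloc[1] == pytest.approx(20.0)

    def test_empty_weight_set_rejected(self):
        G = _matrix([[1.0], [0.0]])
        w = GRSWeights(pd.Series(dtype=float), pd.Series(dtype=float))
        with pytest.raises(InputDataError):
            compute_weighted_grs(G, w)


def _fitted_grs(G, pheno):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = fit_grs_weights(G, pheno)
    return compute_weighted_grs(G, w)


class TestTSLSContinuous:
    def test_confounded_recovery_and_ols_bias(self):
        """2SLS removes the confounder bias that plain OLS retains."""
        G, pheno, truth = _cohort(n_individuals=10_000, true_theta=0.5, seed=11)
        score = _fitted_grs(G, pheno)
        cov = pheno[["age", "sex"]]
        res = tsls_continuous(score, pheno.bmi, pheno.outcome, cov)
        assert abs(res.beta - truth.theta) < 3 * res.se
        ols_slope, ols_se, _ = phenotypic_association(pheno.bmi, pheno.outcome, cov)
        assert abs(ols_slope - truth.theta) > 5 * ols_se
        assert res.first_stage_F > 10 and not res.weak_instrument

    def test_null_outcome_recovers_zero(self):
        G, pheno, _ = _cohort(n_individuals=5000, true_theta=0.0,
                              confounder_effect=(0.0, 0.0), seed=9)
        score = _fitted_grs(G, pheno)
        res = tsls_continuous(score, pheno.bmi, pheno.outcome, pheno[["age", "sex"]])
        assert abs(res.beta) < 3 * res.se

    def test_negating_instrument_leaves_estimate_unchanged(self):
        G, pheno, _ = _cohort(n_individuals=2000, seed=13)
        score = _fitted_grs(G, pheno)
        cov = pheno[["age", "sex"]]
        a = tsls_continuous(score, pheno.bmi, pheno.outcome, cov)
        b = tsls_continuous(-score, pheno.bmi, pheno.outcome, cov)
        assert b.first_stage_beta == pytest.approx(-a.first_stage_beta)
        assert b.beta == pytest.approx(a.beta, rel=1e-10)

    def test_single_instrument_equals_wald_ratio(self):
        """2SLS with one instrument is the ratio of reduced-form to
        first-stage covariate-adjusted slopes."""
        G, pheno, _ = _cohort(n_individuals=3000, seed=17)
        score = _fitted_grs(G, pheno)
        cov = pheno[["age", "sex"]]
        res = tsls_continuous(score, pheno.bmi, pheno.outcome, cov)
        rf, _, _ = phenotypic_association(score, pheno.outcome, cov)
        fs, _, _ = phenotypic_association(score, pheno.bmi, cov)
        assert res.beta == pytest.approx(rf / fs, abs=1e-8)

    def test_matches_statsmodels_iv2sls(self):
        """Independent cross-check against the statsmodels IV routine."""
        from statsmodels.sandbox.regression.gmm import IV2SLS

        G, pheno, _ = _cohort(n_individuals=2000, seed=23)
        score = _fitted_grs(G, pheno)
        sex = (pheno.sex == "female").astype(float).to_numpy()
        W = np.column_stack([np.ones(len(pheno)), pheno.age, sex])
        X = np.column_stack([W, pheno.bmi])
        Z = np.column_stack([W, score])
        sm_res = IV2SLS(pheno.outcome.to_numpy(), X, instrument=Z).fit()
        res = tsls_continuous(score, pheno.bmi, pheno.outcome, pheno[["age", "sex"]])
        assert res.beta == pytest.approx(sm_res.params[-1], rel=1e-8)
        assert res.se == pytest.approx(sm_res.bse[-1], rel=1e-6)

    def test_too_few_cases_rejected(self):
        G, pheno, _ = _cohort(n_individuals=50, seed=2)
        score = _fitted_grs(G, pheno)
        with pytest.raises(InputDataError):
            tsls_continuous(score, pheno.bmi, pheno.outcome, pheno[["age", "sex"]])


class TestTwoStageBinary:
    def test_recovers_log_odds_per_unit(self):
        G, pheno, truth = _cohort(
            n_individuals=20_000, outcome_type="binary", true_theta=0.1,
            baseline_prevalence=0.2, seed=31,
        )
        score = _fitted_grs(G, pheno)
        res = two_stage_binary(score, pheno.bmi, pheno.outcome, pheno[["age", "sex"]])
        assert abs(res.beta - truth.theta) < 3 * res.se

    def test_independent_outcome_recovers_zero(self):
        G, pheno, _ = _cohort(
            n_individuals=8000, outcome_type="binary", true_theta=0.0,
            confounder_effect=(0.0, 0.0), baseline_prevalence=0.2, seed=37,
        )
        score = _fitted_grs(G, pheno)
        res = two_stage_binary(score, pheno.bmi, pheno.outcome, pheno[["age", "sex"]])
        assert abs(res.beta) < 3 * res.se

    def test_unit_rescaling_halves_log_odds(self):
        G, pheno, _ = _cohort(
            n_individuals=6000, outcome_type="binary", true_theta=0.15,
            baseline_prevalence=0.2, seed=41,
        )
        score = _fitted_grs(G, pheno)
        cov = pheno[["age", "sex"]]
        a = two_stage_binary(score, pheno.bmi, pheno.outcome, cov)
        b = two_stage_binary(score, 2.0 * pheno.bmi, pheno.outcome, cov)
        assert b.beta == pytest.approx(a.beta / 2.0, rel=1e-6)

    def test_single_class_outcome_rejected(self):
        G, pheno, _ = _cohort(n_individuals=500, seed=2)
        score = _fitted_grs(G, pheno)
        flat = pd.Series(0.0, index=pheno.index)
        with pytest.raises(InputDataError):
            two_stage_binary(score, pheno.bmi, flat, pheno[["age", "sex"]])

    def test_bootstrap_se_reproducible(self):
        G, pheno, _ = _cohort(
            n_individuals=2000, outcome_type="binary", baseline_prevalence=0.3, seed=43
        )
        score = _fitted_grs(G, pheno)
        kw = dict(bootstrap=True, n_boot=50, seed=99)
        a = two_stage_binary(score, pheno.bmi, pheno.outcome, pheno[["age", "sex"]], **kw)
        b = two_stage_binary(score, pheno.bmi, pheno.outcome, pheno[["age", "sex"]], **kw)
        assert a.se == b.se


class TestIVConfounderCheck:
    def test_null_pvalues_uniform_over_replicates(self):
        """Confounders independent of genotype give uniform p-values."""
        rng = np.random.default_rng(123)
        pvals = []
        n = 400
        for _ in range(200):
            grs = pd.Series(rng.normal(0, 1, n))
            conf = pd.DataFrame({"brinkman": rng.gamma(2, 100, n)})
            cov = pd.DataFrame(
                {"age": rng.normal(55, 9, n), "sex": rng.integers(0, 2, n)}
            )
            table = iv_confounder_check(grs, conf, cov)
            pvals.append(table.loc["brinkman", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_association(self):
        rng = np.random.default_rng(5)
        n = 500
        grs = pd.Series(rng.normal(0, 1, n))
        cov = pd.DataFrame({"age": rng.normal(55, 9, n), "sex": rng.integers(0, 2, n)})
        table = iv_confounder_check(grs, pd.DataFrame({"self": grs}), cov)
        assert table.loc["self", "slope"] == pytest.approx(1.0, abs=1e-10)
        assert table.loc["self", "p"] < 1e-100

    def test_constant_confounder_zero_slope(self):
        rng = np.random.default_rng(6)
        n = 300
        grs = pd.Series(rng.normal(0, 1, n))
        cov = pd.DataFrame({"age": rng.normal(55, 9, n), "sex": rng.integers(0, 2, n)})
        table = iv_confounder_check(
            grs, pd.DataFrame({"flat": np.full(n, 3.0)}), cov
        )
        assert table.loc["flat", "slope"] == 0.0


class TestPhenotypicAssociation:
    def test_noiseless_limit_recovers_slope(self):
        rng = np.random.default_rng(8)
        n = 500
        x = pd.Series(rng.normal(23, 3, n))
        cov = pd.DataFrame({"age": rng.normal(55, 9, n), "sex": rng.integers(0, 2, n)})
        y = 2.0 * x + rng.normal(0, 1e-8, n)
        slope, se, p = phenotypic_association(x, y, cov)
        assert slope == pytest.approx(2.0, abs=1e-6)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(9)
        n = 300
        x = pd.Series(rng.normal(0, 1, n))
        y = pd.Series(0.5 * x + rng.normal(0, 1, n))
        cov = pd.DataFrame({"age": rng.normal(55, 9, n), "sex": rng.integers(0, 2, n)})
        perm = rng.permutation(n)
        a = phenotypic_association(x, y, cov)
        b = phenotypic_association(
            x.iloc[perm].reset_index(drop=True),
            y.iloc[perm].reset_index(drop=True),
            cov.iloc[perm].reset_index(drop=True),
        )
        assert a[0] == pytest.approx(b[0], rel=1e-10)
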