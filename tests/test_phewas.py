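import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import kstest

from mendelscan.exceptions import AnalysisError
from mendelscan.phewas import (
    GRSWeight,
    GRSWeights,
    build_weighted_grs,
    fit_logistic_glm,
    run_phewas,
    run_stratified_grs,
)
from mendelscan.synthetic import SimConfig, instrument_exposure_table, simulate_cohort


def _weights(pairs):
    return GRSWeights([GRSWeight(vid, ea, oa, w) for vid, ea, oa, w in pairs])


class TestGRS:
    def test_weighted_dosage_sum(self):
        geno = pd.DataFrame({"rs1": [2, 0, 1], "rs2": [1, 0, 2]})
        w = _weights([("rs1", "T", "C", 0.2), ("rs2", "A", "G", 0.1)])
        score = build_weighted_grs(geno, w)
        raw = np.array([0.5, 0.0, 0.4])  # e.g. (2,1)·(0.2,0.1) = 0.5
        expected = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(score, expected, atol=1e-12)

    def test_standardized_moments(self, small_cohort):
        w = GRSWeights.from_summary_stats(
            instrument_exposure_table(small_cohort.config)
        )
        score = build_weighted_grs(small_cohort.genotypes, w)
        assert abs(score.mean()) < 1e-10
        assert abs(score.std() - 1.0) < 1e-10

    def test_orientation_invariance(self):
        """A weight on the decreasing allele gives identical scores."""
        rng = np.random.default_rng(0)
        geno = pd.DataFrame({
            "rs1": rng.integers(0, 3, 100), "rs2": rng.integers(0, 3, 100),
        })
        w_inc = _weights([("rs1", "T", "C", 0.2), ("rs2", "A", "G", 0.1)])
        # same associations stated on the other allele with flipped dosages
        geno_flipped = geno.copy()
        geno_flipped["rs1"] = 2 - geno_flipped["rs1"]
        w_dec = _weights([("rs1", "C", "T", -0.2), ("rs2", "A", "G", 0.1)])
        a = build_weighted_grs(geno, w_inc)
        b = build_weighted_grs(geno_flipped, w_dec)
        np.testing.assert_array_equal(a, b)

    def test_zero_variance_raises(self):
        geno = pd.DataFrame({"rs1": [1, 1, 1]})
        with pytest.raises(AnalysisError, match="zero variance"):
            build_weighted_grs(geno, _weights([("rs1", "T", "C", 0.2)]))

    def test_missing_variant_raises(self):
        geno = pd.DataFrame({"rs1": [0, 1, 2]})
        with pytest.raises(AnalysisError, match="rs9"):
            build_weighted_grs(geno, _weights([("rs9", "T", "C", 0.2)]))

    def test_out_of_range_dosage_raises(self):
        geno = pd.DataFrame({"rs1": [0, 1, 3]})
        with pytest.raises(AnalysisError, match=r"\[0, 2\]"):
            build_weighted_grs(geno, _weights([("rs1", "T", "C", 0.2)]))


class TestLogisticFit:
    def test_matches_statsmodels_newton_oracle(self):
        """IRLS agrees with an independent GLM fit to 1e-8 on a small fixture."""
        rng = np.random.default_rng(42)
        n = 50
        x = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = (rng.random(n) < expit(0.3 + 0.8 * x[:, 1] - 0.5 * x[:, 2])).astype(float)
        fit = fit_logistic_glm(y, x)
        oracle = sm.GLM(y, x, family=sm.families.Binomial()).fit(tol=1e-12)
        assert fit.converged
        np.testing.assert_allclose(fit.coef, oracle.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, oracle.bse, atol=1e-8)

    def test_null_pvalues_uniform(self):
        """Wald p-values are calibrated when the score is pure noise."""
        rng = np.random.default_rng(5)
        n = 2000
        pvals = []
        for _ in range(400):
            x = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = (rng.random(n) < 0.2).astype(float)
            pvals.append(fit_logistic_glm(y, x).pvalues[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_recovers_generative_log_odds(self):
        """Mean estimate matches the configured per-SD log-OR."""
        rng = np.random.default_rng(8)
        truth, n, reps = -0.03, 50_000, 40
        ests = []
        for _ in range(reps):
            score = rng.normal(size=n)
            y = (rng.random(n) < expit(math.log(0.1 / 0.9) + truth * score)).astype(float)
            fit = fit_logistic_glm(y, np.column_stack([np.ones(n), score]))
            ests.append(fit.coef[1])
        se_mean = 1.0 / math.sqrt(n * 0.1 * 0.9) / math.sqrt(reps)
        assert abs(np.mean(ests) - truth) < 4 * se_mean

    def test_perfect_separation_flagged(self):
        x = np.column_stack([np.ones(20), np.arange(20.0)])
        y = (x[:, 1] >= 10).astype(float)
        fit = fit_logistic_glm(y, x)
        assert not fit.converged

    def test_single_class_outcome_raises(self):
        with pytest.raises(AnalysisError, match="both classes"):
            fit_logistic_glm(np.zeros(10), np.ones((10, 1)))

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=30)
        x = np.column_stack([np.ones(30), z, z])  # duplicated column
        y = (rng.random(30) < 0.5).astype(float)
        with pytest.raises(AnalysisError, match="rank deficient"):
            fit_logistic_glm(y, x)


@pytest.fixture(scope="module")
def scanned():
    cfg = SimConfig(seed=31, n_individuals=8000, n_phecodes=40,
                    n_null_phecodes=36, phecode_log_or=2.0,
                    phecode_prevalence_range=(0.003, 0.2))
    cohort = simulate_cohort(cfg)
    weights = GRSWeights.from_summary_stats(instrument_exposure_table(cfg))
    return cohort, run_phewas(cohort, weights, min_cases=200)


class TestPheWAS:
    def test_case_count_floor_enforced(self, scanned):
        cohort, table = scanned
        assert (table["n_cases"] >= 200).all()
        counts = cohort.phecodes.sum()
        assert (counts < 200).any()  # the floor actually pruned something
        for phe in counts[counts < 200].index:
            assert phe not in set(table["phecode"])

    def test_exactly_199_cases_excluded_200_included(self):
        cfg = SimConfig(seed=2, n_individuals=2000, n_phecodes=2, n_null_phecodes=2)
        cohort = simulate_cohort(cfg)
        phe = np.zeros((2000, 2), dtype=np.int8)
        phe[:199, 0] = 1
        phe[:200, 1] = 1
        cohort.phecodes = pd.DataFrame(phe, columns=["phecode_0001", "phecode_0002"])
        weights = GRSWeights.from_summary_stats(instrument_exposure_table(cfg))
        table = run_phewas(cohort, weights, min_cases=200)
        assert set(table["phecode"]) == {"phecode_0002"}

    def test_q_values_match_bh_oracle_and_dominate_p(self, scanned):
        from test_mr import _bh_oracle

        _, table = scanned
        ok = table[table["converged"]]
        np.testing.assert_allclose(
            ok["q_value"].to_numpy(), _bh_oracle(ok["pvalue"].to_numpy()), atol=1e-12
        )
        assert (ok["q_value"] >= ok["pvalue"] - 1e-15).all()
        assert (ok["pvalue"].diff().dropna() >= 0).all()  # sorted by p
        q = ok["q_value"].to_numpy()
        assert (np.diff(q) >= -1e-15).all()  # monotone after sorting

    def test_strong_signal_phecodes_discovered(self, scanned):
        """Phecodes with a large exposure effect clear the FDR threshold."""
        cohort, table = scanned
        signal = {k for k, v in cohort.truth["phecode_log_or"].items() if v != 0.0}
        eligible_signal = signal & set(table["phecode"])
        assert eligible_signal  # the fixture must actually exercise this
        hits = table[table["phecode"].isin(eligible_signal)]
        assert hits["significant"].all()

    def test_no_eligible_phecodes_returns_empty(self):
        cfg = SimConfig(seed=2, n_individuals=300, n_phecodes=3, n_null_phecodes=3,
                        phecode_prevalence_range=(0.01, 0.02))
        cohort = simulate_cohort(cfg)
        weights = GRSWeights.from_summary_stats(instrument_exposure_table(cfg))
        table = run_phewas(cohort, weights, min_cases=200)
        assert len(table) == 0


class TestStratified:
    def test_empty_stratum_error_names_it(self, small_cohort):
        weights = GRSWeights.from_summary_stats(
            instrument_exposure_table(small_cohort.config)
        )
        with pytest.raises(AnalysisError, match="abstainer"):
            run_stratified_grs(
                small_cohort, weights, outcome="mediator",
                outcome_type="continuous",
                stratum_flag=np.ones(small_cohort.n, dtype=bool),
            )

    def test_exchangeable_strata_agree(self):
        """A random stratum label produces only sampling-noise differences."""
        z_flags = 0
        reps = 60
        for s in range(reps):
            cfg = SimConfig(seed=1000 + s, n_individuals=4000,
                            n_phecodes=1, n_null_phecodes=1)
            cohort = simulate_cohort(cfg)
            weights = GRSWeights.from_summary_stats(instrument_exposure_table(cfg))
            rng = np.random.default_rng(s)
            flag = rng.random(cohort.n) < 0.5
            t = run_stratified_grs(cohort, weights, outcome="mediator",
                                   outcome_type="continuous", stratum_flag=flag)
            d = t.iloc[0]["estimate"] - t.iloc[1]["estimate"]
            se = math.hypot(t.iloc[0]["se"], t.iloc[1]["se"])
            z_flags += abs(d / se) > 1.96
        assert z_flags / reps < 0.15  # nominal 5%, generous Monte-Carlo margin

    def test_continuous_outcome_standardized_per_sd(self, small_cohort):
        weights = GRSWeights.from_summary_stats(
            instrument_exposure_table(small_cohort.config)
        )
        t = run_stratified_grs(small_cohort, weights, outcome="mediator",
                               outcome_type="continuous")
        assert set(t["stratum"]) == {"abstainer", "consumer"}
        assert (t["n"] > 0).all()
        # per-SD effects of a two-variant score are necessarily small
        assert (t["estimate"].abs() < 0.5).all()

    def test_unknown_outcome_rejected(self, small_cohort):
        weights = GRSWeights.from_summary_stats(
            instrument_exposure_table(small_cohort.config)
        )
        with pytest.raises(AnalysisError, match="unknown outcome"):
            run_stratified_grs(small_cohort, weights, outcome="nope")
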