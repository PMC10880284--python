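import math
from dataclasses import replace

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record, make_table
from mendelscan.exceptions import AnalysisError
from mendelscan.mr import (
    HarmonizedPair,
    bidirectional_mr,
    clump_by_ld,
    harmonize_pairs,
    ivw_random_effects,
    mr_scan_panel,
    variance_explained,
    wald_ratio,
)
from mendelscan.synthetic import SimConfig, ar1_ld_matrix, simulate_bidirectional_tables

import pandas as pd


def _harmonize_one(exp_rec, out_rec):
    return harmonize_pairs(make_table([exp_rec], trait_id="e"),
                           make_table([out_rec], trait_id="o"))[0]


class TestHarmonization:
    def test_identical_alleles_unchanged(self):
        p = _harmonize_one(make_record(beta=0.10), make_record(beta=0.02))
        assert p.action_taken == "unchanged" and p.kept
        assert p.beta_outcome == 0.02

    def test_swapped_alleles_flip_sign_and_frequency(self):
        p = _harmonize_one(
            make_record(ea="T", oa="C", beta=0.10, eaf=0.27),
            make_record(ea="C", oa="T", beta=0.02, eaf=0.73),
        )
        assert p.action_taken == "swapped" and p.kept
        assert p.beta_outcome == -0.02
        assert p.eaf_outcome == pytest.approx(0.27)

    def test_strand_flip_resolves_complemented_report(self):
        p = _harmonize_one(
            make_record(ea="T", oa="C", beta=0.10),
            make_record(ea="A", oa="G", beta=0.02),
        )
        assert p.action_taken == "strand_flipped"
        assert p.beta_outcome == 0.02

    def test_swapped_and_flipped(self):
        p = _harmonize_one(
            make_record(ea="T", oa="C", beta=0.10, eaf=0.27),
            make_record(ea="G", oa="A", beta=0.02, eaf=0.73),
        )
        assert p.action_taken == "swapped_and_flipped"
        assert p.beta_outcome == -0.02

    def test_allele_mismatch_excluded(self):
        p = _harmonize_one(
            make_record(ea="T", oa="C"), make_record(ea="T", oa="G")
        )
        assert p.status == "excluded:allele_mismatch"

    def test_palindromic_at_half_frequency_excluded(self):
        p = _harmonize_one(
            make_record(ea="A", oa="T", eaf=0.50),
            make_record(ea="A", oa="T", eaf=0.50),
        )
        assert p.status == "excluded:palindromic_ambiguous"

    def test_palindromic_missing_frequency_excluded(self):
        p = _harmonize_one(
            make_record(ea="C", oa="G", eaf=math.nan),
            make_record(ea="C", oa="G", eaf=0.2),
        )
        assert p.status == "excluded:palindromic_ambiguous"

    def test_palindromic_frequency_aligned_same_side(self):
        p = _harmonize_one(
            make_record(ea="A", oa="T", eaf=0.20, beta=0.1),
            make_record(ea="A", oa="T", eaf=0.22, beta=0.02),
        )
        assert p.kept and p.action_taken == "unchanged"
        assert p.beta_outcome == 0.02

    def test_palindromic_frequency_aligned_opposite_side(self):
        p = _harmonize_one(
            make_record(ea="A", oa="T", eaf=0.20, beta=0.1),
            make_record(ea="A", oa="T", eaf=0.80, beta=0.02),
        )
        assert p.kept and p.action_taken == "swapped"
        assert p.beta_outcome == -0.02
        assert p.eaf_outcome == pytest.approx(0.20)

    def test_empty_intersection_raises(self):
        with pytest.raises(AnalysisError, match="no shared variants"):
            harmonize_pairs(
                make_table([make_record("rs1")], trait_id="e"),
                make_table([make_record("rs2")], trait_id="o"),
            )

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=4, max_size=4))
    def test_relabelling_never_changes_ivw(self, ops):
        """Allele bookkeeping is pure bookkeeping: IVW is invariant to it."""
        alleles = [("A", "G"), ("T", "C"), ("G", "C"), ("C", "A")]
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        exp = make_table(
            [make_record(f"v{i}", ea, oa, beta=0.1 + 0.01 * i, eaf=0.2 + 0.05 * i)
             for i, (ea, oa) in enumerate(alleles)], trait_id="e",
        )
        base_out = [
        make_record(f"v{i}", ea, oa, beta=0.01 * (i - 1.5), se=0.008,
                        eaf=0.2 + 0.05 * i)
            for i, (ea, oa) in enumerate(alleles)
        ]
        baseline = ivw_random_effects(
            harmonize_pairs(exp, make_table(base_out, trait_id="o"))
        )
        fuzzed = []
        for rec, (swap, flip) in zip(base_out, ops):
            r = rec.with_alleles_swapped() if swap else rec
            if flip:
                r = replace(r, effect_allele=comp[r.effect_allele],
                            other_allele=comp[r.other_allele])
            fuzzed.append(r)
        res = ivw_random_effects(
            harmonize_pairs(exp, make_table(fuzzed, trait_id="o"))
        )
        assert abs(res.estimate - baseline.estimate) < 1e-12
        assert abs(res.se - baseline.se) < 1e-12


class TestWaldRatio:
    def test_arithmetic(self):
        r, se = wald_ratio(HarmonizedPair("v", beta_exposure=0.5,
                                          beta_outcome=0.05, se_outcome=0.01))
        assert r == pytest.approx(0.1) and se == pytest.approx(0.02)

    def test_zero_outcome_beta(self):
        r, _ = wald_ratio(HarmonizedPair("v", beta_exposure=0.5,
                                         beta_outcome=0.0, se_outcome=0.01))
        assert r == 0.0

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(AnalysisError, match="zero exposure"):
            wald_ratio(HarmonizedPair("v", beta_exposure=0.0,
                                      beta_outcome=0.1, se_outcome=0.01))

    def test_se_matches_parametric_bootstrap(self, rng):
        """First-order ratio SE agrees with simulation at fixed exposure beta."""
        b_exp, b_out, se_out = 0.5, 0.05, 0.01
        _, se = wald_ratio(HarmonizedPair("v", beta_exposure=b_exp,
                                          beta_outcome=b_out, se_outcome=se_out))
        draws = rng.normal(b_out, se_out, 1_000_000) / b_exp
        assert abs(np.std(draws) - se) / se < 0.03


class TestIVW:
    def _pairs(self, bx, by, sy):
        return [HarmonizedPair(f"v{i}", beta_exposure=x, se_exposure=0.01,
                               beta_outcome=y, se_outcome=s)
                for i, (x, y, s) in enumerate(zip(bx, by, sy))]

    def test_single_instrument_equals_wald_ratio_exactly(self):
        pair = self._pairs([0.14], [-0.015], [0.012])[0]
        res = ivw_random_effects([pair])
        r, se = wald_ratio(pair)
        assert res.estimate == r and res.se == se
        assert math.isnan(res.q) and res.q_df == 0

    def test_identical_ratios_give_zero_q_and_fixed_se(self):
        res = ivw_random_effects(self._pairs([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))
        assert res.estimate == pytest.approx(0.1, abs=1e-15)
        assert res.q == pytest.approx(0.0, abs=1e-20)
        assert res.se == res.se_fixed

    def test_matches_wls_through_origin_oracle(self):
        """IVW equals weighted regression of outcome on exposure betas."""
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.2, 5)
        by = rng.normal(0.0, 0.02, 5)
        sy = rng.uniform(0.005, 0.02, 5)
        res = ivw_random_effects(self._pairs(bx, by, sy))
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        theta = fit.params[0]
        se_fixed = float(fit.bse[0] / np.sqrt(fit.scale))
        se_re = se_fixed * max(1.0, math.sqrt(fit.scale))
        assert res.estimate == pytest.approx(theta, abs=1e-12)
        assert res.se_fixed == pytest.approx(se_fixed, abs=1e-12)
        assert res.se == pytest.approx(se_re, abs=1e-12)
        assert res.q == pytest.approx(fit.scale * 4, rel=1e-12)

    def test_no_kept_pairs_raises(self):
        with pytest.raises(AnalysisError, match="no kept"):
            ivw_random_effects([HarmonizedPair("v", status="excluded:allele_mismatch")])


class TestClumping:
    def _table(self, pvals):
        return make_table([
            make_record(f"v{i}", "A", "G", beta=0.1, pvalue=p)
            for i, p in enumerate(pvals)
        ])

    def test_uncorrelated_variants_all_kept(self):
        ids = [f"v{i}" for i in range(4)]
        ld = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        kept = clump_by_ld(self._table([1e-10, 1e-9, 1e-12, 0.5]), ld,
                           r2_threshold=0.01)
        assert set(kept) == {"v0", "v1", "v2"}  # v3 fails the p threshold

    def test_correlated_pair_keeps_smaller_p(self):
        ids = ["v0", "v1"]
        ld = pd.DataFrame([[1.0, math.sqrt(0.5)], [math.sqrt(0.5), 1.0]],
                          index=ids, columns=ids)
        kept = clump_by_ld(self._table([1e-9, 1e-12]), ld, r2_threshold=0.01)
        assert kept == ["v1"]

    def test_missing_ld_entries_raise(self):
        ld = pd.DataFrame([[1.0]], index=["v0"], columns=["v0"])
        with pytest.raises(AnalysisError, match="v1"):
            clump_by_ld(self._table([1e-9, 1e-9]), ld)

    def test_greedy_selection_verified_exhaustively(self):
        """Every kept-kept pair is below threshold; every drop is blocked."""
        rng = np.random.default_rng(7)
        m, thr = 50, 0.01
        ld_arr = ar1_ld_matrix(m, 0.45)
        ids = [f"v{i}" for i in range(m)]
        ld = pd.DataFrame(ld_arr, index=ids, columns=ids)
        pvals = rng.uniform(1e-30, 1e-9, m)
        table = self._table(pvals)
        kept = clump_by_ld(table, ld, r2_threshold=thr)
        p_by_id = {f"v{i}": pvals[i] for i in range(m)}
        kept_set = set(kept)
        for a in kept:
            for b in kept:
                if a != b:
                    assert ld.loc[a, b] ** 2 < thr
        for vid in set(ids) - kept_set:
            blockers = [k for k in kept
                        if ld.loc[vid, k] ** 2 >= thr and p_by_id[k] <= p_by_id[vid]]
            assert blockers, f"{vid} dropped without a blocking kept variant"


class TestVarianceExplained:
    def test_closed_form(self):
        assert variance_explained(make_record(eaf=0.5, beta=0.1)) == pytest.approx(0.005)
        assert variance_explained(make_record(eaf=0.3, beta=0.0)) == 0.0

    def test_missing_eaf_raises(self):
        with pytest.raises(AnalysisError, match="eaf"):
            variance_explained(make_record(eaf=math.nan))

    def test_agrees_with_regression_r2_on_simulated_dosages(self, rng):
        f, beta, n = 0.27, 0.1389, 1_000_000
        d = rng.binomial(2, f, n).astype(float)
        g_var = 2 * f * (1 - f) * beta**2
        y = beta * (d - 2 * f) + rng.normal(0, math.sqrt(1 - g_var), n)
        r2_sample = np.corrcoef(d, y)[0, 1] ** 2
        r2_formula = variance_explained(make_record(eaf=f, beta=beta))
        assert abs(r2_sample - r2_formula) < 3 * math.sqrt(2.0 / n) + 1e-4


def _bh_oracle(pvals):
    """Textbook step-up BH: q_i = min_{j >= rank(i)} p_(j) m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPanelScan:
    def test_q_values_equal_independent_bh_oracle(self):
        from mendelscan.synthetic import simulate_omics_panel

        cfg = SimConfig(seed=21, panel_size=60, panel_signal_fraction=0.2)
        panel = simulate_omics_panel(cfg)
        res = mr_scan_panel(panel.exposure, panel.outcomes)
        tab = res.table
        np.testing.assert_allclose(
            tab["q_value"].to_numpy(),
            _bh_oracle(tab["pvalue"].to_numpy()),
            atol=1e-12,
        )

    def test_noise_free_signal_recovered_exactly(self):
        exp = make_table([
            make_record("rs1", "T", "C", beta=0.14, se=0.016, eaf=0.27),
            make_record("rs2", "A", "G", beta=0.11, se=0.014, eaf=0.37),
        ], trait_id="e")
        theta = 0.3
        signal = make_table([
            make_record("rs1", "T", "C", beta=theta * 0.14, se=1e-9, eaf=0.27),
            make_record("rs2", "A", "G", beta=theta * 0.11, se=1e-9, eaf=0.37),
        ], trait_id="signal")
        null = make_table([
            make_record("rs1", "T", "C", beta=0.001, se=0.01, eaf=0.27),
            make_record("rs2", "A", "G", beta=-0.002, se=0.01, eaf=0.37),
        ], trait_id="null")
        res = mr_scan_panel(exp, [null, signal])
        row = res.table[res.table["trait_id"] == "signal"].iloc[0]
        assert row["estimate"] == pytest.approx(theta, abs=1e-12)
        assert res.table.iloc[0]["trait_id"] == "signal"  # smallest p first

    def test_failed_traits_reported_but_out_of_multiplicity(self):
        exp = make_table([make_record("rs1", "T", "C", beta=0.14, se=0.016)],
                         trait_id="e")
        good = make_table([make_record("rs1", "T", "C", beta=0.01, se=0.01)],
                          trait_id="good")
        disjoint = make_table([make_record("rsX", "A", "G")], trait_id="bad")
        res = mr_scan_panel(exp, [good, disjoint])
        assert res.failures.keys() == {"bad"}
        ok = res.table[res.table["status"] == "ok"]
        assert list(ok["trait_id"]) == ["good"]
        # multiplicity set of one: q equals p
        assert ok.iloc[0]["q_value"] == pytest.approx(ok.iloc[0]["pvalue"])


class TestBidirectional:
    def test_forward_invariant_to_reverse_instrument_set(self):
        tabs = simulate_bidirectional_tables(SimConfig(seed=17))
        f1, _ = bidirectional_mr(tabs.trait_a, tabs.trait_b,
                                 tabs.instruments_a, tabs.instruments_b)
        f2, _ = bidirectional_mr(tabs.trait_a, tabs.trait_b,
                                 tabs.instruments_a, tabs.instruments_b[:5])
        assert f1.estimate == f2.estimate and f1.se == f2.se

    def test_directions_use_their_own_instruments(self):
        tabs = simulate_bidirectional_tables(SimConfig(seed=17))
        fwd, rev = bidirectional_mr(tabs.trait_a, tabs.trait_b,
                                    tabs.instruments_a, tabs.instruments_b)
        assert fwd.n_snps == len(tabs.instruments_a)
        assert rev.n_snps == len(tabs.instruments_b)
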