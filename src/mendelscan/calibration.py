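"""Replicate-based calibration studies of the pipeline's estimators.

Each study exercises one estimator on the synthetic generator at a
known-truth regime and measures a frequentist operating characteristic:
bias and confidence-interval coverage of the IVW estimator, type-I
calibration of Cochran's Q and of the PheWAS scan, recovery of the
mediated proportion, agreement of the colocalization posteriors with
the exhaustive enumeration oracle, scenario discrimination, invariance
of IVW to allele relabelling, stratified attenuation, and the
bidirectional null. The studies are what the test suite asserts against
and what the acceptance script reports.

Every study takes a master seed and derives one child seed per
replicate, so results are reproducible and replicates independent.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from . import synthetic
from .coloc import ColocPriors, coloc_enumeration_oracle, coloc_posteriors
from .io_formats import SummaryStatRecord, SummaryStatsTable
from .mediation import run_network_mediation
from .mr import HarmonizedPair, bidirectional_mr, harmonize_pairs, ivw_random_effects, wald_ratio
from .phewas import GRSWeights, run_phewas, run_stratified_grs
from .pipeline import demo_config, run_pipeline, write_report
from .synthetic import SimConfig


def _child_seeds(seed: int, n: int) -> list[int]:
    # uint32 state words, comfortably below 2**31 after masking
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# IVW estimator: bias, coverage, heterogeneity calibration
# ---------------------------------------------------------------------------

IVW_TRUE_LOG_OR = -0.105


def _ivw_regime(seed: int, **overrides) -> SimConfig:
    """Two instruments at the study's strengths; one binary outcome trait."""
    defaults = dict(
        seed=seed,
        exposure_n=10_000,
        panel_size=1,
        panel_signal_fraction=1.0,
        panel_theta_fixed=IVW_TRUE_LOG_OR,
        panel_trait_type="case-control",
        panel_n=100_000,
        panel_case_fraction=0.25,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def ivw_recovery_study(seed: int, n_reps: int = 1000) -> dict:
    """Bias and 95% CI coverage of random-effects IVW at the 2-instrument regime."""
    ests, covered = [], 0
    for s in _child_seeds(seed, n_reps):
        panel = synthetic.simulate_omics_panel(_ivw_regime(s))
        res = ivw_random_effects(harmonize_pairs(panel.exposure, panel.outcomes[0]))
        ests.append(res.estimate)
        covered += res.ci_low <= IVW_TRUE_LOG_OR <= res.ci_high
    return {
        "true_log_or": IVW_TRUE_LOG_OR,
        "mean_estimate": float(np.mean(ests)),
        "bias": float(np.mean(ests) - IVW_TRUE_LOG_OR),
        "coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def q_calibration_study(seed: int, n_reps: int = 2000) -> dict:
    """Cochran's Q rejection rate at alpha=0.05 under 5 homogeneous instruments."""
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        cfg = _ivw_regime(
            s,
            instrument_ids=tuple(f"v{i}" for i in range(5)),
            instrument_chrom=("1",) * 5,
            instrument_pos=tuple(range(100, 105)),
            instrument_effect_allele=("A",) * 5,
            instrument_other_allele=("G",) * 5,
            instrument_eaf=(0.2, 0.3, 0.4, 0.3, 0.25),
            instrument_r2=(0.006,) * 5,
        )
        panel = synthetic.simulate_omics_panel(cfg)
        res = ivw_random_effects(harmonize_pairs(panel.exposure, panel.outcomes[0]))
        rejections += res.q_pvalue < 0.05
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

def mediation_recovery_study(seed: int, n_reps: int = 500) -> dict:
    """Median recovered proportion mediated and CI coverage at truth 1/3."""
    props, covered = [], 0
    truth = SimConfig().proportion_mediated_truth
    for s in _child_seeds(seed, n_reps):
        chain = synthetic.simulate_mediation_chain(SimConfig(seed=s))
        res = run_network_mediation(
            chain.exposure, chain.mediator, chain.outcome,
            chain.exposure_instruments, mediator_ld=chain.mediator_ld,
        )
        props.append(res.proportion)
        lo, hi = res.ci_proportion
        covered += lo <= truth <= hi
    return {
        "true_proportion": truth,
        "median_proportion": float(np.median(props)),
        "ci_coverage": covered / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def coloc_oracle_agreement_study(seed: int, n_regions: int = 100) -> dict:
    """Max |PP difference| between log-space posteriors and enumeration oracle."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for s in _child_seeds(seed, n_regions):
        m = int(rng.integers(2, 21))
        cfg = SimConfig(
            seed=s, region_n_snps=m,
            region_ld_decay=float(rng.uniform(0.0, 0.4)),
            region_causal_z=float(rng.uniform(2.0, 10.0)),
        )
        scenario = str(rng.choice(synthetic.SCENARIOS))
        pair = synthetic.simulate_region_pair(cfg, scenario)
        pp = coloc_posteriors(pair).pp
        pp_oracle = coloc_enumeration_oracle(pair)
        max_diff = max(max_diff, float(np.max(np.abs(pp - pp_oracle))))
    return {"max_abs_pp_diff": max_diff, "n_regions": n_regions}


def coloc_discrimination_study(seed: int, n_reps: int = 200) -> dict:
    """Mean posteriors under shared (H4) vs distinct (H3) causal variants."""
    pp4_h4, pp3_h3, pp4_h3 = [], [], []
    for s in _child_seeds(seed, n_reps):
        cfg = SimConfig(seed=s)  # m=200, AR-1 decay 0.9, |z| ~ 8
        res4 = coloc_posteriors(synthetic.simulate_region_pair(cfg, "H4"))
        res3 = coloc_posteriors(synthetic.simulate_region_pair(cfg, "H3"))
        pp4_h4.append(res4.pp4)
        pp3_h3.append(res3.pp3)
        pp4_h3.append(res3.pp4)
    return {
        "mean_pp4_under_h4": float(np.mean(pp4_h4)),
        "mean_pp3_under_h3": float(np.mean(pp3_h3)),
        "mean_pp4_under_h3": float(np.mean(pp4_h3)),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# PheWAS scan
# ---------------------------------------------------------------------------

def phewas_calibration_study(
    seed: int,
    n_reps: int = 25,
    n_individuals: int = 20_000,
    n_phecodes: int = 300,
    min_cases: int = 200,
) -> dict:
    """Type-I error, BH false discoveries, and case filtering on all-null scans."""
    n_tests = n_p05 = 0
    fdp_events = 0  # all phecodes null, so FDP is 1 iff anything is discovered
    filter_violations = 0
    n_filtered = 0  # phecodes kept out of the scan by the case-count floor
    for s in _child_seeds(seed, n_reps):
        cfg = SimConfig(
            seed=s, n_individuals=n_individuals,
            n_phecodes=n_phecodes, n_null_phecodes=n_phecodes,
        )
        cohort = synthetic.simulate_cohort(cfg)
        weights = GRSWeights.from_summary_stats(
            synthetic.instrument_exposure_table(cfg)
        )
        table = run_phewas(cohort, weights, min_cases=min_cases)
        ok = table[table["converged"]]
        n_tests += len(ok)
        n_p05 += int((ok["pvalue"] < 0.05).sum())
        fdp_events += int(ok["significant"].any())
        filter_violations += int((table["n_cases"] < min_cases).sum())
        n_filtered += n_phecodes - len(table)
    return {
        "type1_rate": n_p05 / n_tests,
        "n_tests": n_tests,
        "mean_fdp": fdp_events / n_reps,
        "fdp_events": fdp_events,
        "n_reps": n_reps,
        "min_case_filter_violations": filter_violations,
        "n_excluded_by_case_filter": n_filtered,
    }


# ---------------------------------------------------------------------------
# harmonization invariance
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _relabel(rec: SummaryStatRecord, swap: bool, flip: bool) -> SummaryStatRecord:
    out = rec
    if swap:
        out = out.with_alleles_swapped()
    if flip:
        from dataclasses import replace
        out = replace(out, effect_allele=_COMP[out.effect_allele],
                      other_allele=_COMP[out.other_allele])
    return out


def harmonization_invariance_study(seed: int, n_fuzz: int = 1000) -> dict:
    """IVW shift under random allele relabellings of the outcome table.

    The fixture has six non-palindromic instruments plus one palindromic
    variant at frequency 1/2, which must always be excluded as
    unresolvable.
    """
    rng = np.random.default_rng(seed)
    alleles = [("A", "G"), ("T", "C"), ("G", "C"), ("C", "A"), ("T", "G"), ("G", "A")]
    exp_recs, out_recs = [], []
    for i, (ea, oa) in enumerate(alleles):
        exp_recs.append(SummaryStatRecord(
            variant_id=f"v{i}", effect_allele=ea, other_allele=oa,
            beta=float(rng.uniform(0.05, 0.2)), se=0.01, eaf=float(rng.uniform(0.1, 0.45)),
        ))
        out_recs.append(SummaryStatRecord(
            variant_id=f"v{i}", effect_allele=ea, other_allele=oa,
            beta=float(rng.normal(0.02, 0.01)), se=0.008, eaf=exp_recs[-1].eaf,
        ))
    # ambiguous palindromic variant: A/T at frequency 1/2
    exp_recs.append(SummaryStatRecord(
        variant_id="pal", effect_allele="A", other_allele="T",
        beta=0.1, se=0.01, eaf=0.5,
    ))
    out_recs.append(SummaryStatRecord(
        variant_id="pal", effect_allele="A", other_allele="T",
        beta=0.02, se=0.008, eaf=0.5,
    ))
    exposure = SummaryStatsTable(trait_id="exp", records=exp_recs)
    baseline = ivw_random_effects(harmonize_pairs(
        exposure, SummaryStatsTable(trait_id="out", records=out_recs)
    ))
    max_shift = 0.0
    palindromic_ok = True
    for _ in range(n_fuzz):
        fuzzed = [
            _relabel(r, swap=bool(rng.integers(2)), flip=bool(rng.integers(2)))
            for r in out_recs
        ]
        pairs = harmonize_pairs(
            exposure, SummaryStatsTable(trait_id="out", records=fuzzed)
        )
        res = ivw_random_effects(pairs)
        max_shift = max(max_shift, abs(res.estimate - baseline.estimate),
                        abs(res.se - baseline.se))
        pal = next(p for p in pairs if p.variant_id == "pal")
        palindromic_ok &= pal.status == "excluded:palindromic_ambiguous"
    return {
        "max_ivw_shift": max_shift,
        "palindromic_always_excluded": palindromic_ok,
        "n_fuzz": n_fuzz,
    }


def single_instrument_identity_check() -> dict:
    """J=1 IVW vs Wald ratio, and J=2 homogeneity degeneracy, bit-for-bit."""
    p1 = HarmonizedPair(variant_id="a", beta_exposure=0.14, se_exposure=0.016,
                        beta_outcome=-0.0147, se_outcome=0.012)
    single = ivw_random_effects([p1])
    wr, wr_se = wald_ratio(p1)
    # two instruments with exactly equal ratios
    p2 = HarmonizedPair(variant_id="b", beta_exposure=0.11, se_exposure=0.016,
                        beta_outcome=0.11 * (p1.beta_outcome / p1.beta_exposure),
                        se_outcome=0.009)
    double = ivw_random_effects([p1, p2])
    return {
        "single_estimate_diff": abs(single.estimate - wr),
        "single_se_diff": abs(single.se - wr_se),
        "homogeneous_q": double.q,
        "re_vs_fixed_se_diff": abs(double.se - double.se_fixed),
    }


# ---------------------------------------------------------------------------
# stratified attenuation and bidirectional null
# ---------------------------------------------------------------------------

def stratified_attenuation_study(
    seed: int, n_reps: int = 200, n_individuals: int = 20_000
) -> dict:
    """Abstainer-stratum null and consumer-stratum recovery of the GRS effect.

    The outcome is the continuous mediator (BMI-like), standardized, so
    the consumer-stratum truth is gamma * sd(GRS genetic component).
    """
    abst_cover0 = cons_cover_truth = 0
    cons_est = []
    truth = None
    for s in _child_seeds(seed, n_reps):
        cfg = SimConfig(seed=s, n_individuals=n_individuals,
                        n_phecodes=1, n_null_phecodes=1)
        cohort = synthetic.simulate_cohort(cfg)
        weights = GRSWeights.from_summary_stats(
            synthetic.instrument_exposure_table(cfg)
        )
        truth = cohort.truth["grs_effect_mediator_consumers"]
        table = run_stratified_grs(cohort, weights, outcome="mediator",
                                   outcome_type="continuous")
        abst = table[table["stratum"] == "abstainer"].iloc[0]
        cons = table[table["stratum"] == "consumer"].iloc[0]
        abst_cover0 += abst["ci_low"] <= 0.0 <= abst["ci_high"]
        cons_cover_truth += cons["ci_low"] <= truth <= cons["ci_high"]
        cons_est.append(cons["estimate"])
    return {
        "abstainer_ci_covers_zero_rate": abst_cover0 / n_reps,
        "consumer_ci_covers_truth_rate": cons_cover_truth / n_reps,
        "consumer_mean_estimate": float(np.mean(cons_est)),
        "consumer_truth": truth,
        "n_reps": n_reps,
    }


def bidirectional_null_study(seed: int, n_reps: int = 200) -> dict:
    """Forward power and reverse-direction null under A->B-only causality."""
    fwd_sig = rev_null = 0
    for s in _child_seeds(seed, n_reps):
        tabs = synthetic.simulate_bidirectional_tables(SimConfig(seed=s))
        fwd, rev = bidirectional_mr(
            tabs.trait_a, tabs.trait_b, tabs.instruments_a, tabs.instruments_b
        )
        fwd_sig += not (fwd.ci_low <= 0.0 <= fwd.ci_high)
        rev_null += rev.pvalue > 0.05
    return {
        "forward_ci_excludes_zero_rate": fwd_sig / n_reps,
        "reverse_p_above_05_rate": rev_null / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# end-to-end determinism
# ---------------------------------------------------------------------------

def pipeline_determinism_study(seed: int, workdir) -> dict:
    """Run the demo pipeline twice at one seed and byte-compare the outputs."""
    workdir = Path(workdir)
    outputs = []
    for run_idx in (1, 2):
        outdir = workdir / f"run{run_idx}"
        cfg = demo_config(seed=seed, outdir=str(outdir))
        report = run_pipeline(cfg)
        files = write_report(report, outdir)
        outputs.append({f.name: f.read_bytes() for f in files})
    identical = outputs[0].keys() == outputs[1].keys() and all(
        outputs[0][k] == outputs[1][k] for k in outputs[0]
    )
    return {"byte_identical": identical, "n_files": len(outputs[0])}
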