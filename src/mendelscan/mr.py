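"""Summary-data two-sample Mendelian randomization.

The causal effect of an exposure on an outcome is estimated from
per-variant association statistics measured in separate samples. Each
instrument j contributes a Wald ratio r_j = beta_out,j / beta_exp,j;
the inverse-variance weighted (IVW) estimate pools them with first-order
weights w_j = beta_exp,j^2 / se_out,j^2 (exposure-side uncertainty
ignored, the standard NOME approximation), which is identical to a
weighted regression of outcome betas on exposure betas through the
origin. Heterogeneity between ratios is summarised by Cochran's Q,
chi-square with J-1 df under homogeneity; the multiplicative
random-effects model inflates the fixed-effect standard error by
max(1, sqrt(Q/df)) so that under-dispersion never shrinks it.

Before any of this, exposure and outcome tables must be harmonized onto
the same effect allele — handling swapped allele order, strand flips,
and strand-ambiguous (palindromic) variants, the latter resolved by
allele frequency or excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import AnalysisError
from .io_formats import SummaryStatRecord, SummaryStatsTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Minor-allele-frequency ceiling below which a palindromic variant's
#: strand can be resolved by comparing frequencies across datasets.
PALINDROMIC_MAF_MAX = 0.42


def _complement_allele(a: str) -> str:
    return _COMPLEMENT[a]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or C/G variants look identical on both strands."""
    return _COMPLEMENT[effect_allele] == other_allele


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one variant on a shared effect allele."""

    variant_id: str
    beta_exposure: float = math.nan
    se_exposure: float = math.nan
    beta_outcome: float = math.nan
    se_outcome: float = math.nan
    eaf_exposure: float = math.nan
    eaf_outcome: float = math.nan
    action_taken: str = "unchanged"  # unchanged | swapped | strand_flipped | swapped_and_flipped
    status: str = "kept"  # kept | excluded:<reason>

    @property
    def kept(self) -> bool:
        return self.status == "kept"


def _harmonize_one(exp: SummaryStatRecord, out: SummaryStatRecord) -> HarmonizedPair:
    ea, oa = exp.effect_allele, exp.other_allele

    def pair(out_rec: SummaryStatRecord, action: str, status: str = "kept") -> HarmonizedPair:
        return HarmonizedPair(
            variant_id=exp.variant_id,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=out_rec.beta,
            se_outcome=out_rec.se,
            eaf_exposure=exp.eaf,
            eaf_outcome=out_rec.eaf,
            action_taken=action,
            status=status,
        )

    def excluded(reason: str) -> HarmonizedPair:
        return HarmonizedPair(variant_id=exp.variant_id, status=f"excluded:{reason}")

    if is_palindromic(ea, oa):
        # allele labels cannot resolve strand; {ea, oa} is complement-invariant
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            return excluded("allele_mismatch")
        if math.isnan(exp.eaf) or math.isnan(out.eaf):
            return excluded("palindromic_ambiguous")
        maf_exp = min(exp.eaf, 1.0 - exp.eaf)
        maf_out = min(out.eaf, 1.0 - out.eaf)
        if maf_exp >= PALINDROMIC_MAF_MAX or maf_out >= PALINDROMIC_MAF_MAX:
            return excluded("palindromic_ambiguous")
        # frequency alignment: the outcome's effect allele is the one whose
        # frequency sits on the same side of 1/2 as the exposure's
        if (out.eaf < 0.5) == (exp.eaf < 0.5):
            return pair(out, "unchanged")
        return pair(out.with_alleles_swapped(), "swapped")

    if (out.effect_allele, out.other_allele) == (ea, oa):
        return pair(out, "unchanged")
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return pair(out.with_alleles_swapped(), "swapped")
    flipped_ea = _complement_allele(out.effect_allele)
    flipped_oa = _complement_allele(out.other_allele)
    if (flipped_ea, flipped_oa) == (ea, oa):
        return pair(out, "strand_flipped")
    if (flipped_ea, flipped_oa) == (oa, ea):
        return pair(out.with_alleles_swapped(), "swapped_and_flipped")
    return excluded("allele_mismatch")


def harmonize_pairs(
    exposure: SummaryStatsTable, outcome: SummaryStatsTable
) -> list[HarmonizedPair]:
    """Align outcome effects onto the exposure's effect alleles.

    Variants are intersected on id; allele order swaps negate the
    outcome beta and complement its frequency; strand flips are
    attempted where plain matching fails. Palindromic variants are kept
    and frequency-aligned only when both frequencies are present and
    both minor-allele frequencies are below 0.42, otherwise excluded
    with reason ``palindromic_ambiguous``.
    """
    out_by_id = {r.variant_id: r for r in outcome.records}
    shared = [r for r in exposure.records if r.variant_id in out_by_id]
    if not shared:
        raise AnalysisError(
            f"no shared variants between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )
    return [_harmonize_one(exp, out_by_id[exp.variant_id]) for exp in shared]


@dataclass(frozen=True)
class MRResult:
    """Causal-effect estimate per 1 SD increase in the exposure."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    method: str
    q: float = math.nan
    q_df: int = 0
    q_pvalue: float = math.nan
    se_fixed: float = math.nan

    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, lower, upper) for log-odds-scale estimates."""
        return math.exp(self.estimate), math.exp(self.ci_low), math.exp(self.ci_high)


def wald_ratio(pair: HarmonizedPair) -> tuple[float, float]:
    """Single-instrument ratio estimate and first-order SE.

    Exposure-side uncertainty is ignored (NOME approximation).
    """
    if pair.beta_exposure == 0:
        raise AnalysisError(f"zero exposure beta for {pair.variant_id}")
    r = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return r, se


def ivw_random_effects(pairs: list[HarmonizedPair]) -> MRResult:
    """Multiplicative random-effects IVW estimate over kept pairs.

    With one instrument this reduces exactly to the Wald ratio; Q is
    undefined. With J >= 2 the standard error is the fixed-effect SE
    scaled by max(1, sqrt(Q/(J-1))).
    """
    kept = [p for p in pairs if p.kept]
    if not kept:
        raise AnalysisError("no kept instrument pairs")
    bx = np.array([p.beta_exposure for p in kept])
    by = np.array([p.beta_outcome for p in kept])
    sy = np.array([p.se_outcome for p in kept])
    if np.any(bx == 0):
        raise AnalysisError("zero exposure beta among kept pairs")
    if np.any(sy <= 0):
        raise AnalysisError("non-positive outcome SE among kept pairs")
    ratios = by / bx
    weights = bx**2 / sy**2
    j = len(kept)
    if j == 1:
        # exact Wald-ratio arithmetic so the J=1 identity is bit-for-bit
        theta = float(ratios[0])
        se_fixed = float(sy[0] / abs(bx[0]))
    else:
        theta = float(np.sum(weights * ratios) / np.sum(weights))
        se_fixed = float(1.0 / math.sqrt(np.sum(weights)))
    if j == 1:
        se = se_fixed  # identical to the Wald-ratio SE
        q = math.nan
        q_df = 0
        q_p = math.nan
        method = "wald_ratio"
    else:
        q = float(np.sum(weights * (ratios - theta) ** 2))
        q_df = j - 1
        q_p = float(stats.chi2.sf(q, q_df))
        se = se_fixed * max(1.0, math.sqrt(q / q_df))
        method = "ivw_mre"
    p = float(2.0 * stats.norm.sf(abs(theta) / se))
    return MRResult(
        estimate=theta,
        se=se,
        ci_low=theta - 1.96 * se,
        ci_high=theta + 1.96 * se,
        pvalue=p,
        n_snps=j,
        method=method,
        q=q,
        q_df=q_df,
        q_pvalue=q_p,
        se_fixed=se_fixed,
    )


@dataclass
class PanelScanResult:
    """Panel-wide MR scan: one IVW result per trait plus BH q-values."""

    table: pd.DataFrame
    results: dict[str, MRResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def mr_scan_panel(
    exposure: SummaryStatsTable,
    panel: list[SummaryStatsTable],
    fdr: float = 0.05,
) -> PanelScanResult:
    """IVW MR of one exposure against every trait in an omics panel.

    Benjamini-Hochberg q-values are computed over exactly the traits
    whose harmonization and estimation succeeded; failures are reported
    with their reason and excluded from the multiplicity set.
    """
    if not panel:
        raise AnalysisError("empty outcome panel")
    results: dict[str, MRResult] = {}
    failures: dict[str, str] = {}
    for outcome in panel:
        try:
            pairs = harmonize_pairs(exposure, outcome)
            results[outcome.trait_id] = ivw_random_effects(pairs)
        except AnalysisError as exc:
            failures[outcome.trait_id] = str(exc)
    rows = []
    ids = list(results)
    if ids:
        pvals = np.array([results[t].pvalue for t in ids])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for t, qv in zip(ids, qvals):
            r = results[t]
            rows.append({
                "trait_id": t, "estimate": r.estimate, "se": r.se,
                "ci_low": r.ci_low, "ci_high": r.ci_high, "pvalue": r.pvalue,
                "q_value": float(qv), "significant": bool(qv < fdr),
                "n_snps": r.n_snps, "q_stat": r.q, "q_pvalue": r.q_pvalue,
                "status": "ok",
            })
    for t, reason in failures.items():
        rows.append({"trait_id": t, "status": f"failed:{reason}"})
    table = pd.DataFrame(rows)
    if len(table) and "pvalue" in table:
        table = table.sort_values(
            ["status", "pvalue"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    return PanelScanResult(table=table, results=results, failures=failures)


def bidirectional_mr(
    trait_a: SummaryStatsTable,
    trait_b: SummaryStatsTable,
    instruments_a: list[str],
    instruments_b: list[str],
) -> tuple[MRResult, MRResult]:
    """Forward (A→B) and reverse (B→A) IVW, each with its own instruments.

    ``trait_a``/``trait_b`` carry each trait's associations for the
    union of both instrument sets; the two directions are computed
    independently.
    """
    forward = ivw_random_effects(
        harmonize_pairs(trait_a.subset(instruments_a), trait_b)
    )
    reverse = ivw_random_effects(
        harmonize_pairs(trait_b.subset(instruments_b), trait_a)
    )
    return forward, reverse


def clump_by_ld(
    table: SummaryStatsTable,
    ld: pd.DataFrame,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
) -> list[str]:
    """Greedy LD clumping of genome-wide-significant variants.

    Variants passing ``p_threshold`` are visited in ascending p-value
    order; a variant is retained iff its squared correlation with every
    already-retained variant is below ``r2_threshold``.
    """
    passing = [r for r in table.records if not math.isnan(r.pvalue) and r.pvalue < p_threshold]
    missing = [r.variant_id for r in passing if r.variant_id not in ld.index]
    if missing:
        raise AnalysisError(f"LD matrix lacks entries for {missing}")
    passing.sort(key=lambda r: (r.pvalue, r.variant_id))
    kept: list[str] = []
    for rec in passing:
        r2 = ld.loc[rec.variant_id, kept].to_numpy(dtype=float) ** 2 if kept else np.array([])
        if np.all(r2 < r2_threshold):
            kept.append(rec.variant_id)
    return kept


def variance_explained(record: SummaryStatRecord) -> float:
    """Trait variance explained by one variant: R^2 = 2 f (1-f) beta^2.

    Valid for a standardized (unit-variance) trait under Hardy-Weinberg.
    """
    if math.isnan(record.eaf):
        raise AnalysisError(f"variant {record.variant_id}: eaf required for variance explained")
    f = record.eaf
    return 2.0 * f * (1.0 - f) * record.beta**2
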