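"""Two-step network MR mediation.

How much of an exposure's causal effect on an outcome flows through a
mediator? With summary data from non-overlapping samples the question
is answered by composing MR estimates:

  step 1   a = exposure -> mediator   (exposure's own instruments)
  step 2   b = mediator -> outcome    (the mediator's instruments)
  total    t = exposure -> outcome    (exposure's own instruments)

The indirect effect is the product a*b, the proportion mediated is
a*b / t, and standard errors follow by first-order propagation of
error treating the three estimates as independent — appropriate when
each comes from a distinct sample. Confidence intervals are symmetric
and deliberately untruncated: a proportion outside [0, 1] is a signal
about the model, not a reporting error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import AnalysisError
from .io_formats import SummaryStatsTable
from .mr import MRResult, clump_by_ld, harmonize_pairs, ivw_random_effects


def indirect_effect(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Product-of-coefficients indirect effect with propagated SE.

    SE = sqrt(a^2 se_b^2 + b^2 se_a^2), the first-order (delta-method)
    variance of a product of independent estimates.
    """
    for name, v in (("a", a), ("se_a", se_a), ("b", b), ("se_b", se_b)):
        if not math.isfinite(v):
            raise AnalysisError(f"non-finite input {name}={v}")
    if se_a < 0 or se_b < 0:
        raise AnalysisError("standard errors must be non-negative")
    est = a * b
    se = math.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    return est, se


def proportion_mediated(
    indirect: float,
    se_indirect: float,
    total: float,
    se_total: float,
    *,
    denominator_uncertainty: bool = True,
) -> tuple[float, float, tuple[float, float]]:
    """Proportion of the total effect routed through the mediator.

    p = indirect / total, with delta-method SE for a ratio of
    independent estimates:

        SE_p = |p| sqrt((se_ind/indirect)^2 + (se_t/total)^2)

    falling back to se_ind/|total| when the indirect effect is exactly
    zero. ``denominator_uncertainty=False`` drops the total-effect term
    (numerator-only propagation). Returns (p, SE_p, (lo, hi)) with a
    symmetric untruncated 95% CI.
    """
    if total == 0:
        raise AnalysisError("total effect is zero; proportion mediated undefined")
    p = indirect / total
    if indirect == 0:
        se_p = se_indirect / abs(total)
    elif denominator_uncertainty:
        se_p = abs(p) * math.sqrt(
            (se_indirect / indirect) ** 2 + (se_total / total) ** 2
        )
    else:
        se_p = se_indirect / abs(total)
    ci = (p - 1.96 * se_p, p + 1.96 * se_p)
    return p, se_p, ci


@dataclass(frozen=True)
class MediationResult:
    """Full decomposition of a total effect into direct and mediated paths."""

    total: float
    se_total: float
    step1: float  # exposure -> mediator
    se_step1: float
    step2: float  # mediator -> outcome
    se_step2: float
    indirect: float
    se_indirect: float
    proportion: float
    se_proportion: float
    ci_proportion: tuple[float, float]
    direct: float
    n_mediator_instruments: int
    #: how the proportion's SE was propagated (output metadata)
    se_method: str = "numerator_and_denominator"
    #: numerator-only alternative, reported alongside the default
    se_proportion_numerator_only: float = math.nan

    def to_dict(self) -> dict:
        return {
            "total": self.total, "se_total": self.se_total,
            "step1_exposure_to_mediator": self.step1, "se_step1": self.se_step1,
            "step2_mediator_to_outcome": self.step2, "se_step2": self.se_step2,
            "indirect": self.indirect, "se_indirect": self.se_indirect,
            "direct": self.direct,
            "proportion_mediated": self.proportion,
            "se_proportion": self.se_proportion,
            "ci_proportion_low": self.ci_proportion[0],
            "ci_proportion_high": self.ci_proportion[1],
            "proportion_se_method": self.se_method,
            "se_proportion_numerator_only": self.se_proportion_numerator_only,
            "n_mediator_instruments": self.n_mediator_instruments,
        }


def run_network_mediation(
    exposure_ss: SummaryStatsTable,
    mediator_ss: SummaryStatsTable,
    outcome_ss: SummaryStatsTable,
    exposure_instruments: list[str],
    mediator_instruments: list[str] | None = None,
    *,
    mediator_ld: pd.DataFrame | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
) -> MediationResult:
    """Two-step network MR from three summary-statistics tables.

    ``exposure_ss`` holds the exposure instruments' associations with
    the exposure; ``mediator_ss`` holds associations with the mediator
    for both the exposure instruments (step 1 outcomes) and the mediator
    instrument candidates; ``outcome_ss`` holds associations with the
    outcome for everything.

    Mediator instruments are either supplied explicitly or selected by
    greedy LD clumping (p < ``p_threshold``, pairwise r^2 <
    ``r2_threshold``) among ``mediator_ss`` variants. The exposure's own
    instruments are excluded from that candidate set: they associate
    with the mediator only through the exposure, so using them as
    mediator instruments would fold the exposure's direct path into
    step 2.
    """
    if mediator_instruments is None:
        if mediator_ld is None:
            raise AnalysisError(
                "either mediator_instruments or mediator_ld must be supplied"
            )
        candidates = SummaryStatsTable(
            trait_id=mediator_ss.trait_id,
            records=[
                r for r in mediator_ss.records
                if r.variant_id not in set(exposure_instruments)
            ],
            trait_type=mediator_ss.trait_type,
        )
        mediator_instruments = clump_by_ld(
            candidates, mediator_ld, p_threshold=p_threshold, r2_threshold=r2_threshold
        )
    if not mediator_instruments:
        raise AnalysisError("no mediator instruments after selection")

    exp_tbl = exposure_ss.subset(exposure_instruments)
    step1 = ivw_random_effects(harmonize_pairs(exp_tbl, mediator_ss))
    total = ivw_random_effects(harmonize_pairs(exp_tbl, outcome_ss))

    med_tbl = mediator_ss.subset(mediator_instruments)
    step2 = ivw_random_effects(harmonize_pairs(med_tbl, outcome_ss))

    return compose_mediation(total, step1, step2)


def compose_mediation(
    total: MRResult, step1: MRResult, step2: MRResult
) -> MediationResult:
    """Assemble a MediationResult from the three MR estimates."""
    ind, se_ind = indirect_effect(step1.estimate, step1.se, step2.estimate, step2.se)
    prop, se_prop, ci = proportion_mediated(ind, se_ind, total.estimate, total.se)
    _, se_prop_num, _ = proportion_mediated(
        ind, se_ind, total.estimate, total.se, denominator_uncertainty=False
    )
    return MediationResult(
        total=total.estimate, se_total=total.se,
        step1=step1.estimate, se_step1=step1.se,
        step2=step2.estimate, se_step2=step2.se,
        indirect=ind, se_indirect=se_ind,
        proportion=prop, se_proportion=se_prop, ci_proportion=ci,
        direct=total.estimate - ind,
        n_mediator_instruments=step2.n_snps,
        se_proportion_numerator_only=se_prop_num,
    )
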