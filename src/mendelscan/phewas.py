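"""Weighted genetic risk score and phenome-wide association scan.

A weighted GRS sums each individual's dosage of the trait-increasing
allele at every instrument variant, weighted by the variant's effect on
the trait, and is standardized to mean 0 / SD 1. The phenome-wide scan
fits one logistic regression per clinical phenotype (phecode) against
the standardized GRS with age, sex and 10 genetic principal components
as covariates, keeps phenotypes with at least 200 cases, and controls
the false discovery rate across the scan with Benjamini-Hochberg.

Logistic fits use a hand-rolled iteratively reweighted least squares
(Newton-Raphson) solver: a scan is thousands of fits against a shared
design matrix, and the solver exploits that regime. Non-converged or
separated fits are flagged and excluded from the multiplicity set
rather than assigned a p-value. The same machinery serves the
consumption-stratified pleiotropy check, where associations driven by
the exposure should attenuate in the stratum that does not consume it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import expit, logit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .exceptions import AnalysisError
from .io_formats import SummaryStatsTable
from .synthetic import CohortBundle

#: coefficient magnitude beyond which a "converged" logistic fit is
#: treated as separated (log-OR scale; e^50 per unit is not a real effect)
SEPARATION_COEF_LIMIT = 50.0


@dataclass(frozen=True)
class GRSWeight:
    variant_id: str
    allele: str  # the allele the weight refers to (and dosages count)
    other_allele: str
    weight: float


@dataclass
class GRSWeights:
    """Per-variant weights for a weighted genetic risk score."""

    weights: list[GRSWeight]

    def __post_init__(self) -> None:
        ids = [w.variant_id for w in self.weights]
        if len(set(ids)) != len(ids):
            raise AnalysisError("duplicate variant in GRS weights")

    def __len__(self) -> int:
        return len(self.weights)

    def __iter__(self):
        return iter(self.weights)

    @classmethod
    def from_summary_stats(cls, table: SummaryStatsTable) -> "GRSWeights":
        return cls([
            GRSWeight(r.variant_id, r.effect_allele, r.other_allele, r.beta)
            for r in table.records
        ])

    def oriented(self) -> "GRSWeights":
        """Weights re-expressed on the trait-increasing allele (all >= 0).

        A negative weight on allele A is the same association as a
        positive weight on the other allele with dosage 2 - d.
        """
        out = []
        for w in self.weights:
            if w.weight < 0:
                out.append(GRSWeight(w.variant_id, w.other_allele, w.allele, -w.weight))
            else:
                out.append(w)
        return GRSWeights(out)


def build_weighted_grs(
    genotypes: pd.DataFrame,
    weights: GRSWeights,
    counted_alleles: dict[str, str] | None = None,
) -> np.ndarray:
    """Standardized weighted allele score over a genotype table.

    ``genotypes`` holds dosages in [0, 2], one column per variant.
    ``counted_alleles`` names the allele each dosage column counts; by
    default it is the allele each weight refers to. Orientation makes
    every weight non-negative on the increasing allele before summing,
    so supplying a weight on the decreasing allele changes nothing.
    """
    oriented = weights.oriented()
    raw = np.zeros(len(genotypes))
    for orig, w in zip(weights, oriented):
        if w.variant_id not in genotypes.columns:
            raise AnalysisError(f"variant {w.variant_id} missing from genotype table")
        d = genotypes[w.variant_id].to_numpy(dtype=float)
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise AnalysisError(f"dosages for {w.variant_id} outside [0, 2]")
        counted = (counted_alleles or {}).get(w.variant_id, orig.allele)
        if counted not in (w.allele, w.other_allele):
            raise AnalysisError(
                f"genotype table counts allele {counted!r} for {w.variant_id}, "
                f"which is neither weight allele"
            )
        if counted != w.allele:
            d = 2.0 - d
        raw += w.weight * d
    sd = float(np.std(raw))
    if np.ptp(raw) == 0.0 or sd < 1e-12 * max(1.0, float(np.max(np.abs(raw)))):
        raise AnalysisError("raw GRS has zero variance")
    return (raw - float(np.mean(raw))) / sd


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    converged: bool
    n_iter: int

    def term(self, index: int) -> tuple[float, float, float]:
        """(log-OR, SE, p) for one design column."""
        return float(self.coef[index]), float(self.se[index]), float(self.pvalues[index])


def fit_logistic_glm(
    y: np.ndarray,
    design: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    Newton-Raphson on the log-likelihood; Wald standard errors from the
    observed information at the optimum. Fits that fail to converge,
    hit a singular information matrix mid-path, or converge to
    separation-scale coefficients are returned with ``converged=False``
    and must not be interpreted.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(design, dtype=float)
    if y.ndim != 1 or x.shape[0] != y.shape[0]:
        raise AnalysisError("outcome and design have mismatched lengths")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise AnalysisError("outcome must be binary with both classes present")

    p = x.shape[1]
    beta = np.zeros(p)
    has_intercept = bool(np.all(x[:, 0] == 1.0))
    if has_intercept:
        beta[0] = float(logit(y.mean()))

    converged = False
    factor = None
    it = 0
    for it in range(1, max_iter + 1):
        eta = x @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = (x * w[:, None]).T @ x
        grad = x.T @ (y - mu)
        try:
            factor = cho_factor(info)
        except LinAlgError:
            if it == 1:
                raise AnalysisError(
                    "design matrix is rank deficient or fit degenerate"
                ) from None
            factor = None
            break  # information singular mid-path: separation territory
        step = cho_solve(factor, grad)
        beta = beta + step
        if float(np.max(np.abs(step))) < tol:
            converged = True
            break
    if converged and float(np.max(np.abs(beta))) > SEPARATION_COEF_LIMIT:
        converged = False

    if factor is not None:
        cov = cho_solve(factor, np.eye(p))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    else:
        se = np.full(p, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = 2.0 * norm.sf(np.abs(beta) / se)
    return LogisticFit(coef=beta, se=se, pvalues=pvals, converged=converged, n_iter=it)


def _covariate_design(cohort: CohortBundle, grs: np.ndarray) -> np.ndarray:
    cov = cohort.covariates
    cols = [np.ones(cohort.n), grs, cov["age"].to_numpy(dtype=float),
            cov["sex"].to_numpy(dtype=float)]
    cols += [cov[f"pc{k + 1}"].to_numpy(dtype=float) for k in range(10)]
    return np.column_stack(cols)


def run_phewas(
    cohort: CohortBundle,
    weights: GRSWeights,
    min_cases: int = 200,
    fdr: float = 0.05,
    sex_filter: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Phenome-wide logistic scan of phecodes against the standardized GRS.

    One fit per phecode with at least ``min_cases`` cases (and at least
    one control), adjusting for age, sex and 10 principal components.
    Benjamini-Hochberg q-values are computed over exactly the eligible,
    converged phecodes and rows are sorted by p-value. ``sex_filter``
    optionally restricts named phecodes to one sex (phecode conventions
    define such restrictions; they are an input here, never inferred).
    """
    grs = build_weighted_grs(cohort.genotypes, weights)
    design = _covariate_design(cohort, grs)
    rows = []
    for col in cohort.phecodes.columns:
        y = cohort.phecodes[col].to_numpy(dtype=float)
        d = design
        if sex_filter and col in sex_filter:
            mask = cohort.covariates["sex"].to_numpy() == sex_filter[col]
            y, d = y[mask], design[mask]
        n_cases = int(y.sum())
        n_controls = int(len(y) - n_cases)
        if n_cases < min_cases or n_controls < 1:
            continue
        try:
            fit = fit_logistic_glm(y, d)
        except AnalysisError:
            continue
        log_or, se, p = fit.term(1)
        rows.append({
            "phecode": col, "n_cases": n_cases, "n_controls": n_controls,
            "log_or": log_or if fit.converged else math.nan,
            "se": se if fit.converged else math.nan,
            "odds_ratio": math.exp(log_or) if fit.converged else math.nan,
            "ci_low": math.exp(log_or - 1.96 * se) if fit.converged else math.nan,
            "ci_high": math.exp(log_or + 1.96 * se) if fit.converged else math.nan,
            "pvalue": p if fit.converged else math.nan,
            "converged": fit.converged,
        })
    if not rows:
        return pd.DataFrame(columns=[
            "phecode", "n_cases", "n_controls", "log_or", "se", "odds_ratio",
            "ci_low", "ci_high", "pvalue", "q_value", "significant", "converged",
        ])
    table = pd.DataFrame(rows)
    table["q_value"] = math.nan
    ok = table["converged"].to_numpy()
    if ok.any():
        qvals = multipletests(table.loc[ok, "pvalue"].to_numpy(), method="fdr_bh")[1]
        table.loc[ok, "q_value"] = qvals
    table["significant"] = (table["q_value"] < fdr).fillna(False)
    return table.sort_values(
        "pvalue", na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def _linear_fit(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """OLS (log of convenience): (estimate, SE, p) for design column 1."""
    xtx = x.T @ x
    try:
        factor = cho_factor(xtx)
    except LinAlgError:
        raise AnalysisError("design matrix is rank deficient") from None
    coef = cho_solve(factor, x.T @ y)
    resid = y - x @ coef
    dof = len(y) - x.shape[1]
    if dof <= 0:
        raise AnalysisError("not enough observations for a linear fit")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * cho_solve(factor, np.eye(x.shape[1]))
    est = float(coef[1])
    se = float(math.sqrt(max(cov[1, 1], 0.0)))
    p = float(2.0 * norm.sf(abs(est) / se)) if se > 0 else math.nan
    return est, se, p


def run_stratified_grs(
    cohort: CohortBundle,
    weights: GRSWeights,
    outcome: str = "outcome",
    outcome_type: str = "binary",
    stratum_flag: np.ndarray | None = None,
    stratum_names: tuple[str, str] = ("abstainer", "consumer"),
) -> pd.DataFrame:
    """Per-stratum GRS association (the consumption-stratified check).

    ``outcome`` names a cohort column ("outcome", "mediator",
    "exposure", or a phecode column). Binary outcomes use the same
    logistic model as the scan; continuous outcomes are standardized
    within the full analysis sample first, so estimates are per SD, and
    fit by ordinary least squares. The stratum flag defaults to the
    cohort's consumption indicator.
    """
    if stratum_flag is None:
        stratum_flag = cohort.consumer
    stratum_flag = np.asarray(stratum_flag, dtype=bool)
    if stratum_flag.shape[0] != cohort.n:
        raise AnalysisError("stratum flag length differs from cohort size")

    if outcome == "outcome":
        y = cohort.outcome.astype(float)
    elif outcome == "mediator":
        y = np.asarray(cohort.mediator, dtype=float)
    elif outcome == "exposure":
        y = np.asarray(cohort.exposure, dtype=float)
    elif outcome in cohort.phecodes.columns:
        y = cohort.phecodes[outcome].to_numpy(dtype=float)
    else:
        raise AnalysisError(f"unknown outcome column {outcome!r}")
    if outcome_type not in ("binary", "continuous"):
        raise AnalysisError(f"outcome_type must be binary or continuous")
    if outcome_type == "continuous":
        sd = float(np.std(y))
        if sd == 0:
            raise AnalysisError("continuous outcome has zero variance")
        y = (y - float(np.mean(y))) / sd

    grs = build_weighted_grs(cohort.genotypes, weights)
    design = _covariate_design(cohort, grs)

    rows = []
    for value, name in ((False, stratum_names[0]), (True, stratum_names[1])):
        mask = stratum_flag == value
        if not mask.any():
            raise AnalysisError(f"stratum {name!r} is empty")
        ys, ds = y[mask], design[mask]
        if outcome_type == "binary":
            fit = fit_logistic_glm(ys, ds)
            est, se, p = fit.term(1)
            conv = fit.converged
        else:
            est, se, p = _linear_fit(ys, ds)
            conv = True
        rows.append({
            "stratum": name, "n": int(mask.sum()),
            "estimate": est, "se": se,
            "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
            "pvalue": p, "converged": conv,
        })
    return pd.DataFrame(rows)
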