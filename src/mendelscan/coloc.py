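"""Bayesian colocalization of two traits over a genomic region.

Under a single-causal-variant-per-trait assumption, the evidence that
two traits share one causal variant in a region is summarised by
posterior probabilities of five hypotheses:

  H0  neither trait has a causal variant in the region
  H1  only trait 1 has one
  H2  only trait 2 has one
  H3  both do, at different variants
  H4  both do, at the same variant

Per-SNP evidence for association is the Wakefield approximate Bayes
factor computed from each SNP's beta and SE and a prior SD on the true
effect; hypothesis evidences are prior-weighted sums of ABF products
over causal configurations, accumulated in log space. LD never enters
the posterior computation — only marginal summary statistics do — which
is exactly what makes the single-causal-variant model tractable.

An exhaustive enumeration oracle (plain extended-precision arithmetic
over all causal configurations) is provided for small regions to verify
the log-space computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exceptions import AnalysisError

#: Default per-SNP prior probabilities (the conventional coloc defaults):
#: causal for trait 1 only, trait 2 only, or both.
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5

#: Default prior SD of a true causal effect, by trait type: per-SD units
#: for quantitative traits, log-OR for case-control.
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.2


def default_prior_sd(trait_type: str) -> float:
    if trait_type == "quantitative":
        return PRIOR_SD_QUANTITATIVE
    if trait_type == "case-control":
        return PRIOR_SD_CASE_CONTROL
    raise AnalysisError(f"unknown trait type {trait_type!r}")


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP causal priors and per-trait prior effect SDs."""

    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12
    prior_sd1: float = PRIOR_SD_QUANTITATIVE
    prior_sd2: float = PRIOR_SD_QUANTITATIVE

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2) < 1.0):
            raise AnalysisError("priors must satisfy 0 < p12 <= p1, p2 < 1")
        if self.prior_sd1 < 0 or self.prior_sd2 < 0:
            raise AnalysisError("prior effect SDs must be non-negative")

    def validate_region(self, n_snps: int) -> None:
        if n_snps * (self.p1 + self.p2 + self.p12) >= 1.0:
            raise AnalysisError(
                f"priors too large for region of {n_snps} SNPs: "
                "m*(p1+p2+p12) must be < 1"
            )

    @classmethod
    def for_trait_types(cls, type1: str, type2: str, **kwargs) -> "ColocPriors":
        return cls(
            prior_sd1=default_prior_sd(type1),
            prior_sd2=default_prior_sd(type2),
            **kwargs,
        )


@dataclass
class ColocResult:
    """Posterior probabilities PP0..PP4 with the evidence that produced them."""

    pp: np.ndarray  # shape (5,)
    log_abf1: np.ndarray
    log_abf2: np.ndarray
    priors: ColocPriors
    n_snps: int

    @property
    def pp0(self) -> float:
        return float(self.pp[0])

    @property
    def pp1(self) -> float:
        return float(self.pp[1])

    @property
    def pp2(self) -> float:
        return float(self.pp[2])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def modal_hypothesis(self) -> int:
        return int(np.argmax(self.pp))

    def to_dict(self) -> dict:
        return {
            "pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
            "pp3": self.pp3, "pp4": self.pp4, "n_snps": self.n_snps,
            "priors": {
                "p1": self.priors.p1, "p2": self.priors.p2, "p12": self.priors.p12,
                "prior_sd1": self.priors.prior_sd1, "prior_sd2": self.priors.prior_sd2,
            },
        }


def wakefield_log_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for association at one SNP.

    With V = se^2, W = prior_sd^2, r = W/(V+W) and z = beta/se:

        log ABF = 1/2 [ log(1 - r) + r z^2 ]

    oriented so positive values favour association (H1 over H0). A
    zero prior SD gives r = 0 and log ABF = 0: a point-null prior
    cannot distinguish the hypotheses. Accepts scalars or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise AnalysisError("standard errors must be positive")
    if prior_sd < 0:
        raise AnalysisError("prior_sd must be non-negative")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


def _log_evidences(l1: np.ndarray, l2: np.ndarray, priors: ColocPriors) -> np.ndarray:
    """Unnormalised log evidence for H0..H4 (shared constant dropped)."""
    m = len(l1)
    lp1, lp2, lp12 = math.log(priors.p1), math.log(priors.p2), math.log(priors.p12)
    sum1 = logsumexp(l1)
    sum2 = logsumexp(l2)
    both = logsumexp(l1 + l2)
    if m == 1:
        # a single-SNP region admits no distinct-variant configuration
        l_h3 = -np.inf
    else:
        # sum over j != k of exp(l1_j + l2_k), evaluated pairwise in log
        # space: exact for any dominance pattern, unlike the log-space
        # subtraction logdiff(sum1+sum2, both), which degenerates when a
        # single SNP carries essentially all evidence for both traits
        pairwise = l1[:, None] + l2[None, :]
        np.fill_diagonal(pairwise, -np.inf)
        l_h3 = float(logsumexp(pairwise))
    return np.array([
        0.0,
        lp1 + sum1,
        lp2 + sum2,
        lp1 + lp2 + l_h3,
        lp12 + both,
    ])


def coloc_posteriors(assoc_pair, priors: ColocPriors | None = None) -> ColocResult:
    """Posterior probabilities of H0..H4 for an aligned regional pair.

    ``assoc_pair`` is any object with attributes ``beta1``, ``se1``,
    ``beta2``, ``se2`` (aligned per-SNP arrays over the same SNPs, same
    effect alleles) and optionally ``trait_types`` used to pick default
    prior effect SDs.
    """
    beta1 = np.asarray(assoc_pair.beta1, dtype=float)
    se1 = np.asarray(assoc_pair.se1, dtype=float)
    beta2 = np.asarray(assoc_pair.beta2, dtype=float)
    se2 = np.asarray(assoc_pair.se2, dtype=float)
    if not (len(beta1) == len(se1) == len(beta2) == len(se2)):
        raise AnalysisError("trait 1 and trait 2 must cover identical SNP sets")
    m = len(beta1)
    if m < 1:
        raise AnalysisError("empty region")
    if priors is None:
        types = getattr(assoc_pair, "trait_types", ("quantitative", "quantitative"))
        priors = ColocPriors.for_trait_types(*types)
    priors.validate_region(m)
    l1 = wakefield_log_abf(beta1, se1, priors.prior_sd1)
    l2 = wakefield_log_abf(beta2, se2, priors.prior_sd2)
    log_ev = _log_evidences(np.atleast_1d(l1), np.atleast_1d(l2), priors)
    log_norm = logsumexp(log_ev)
    pp = np.exp(log_ev - log_norm)
    pp /= pp.sum()  # clean residual rounding so sum(pp) == 1 within 1e-12
    return ColocResult(
        pp=pp,
        log_abf1=np.atleast_1d(l1),
        log_abf2=np.atleast_1d(l2),
        priors=priors,
        n_snps=m,
    )


ENUMERATION_MAX_SNPS = 20


def coloc_enumeration_oracle(assoc_pair, priors: ColocPriors | None = None) -> np.ndarray:
    """Exhaustive-configuration posteriors for small regions.

    Loops explicitly over every single-SNP causal configuration for each
    trait in plain (non-log) extended-precision arithmetic:

        S0 = 1
        S1 = sum_j p1 ABF1_j
        S2 = sum_k p2 ABF2_k
        S3 = sum_{j != k} p1 p2 ABF1_j ABF2_k
        S4 = sum_j p12 ABF1_j ABF2_j

    and normalises. Independent of the log-space path; used to verify it.
    """
    beta1 = np.asarray(assoc_pair.beta1, dtype=float)
    se1 = np.asarray(assoc_pair.se1, dtype=float)
    beta2 = np.asarray(assoc_pair.beta2, dtype=float)
    se2 = np.asarray(assoc_pair.se2, dtype=float)
    m = len(beta1)
    if m > ENUMERATION_MAX_SNPS:
        raise AnalysisError(
            f"enumeration oracle limited to {ENUMERATION_MAX_SNPS} SNPs (got {m})"
        )
    if priors is None:
        types = getattr(assoc_pair, "trait_types", ("quantitative", "quantitative"))
        priors = ColocPriors.for_trait_types(*types)
    priors.validate_region(m)
    # 80-bit longdouble keeps exp() finite for |log ABF| up to ~1.1e4
    abf1 = np.exp(
        np.asarray(wakefield_log_abf(beta1, se1, priors.prior_sd1), dtype=np.longdouble)
    )
    abf2 = np.exp(
        np.asarray(wakefield_log_abf(beta2, se2, priors.prior_sd2), dtype=np.longdouble)
    )
    p1 = np.longdouble(priors.p1)
    p2 = np.longdouble(priors.p2)
    p12 = np.longdouble(priors.p12)
    s0 = np.longdouble(1.0)
    s1 = np.longdouble(0.0)
    s2 = np.longdouble(0.0)
    s3 = np.longdouble(0.0)
    s4 = np.longdouble(0.0)
    for j in range(m):
        s1 += p1 * abf1[j]
        s2 += p2 * abf2[j]
        s4 += p12 * abf1[j] * abf2[j]
        for k in range(m):
            if j != k:
                s3 += p1 * p2 * abf1[j] * abf2[k]
    evid = np.array([s0, s1, s2, s3, s4], dtype=np.longdouble)
    pp = evid / evid.sum()
    return pp.astype(float)
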