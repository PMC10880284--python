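"""Synthetic cohorts, omics panels, and regional association pairs.

The generator emulates the statistical structure of the data a
genetically-proxied caffeine analysis consumes, with fully known ground
truth:

* an individual-level cohort: two instrument variants drawn under
  Hardy-Weinberg, a standardized exposure they explain ~0.76% and
  ~0.56% of, a standardized mediator (BMI-like) downstream of the
  exposure, binary phecode outcomes from logistic models with
  configured log-ORs, covariates, and a consumption flag that gates the
  genotype->exposure path (the truth behind stratified pleiotropy
  checks);

* summary-statistic panels: a sparse-signal omics panel (protein- or
  metabolite-scale) where each trait's per-instrument outcome beta is
  theta_t times the instrument's exposure effect plus sampling noise;

* a mediation chain at the summary level (exposure -> mediator ->
  outcome) with independent mediator instruments and an LD matrix for
  clumping;

* LD-structured regional z-score pairs under the five colocalization
  scenarios H0..H4, with AR-1 LD.

Every simulated object carries its generating parameters in a truth
ledger so downstream tests can score recovery. A single integer seed
determines everything; independent sub-streams are derived from it per
product, so identical (seed, config) pairs give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import norm

from .exceptions import ConfigError
from .io_formats import SummaryStatRecord, SummaryStatsTable

# fixed spawn keys for the per-product random sub-streams
_STREAMS = {
    "cohort": 0,
    "panel": 1,
    "region": 2,
    "chain": 3,
    "exposure_gwas": 4,
    "bidirectional": 5,
}

_NONPALINDROMIC = (("A", "G"), ("G", "A"), ("T", "C"), ("C", "T"))


@dataclass(frozen=True)
class SimConfig:
    """Generative configuration; defaults mirror the study design.

    ``instrument_beta`` is derived from ``instrument_r2`` (per-allele
    effect on the standardized exposure such that 2 f (1-f) beta^2
    equals the target variance explained) unless given explicitly.

    ``theta_outcome`` is the direct log-OR of the binary outcome per SD
    exposure conditional on the mediator; the total effect is
    theta_outcome + gamma_mediator * delta_mediator_outcome. Defaults
    give a total of -0.105 (OR approximately 0.90 per SD) with one third
    mediated.
    """

    seed: int = 0
    # --- cohort ---
    n_individuals: int = 10_000
    instrument_ids: tuple[str, ...] = ("rs2472297", "rs4410790")
    instrument_chrom: tuple[str, ...] = ("15", "7")
    instrument_pos: tuple[int, ...] = (75_027_880, 17_284_577)
    instrument_effect_allele: tuple[str, ...] = ("T", "C")
    instrument_other_allele: tuple[str, ...] = ("C", "T")
    instrument_eaf: tuple[float, ...] = (0.27, 0.37)
    instrument_r2: tuple[float, ...] = (0.0076, 0.0056)
    instrument_beta: tuple[float, ...] | None = None
    exposure_n: int = 10_000  # exposure-GWAS sample size for summary SEs
    theta_outcome: float = -0.07
    gamma_mediator: float = -0.2
    delta_mediator_outcome: float = 0.175
    outcome_prevalence: float = 0.10
    n_phecodes: int = 100
    n_null_phecodes: int = 90
    phecode_log_or: float = 0.05
    phecode_prevalence_range: tuple[float, float] = (0.005, 0.15)
    consumer_fraction: float = 0.8
    abstainer_attenuation: float = 0.0
    # --- omics panel ---
    panel_size: int = 249
    panel_signal_fraction: float = 0.05
    panel_theta_range: tuple[float, float] = (0.2, 0.4)
    panel_theta_fixed: float | None = None
    panel_n: int = 35_000
    panel_trait_type: str = "quantitative"
    panel_case_fraction: float = 0.25
    # --- mediation chain ---
    n_mediator_snps: int = 50
    n_mediator_null_snps: int = 10
    mediator_n: int = 806_834
    mediator_beta_range: tuple[float, float] = (0.015, 0.05)
    mediator_ld_tag_r: float = 0.8
    outcome_n: int = 800_000
    outcome_case_fraction: float = 0.21
    # --- regional pair ---
    region_n_snps: int = 200
    region_ld_decay: float = 0.9
    region_causal_z: float = 8.0
    region_n1: int = 10_000
    region_n2: int = 100_000
    trait_types: tuple[str, str] = ("quantitative", "quantitative")
    region_h3_max_r2: float = 0.2

    def __post_init__(self) -> None:
        counts = {
            "n_individuals": self.n_individuals, "n_phecodes": self.n_phecodes,
            "panel_size": self.panel_size, "region_n_snps": self.region_n_snps,
            "exposure_n": self.exposure_n, "panel_n": self.panel_n,
            "mediator_n": self.mediator_n, "outcome_n": self.outcome_n,
            "n_mediator_snps": self.n_mediator_snps,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive (got {v})")
        if self.n_null_phecodes < 0 or self.n_null_phecodes > self.n_phecodes:
            raise ConfigError("n_null_phecodes must be in [0, n_phecodes]")
        for f in self.instrument_eaf:
            if not 0.0 < f < 1.0:
                raise ConfigError(f"instrument_eaf must be in (0,1) (got {f})")
        for frac_name in ("panel_signal_fraction", "consumer_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{frac_name} must be in [0,1] (got {v})")
        if not 0.0 <= self.region_ld_decay < 1.0:
            raise ConfigError("region_ld_decay must be in [0,1)")
        if not 0.0 < self.outcome_prevalence < 1.0:
            raise ConfigError("outcome_prevalence must be in (0,1)")
        lengths = {
            len(self.instrument_ids), len(self.instrument_eaf),
            len(self.instrument_r2), len(self.instrument_effect_allele),
            len(self.instrument_other_allele),
        }
        if len(lengths) != 1:
            raise ConfigError("instrument field lengths differ")

    # -- derived quantities -------------------------------------------------

    @property
    def betas(self) -> np.ndarray:
        """Per-allele instrument effects on the standardized exposure."""
        if self.instrument_beta is not None:
            return np.asarray(self.instrument_beta, dtype=float)
        f = np.asarray(self.instrument_eaf)
        r2 = np.asarray(self.instrument_r2)
        return np.sqrt(r2 / (2.0 * f * (1.0 - f)))

    @property
    def genetic_variance(self) -> float:
        """Exposure variance explained by all instruments together."""
        f = np.asarray(self.instrument_eaf)
        return float(np.sum(2.0 * f * (1.0 - f) * self.betas**2))

    @property
    def total_effect(self) -> float:
        """Total log-OR of the outcome per SD exposure (direct + mediated)."""
        return self.theta_outcome + self.gamma_mediator * self.delta_mediator_outcome

    @property
    def proportion_mediated_truth(self) -> float:
        return self.gamma_mediator * self.delta_mediator_outcome / self.total_effect

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-product sub-stream of the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    # -- (de)serialisation --------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        out = {}
        for name in self.__dataclass_fields__:  # type: ignore[attr-defined]
            v = getattr(self, name)
            out[name] = list(v) if isinstance(v, tuple) else v
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# individual-level cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Individual-level tables plus the truth that generated them."""

    genotypes: pd.DataFrame  # dosages in {0,1,2}, one column per instrument
    covariates: pd.DataFrame  # age, sex, pc1..pc10
    exposure: np.ndarray  # standardized plasma-caffeine-like trait
    mediator: np.ndarray  # standardized BMI-like trait
    outcome: np.ndarray  # binary osteoarthritis-like outcome
    phecodes: pd.DataFrame  # binary case table, columns phecode_*
    consumer: np.ndarray  # self-reported consumption flag
    config: SimConfig
    truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.exposure)

    def to_frame(self) -> pd.DataFrame:
        """One row per individual, in the cohort-table TSV schema."""
        df = pd.concat(
            [
                self.genotypes.reset_index(drop=True),
                self.covariates.reset_index(drop=True),
            ],
            axis=1,
        )
        df["consumer"] = self.consumer.astype(int)
        df["exposure"] = self.exposure
        df["mediator"] = self.mediator
        df["outcome"] = self.outcome.astype(int)
        return pd.concat([df, self.phecodes.reset_index(drop=True)], axis=1)


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Draw an individual-level cohort under the configured model.

    Dosages are Hardy-Weinberg (binomial(2, f)); the exposure is the
    centred weighted dosage sum plus Gaussian noise, scaled to unit
    variance; the mediator is gamma * exposure plus noise (unit
    variance); each binary outcome is a logistic draw with its
    configured log-OR. Among non-consumers the genotype->exposure path
    is multiplied by ``abstainer_attenuation`` (default 0: disabled).
    """
    rng = config.rng("cohort")
    n = config.n_individuals
    f = np.asarray(config.instrument_eaf)
    betas = config.betas

    dosages = rng.binomial(2, f, size=(n, len(f))).astype(np.int8)
    genetic = (dosages - 2.0 * f) @ betas
    g_var = config.genetic_variance
    if g_var >= 1.0:
        raise ConfigError("instrument effects explain >= 100% of exposure variance")

    consumer = rng.random(n) < config.consumer_fraction
    path_scale = np.where(consumer, 1.0, config.abstainer_attenuation)
    exposure = path_scale * genetic + rng.normal(0.0, math.sqrt(1.0 - g_var), n)

    gm = config.gamma_mediator
    if abs(gm) >= 1.0:
        raise ConfigError("abs(gamma_mediator) must be < 1 for a unit-variance mediator")
    mediator = gm * exposure + rng.normal(0.0, math.sqrt(1.0 - gm**2), n)

    covariates = pd.DataFrame({
        "age": np.round(rng.normal(57.0, 8.0, n), 1),
        "sex": rng.binomial(1, 0.54, n).astype(np.int8),
    })
    for k in range(10):
        covariates[f"pc{k + 1}"] = rng.normal(0.0, 1.0, n)

    lin = logit(config.outcome_prevalence) + config.theta_outcome * exposure \
        + config.delta_mediator_outcome * mediator
    outcome = (rng.random(n) < expit(lin)).astype(np.int8)

    n_signal = config.n_phecodes - config.n_null_phecodes
    lo, hi = config.phecode_prevalence_range
    prevalence = np.exp(rng.uniform(math.log(lo), math.log(hi), config.n_phecodes))
    signs = rng.choice([-1.0, 1.0], size=config.n_phecodes)
    log_or = np.where(
        np.arange(config.n_phecodes) < n_signal, signs * config.phecode_log_or, 0.0
    )
    phe = np.empty((n, config.n_phecodes), dtype=np.int8)
    for k in range(config.n_phecodes):
        if log_or[k] == 0.0:
            p = prevalence[k]
            phe[:, k] = rng.random(n) < p
        else:
            p = expit(logit(prevalence[k]) + log_or[k] * exposure)
            phe[:, k] = rng.random(n) < p
    phe_cols = [f"phecode_{k + 1:04d}" for k in range(config.n_phecodes)]
    phecodes = pd.DataFrame(phe, columns=phe_cols)

    truth = {
        "instrument_beta": betas.tolist(),
        "variance_explained": [
            2.0 * fi * (1.0 - fi) * bi**2 for fi, bi in zip(f, betas)
        ],
        "genetic_variance": g_var,
        "grs_sd": math.sqrt(g_var),
        "theta_outcome_direct": config.theta_outcome,
        "total_effect": config.total_effect,
        "proportion_mediated": config.proportion_mediated_truth,
        "gamma_mediator": config.gamma_mediator,
        "delta_mediator_outcome": config.delta_mediator_outcome,
        # effect of +1 SD of the (true-weight) GRS on each trait, by stratum
        "grs_effect_exposure_consumers": math.sqrt(g_var),
        "grs_effect_exposure_abstainers": config.abstainer_attenuation * math.sqrt(g_var),
        "grs_effect_mediator_consumers": gm * math.sqrt(g_var),
        "grs_effect_mediator_abstainers": config.abstainer_attenuation * gm * math.sqrt(g_var),
        "phecode_log_or": dict(zip(phe_cols, log_or.tolist())),
        "phecode_prevalence": dict(zip(phe_cols, prevalence.tolist())),
    }
    return CohortBundle(
        genotypes=pd.DataFrame(dosages, columns=list(config.instrument_ids)),
        covariates=covariates,
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        phecodes=phecodes,
        consumer=consumer,
        config=config,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# summary-statistic building blocks
# ---------------------------------------------------------------------------

def _record(
    vid: str, chrom: str, pos: int, ea: str, oa: str, eaf: float,
    beta: float, se: float, n: float,
) -> SummaryStatRecord:
    z = beta / se
    return SummaryStatRecord(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se,
        pvalue=max(float(2.0 * norm.sf(abs(z))), 5e-324), n=n,
    )


def _instrument_se(config: SimConfig) -> np.ndarray:
    """Sampling SE of per-allele effects on the standardized exposure."""
    f = np.asarray(config.instrument_eaf)
    return 1.0 / np.sqrt(config.exposure_n * 2.0 * f * (1.0 - f))


def instrument_exposure_table(
    config: SimConfig, estimated: bool = True
) -> SummaryStatsTable:
    """The instruments' associations with the exposure, as a GWAS would report.

    With ``estimated=True`` betas carry sampling noise at the
    exposure-GWAS sample size; otherwise the generative values are
    returned exactly.
    """
    rng = config.rng("exposure_gwas")
    ses = _instrument_se(config)
    betas = config.betas + (rng.normal(0.0, ses) if estimated else 0.0)
    records = [
        _record(
            config.instrument_ids[j], config.instrument_chrom[j],
            config.instrument_pos[j], config.instrument_effect_allele[j],
            config.instrument_other_allele[j], config.instrument_eaf[j],
            float(betas[j]), float(ses[j]), config.exposure_n,
        )
        for j in range(len(config.instrument_ids))
    ]
    return SummaryStatsTable(
        trait_id="plasma_caffeine", records=records, trait_type="quantitative",
    )


@dataclass
class OmicsPanel:
    """Exposure table plus one outcome table per panel trait, with truth."""

    exposure: SummaryStatsTable
    outcomes: list[SummaryStatsTable]
    theta: np.ndarray  # true causal effect per SD exposure, per trait
    config: SimConfig


def simulate_omics_panel(config: SimConfig) -> OmicsPanel:
    """Sparse-signal omics panel of instrument-level summary statistics.

    For each trait t the per-instrument outcome beta is
    theta_t * beta_exposure,j + N(0, SE_j^2); a ``panel_signal_fraction``
    of traits get theta_t != 0, drawn uniformly in magnitude from
    ``panel_theta_range`` with random sign (or fixed to
    ``panel_theta_fixed`` when set).
    """
    rng = config.rng("panel")
    m = config.panel_size
    n_signal = int(round(config.panel_signal_fraction * m))
    theta = np.zeros(m)
    if n_signal:
        idx = rng.choice(m, size=n_signal, replace=False)
        if config.panel_theta_fixed is not None:
            theta[idx] = config.panel_theta_fixed
        else:
            lo, hi = config.panel_theta_range
            theta[idx] = rng.choice([-1.0, 1.0], n_signal) * rng.uniform(lo, hi, n_signal)

    f = np.asarray(config.instrument_eaf)
    if config.panel_trait_type == "quantitative":
        ses = 1.0 / np.sqrt(config.panel_n * 2.0 * f * (1.0 - f))
    elif config.panel_trait_type == "case-control":
        phi = config.panel_case_fraction
        ses = 1.0 / np.sqrt(config.panel_n * phi * (1.0 - phi) * 2.0 * f * (1.0 - f))
    else:
        raise ConfigError(f"unknown panel_trait_type {config.panel_trait_type!r}")

    betas_true = config.betas
    outcomes = []
    for t in range(m):
        b_out = theta[t] * betas_true + rng.normal(0.0, ses)
        records = [
            _record(
                config.instrument_ids[j], config.instrument_chrom[j],
                config.instrument_pos[j], config.instrument_effect_allele[j],
                config.instrument_other_allele[j], config.instrument_eaf[j],
                float(b_out[j]), float(ses[j]), config.panel_n,
            )
            for j in range(len(betas_true))
        ]
        outcomes.append(
            SummaryStatsTable(
                trait_id=f"trait_{t + 1:04d}", records=records,
                trait_type=config.panel_trait_type,
            )
        )
    return OmicsPanel(
        exposure=instrument_exposure_table(config),
        outcomes=outcomes,
        theta=theta,
        config=config,
    )


# ---------------------------------------------------------------------------
# mediation chain at the summary level
# ---------------------------------------------------------------------------

@dataclass
class MediationChain:
    """Summary tables for a two-step exposure -> mediator -> outcome design."""

    exposure: SummaryStatsTable  # exposure instruments vs exposure
    mediator: SummaryStatsTable  # everything vs mediator
    outcome: SummaryStatsTable  # everything vs outcome
    mediator_ld: pd.DataFrame
    exposure_instruments: list[str]
    config: SimConfig
    truth: dict = field(default_factory=dict)


def simulate_mediation_chain(config: SimConfig) -> MediationChain:
    """Generate the three summary-statistics tables of a mediation design.

    Mediator instruments are independent variants with effects drawn
    from ``mediator_beta_range`` (plus null variants below the
    significance threshold); consecutive significant variants are tagged
    pairs at LD r = ``mediator_ld_tag_r`` so clumping has work to do.
    The exposure instruments also appear in the mediator and outcome
    tables with their downstream effects (gamma * beta and
    total * beta).
    """
    rng = config.rng("chain")
    f_exp = np.asarray(config.instrument_eaf)
    betas = config.betas
    se_exp = _instrument_se(config)
    gamma = config.gamma_mediator
    delta = config.delta_mediator_outcome
    total = config.total_effect

    k_sig = config.n_mediator_snps
    k_null = config.n_mediator_null_snps
    k = k_sig + k_null
    f_med = rng.uniform(0.1, 0.9, k)
    lo, hi = config.mediator_beta_range
    u = np.zeros(k)
    u[:k_sig] = rng.choice([-1.0, 1.0], k_sig) * rng.uniform(lo, hi, k_sig)
    # tag every second significant variant to its predecessor at r
    r_tag = config.mediator_ld_tag_r
    tagged = np.arange(1, k_sig, 2)
    u[tagged] = r_tag * u[tagged - 1]

    se_med_snps = 1.0 / np.sqrt(config.mediator_n * 2.0 * f_med * (1.0 - f_med))
    se_med_instr = 1.0 / np.sqrt(config.mediator_n * 2.0 * f_exp * (1.0 - f_exp))
    phi = config.outcome_case_fraction
    se_out_snps = 1.0 / np.sqrt(
        config.outcome_n * phi * (1.0 - phi) * 2.0 * f_med * (1.0 - f_med)
    )
    se_out_instr = 1.0 / np.sqrt(
        config.outcome_n * phi * (1.0 - phi) * 2.0 * f_exp * (1.0 - f_exp)
    )

    med_ids = [f"bmi_snp_{i + 1:03d}" for i in range(k)]
    instr_ids = list(config.instrument_ids)

    def snp_records(trait_betas_instr, ses_instr, trait_betas_snps, ses_snps, n):
        recs = []
        for j, vid in enumerate(instr_ids):
            recs.append(_record(
                vid, config.instrument_chrom[j], config.instrument_pos[j],
                config.instrument_effect_allele[j], config.instrument_other_allele[j],
                float(f_exp[j]), float(trait_betas_instr[j]), float(ses_instr[j]), n,
            ))
        for i, vid in enumerate(med_ids):
            recs.append(_record(
                vid, "2", 1_000_000 + 10_000 * i, "A", "G",
                float(f_med[i]), float(trait_betas_snps[i]), float(ses_snps[i]), n,
            ))
        return recs

    # estimated betas: generative value + sampling noise at each GWAS's n
    exp_table = instrument_exposure_table(config)
    med_instr_b = gamma * betas + rng.normal(0.0, se_med_instr)
    med_snps_b = u + rng.normal(0.0, se_med_snps)
    out_instr_b = total * betas + rng.normal(0.0, se_out_instr)
    out_snps_b = delta * u + rng.normal(0.0, se_out_snps)

    mediator = SummaryStatsTable(
        trait_id="bmi",
        records=snp_records(med_instr_b, se_med_instr, med_snps_b, se_med_snps,
                            config.mediator_n),
        trait_type="quantitative",
    )
    outcome = SummaryStatsTable(
        trait_id="osteoarthritis",
        records=snp_records(out_instr_b, se_out_instr, out_snps_b, se_out_snps,
                            config.outcome_n),
        trait_type="case-control",
    )

    all_ids = instr_ids + med_ids
    ld = np.eye(len(all_ids))
    offset = len(instr_ids)
    for i in tagged:
        a, b = offset + i - 1, offset + i
        ld[a, b] = ld[b, a] = r_tag
    mediator_ld = pd.DataFrame(ld, index=all_ids, columns=all_ids)

    truth = {
        "a_exposure_to_mediator": gamma,
        "b_mediator_to_outcome": delta,
        "total_effect": total,
        "indirect_effect": gamma * delta,
        "proportion_mediated": config.proportion_mediated_truth,
        "mediator_snp_effects": dict(zip(med_ids, u.tolist())),
    }
    return MediationChain(
        exposure=exp_table, mediator=mediator, outcome=outcome,
        mediator_ld=mediator_ld, exposure_instruments=instr_ids,
        config=config, truth=truth,
    )


# ---------------------------------------------------------------------------
# LD-structured regional association pairs
# ---------------------------------------------------------------------------

SCENARIOS = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class RegionalAssocPair:
    """Aligned regional summary statistics for two traits, with truth."""

    snp_ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    ld: np.ndarray  # correlation matrix, unit diagonal, PSD
    scenario: str
    causal1: int | None
    causal2: int | None
    trait_types: tuple[str, str]
    n1: int
    n2: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def ar1_ld_matrix(m: int, decay: float) -> np.ndarray:
    """AR-1 correlation: r_ij = decay^|i-j|; PSD by construction for |decay|<1."""
    idx = np.arange(m)
    return decay ** np.abs(idx[:, None] - idx[None, :])


def simulate_region_pair(config: SimConfig, scenario: str) -> RegionalAssocPair:
    """Joint regional z-scores for two traits under one coloc scenario.

    z ~ MVN(LD[:, c] * z_causal, LD) per trait: the causal SNP's
    non-centrality is spread over its LD neighbours, the noise is
    LD-correlated. Betas are recovered as z * SE with SEs from each
    trait's sample size. Under H4 the causal indices coincide; under H3
    they are distinct and constrained to r^2 < ``region_h3_max_r2``
    (unconstrained draws under strong AR-1 LD would place them in
    near-perfect LD, which is H4 in all but name).
    """
    if scenario not in SCENARIOS:
        raise ConfigError(f"scenario must be one of {SCENARIOS} (got {scenario!r})")
    m = config.region_n_snps
    if m < 2:
        raise ConfigError("region_n_snps must be >= 2")
    rng = config.rng("region")
    ld = ar1_ld_matrix(m, config.region_ld_decay)
    try:
        chol = np.linalg.cholesky(ld + 1e-12 * np.eye(m))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - AR-1 is PSD
        raise ConfigError("LD matrix is not positive semi-definite") from exc

    causal1: int | None = None
    causal2: int | None = None
    if scenario in ("H1", "H3", "H4"):
        causal1 = int(rng.integers(m))
    if scenario == "H2":
        causal2 = int(rng.integers(m))
    elif scenario == "H4":
        causal2 = causal1
    elif scenario == "H3":
        for _ in range(1000):
            c2 = int(rng.integers(m))
            assert causal1 is not None
            if ld[causal1, c2] ** 2 < config.region_h3_max_r2:
                causal2 = c2
                break
        else:
            raise ConfigError(
                "could not place distinct causal variants below the H3 LD cap; "
                "region too small or LD too strong"
            )

    def draw_z(causal: int | None) -> np.ndarray:
        mean = np.zeros(m)
        if causal is not None:
            sign = rng.choice([-1.0, 1.0])
            mean = ld[:, causal] * sign * config.region_causal_z
        return mean + chol @ rng.standard_normal(m)

    z1 = draw_z(causal1)
    z2 = draw_z(causal2)

    def ses(trait_type: str, n: int) -> np.ndarray:
        if trait_type == "quantitative":
            return np.full(m, 1.0 / math.sqrt(n))
        if trait_type == "case-control":
            phi = config.outcome_case_fraction
            return np.full(m, 1.0 / math.sqrt(n * phi * (1.0 - phi)))
        raise ConfigError(f"unknown trait type {trait_type!r}")

    se1 = ses(config.trait_types[0], config.region_n1)
    se2 = ses(config.trait_types[1], config.region_n2)
    return RegionalAssocPair(
        snp_ids=[f"region_snp_{i + 1:04d}" for i in range(m)],
        beta1=z1 * se1, se1=se1, beta2=z2 * se2, se2=se2,
        ld=ld, scenario=scenario, causal1=causal1, causal2=causal2,
        trait_types=config.trait_types, n1=config.region_n1, n2=config.region_n2,
    )


# ---------------------------------------------------------------------------
# bidirectional design at the summary level
# ---------------------------------------------------------------------------

@dataclass
class BidirectionalTables:
    """Two traits' associations over both instrument sets, with truth.

    Generated under a one-way causal model: trait A affects trait B with
    effect ``gamma_mediator`` (per SD), and nothing flows back. Trait
    B's instruments therefore carry pure sampling noise against trait A
    — the truth behind a reverse-direction null.
    """

    trait_a: SummaryStatsTable
    trait_b: SummaryStatsTable
    instruments_a: list[str]
    instruments_b: list[str]
    config: SimConfig
    truth: dict = field(default_factory=dict)


def simulate_bidirectional_tables(config: SimConfig) -> BidirectionalTables:
    """Summary statistics for a bidirectional MR design (A -> B only)."""
    rng = config.rng("bidirectional")
    f_a = np.asarray(config.instrument_eaf)
    betas_a = config.betas
    se_a_on_a = _instrument_se(config)
    effect = config.gamma_mediator  # A -> B, per SD

    k = config.n_mediator_snps
    f_b = rng.uniform(0.1, 0.9, k)
    lo, hi = config.mediator_beta_range
    u_b = rng.choice([-1.0, 1.0], k) * rng.uniform(lo, hi, k)
    se_b_on_b = 1.0 / np.sqrt(config.mediator_n * 2.0 * f_b * (1.0 - f_b))
    se_b_on_a = 1.0 / np.sqrt(config.exposure_n * 2.0 * f_b * (1.0 - f_b))
    se_a_on_b = 1.0 / np.sqrt(config.mediator_n * 2.0 * f_a * (1.0 - f_a))

    ids_a = list(config.instrument_ids)
    ids_b = [f"coffee_snp_{i + 1:03d}" for i in range(k)]

    def table(trait_id, b_instr_a, se_instr_a, b_instr_b, se_instr_b, n):
        recs = []
        for j, vid in enumerate(ids_a):
            recs.append(_record(
                vid, config.instrument_chrom[j], config.instrument_pos[j],
                config.instrument_effect_allele[j], config.instrument_other_allele[j],
                float(f_a[j]), float(b_instr_a[j]), float(se_instr_a[j]), n,
            ))
        for i, vid in enumerate(ids_b):
            recs.append(_record(
                vid, "11", 2_000_000 + 10_000 * i, "T", "C",
                float(f_b[i]), float(b_instr_b[i]), float(se_instr_b[i]), n,
            ))
        return SummaryStatsTable(trait_id=trait_id, records=recs,
                                 trait_type="quantitative")

    trait_a = table(
        "plasma_caffeine",
        betas_a + rng.normal(0.0, se_a_on_a),
        se_a_on_a,
        rng.normal(0.0, se_b_on_a),  # B's instruments do not affect A
        se_b_on_a,
        config.exposure_n,
    )
    trait_b = table(
        "coffee_intake",
        effect * betas_a + rng.normal(0.0, se_a_on_b),
        se_a_on_b,
        u_b + rng.normal(0.0, se_b_on_b),
        se_b_on_b,
        config.mediator_n,
    )
    return BidirectionalTables(
        trait_a=trait_a, trait_b=trait_b,
        instruments_a=ids_a, instruments_b=ids_b,
        config=config,
        truth={"forward_effect": effect, "reverse_effect": 0.0},
    )


# ---------------------------------------------------------------------------
# cohort-table round trip
# ---------------------------------------------------------------------------

_COHORT_RESERVED = {"age", "sex", "consumer", "exposure", "mediator", "outcome"} | {
    f"pc{k + 1}" for k in range(10)
}


def cohort_from_frame(df: pd.DataFrame, config: SimConfig | None = None) -> CohortBundle:
    """Rebuild a CohortBundle from its one-row-per-individual TSV schema.

    Genotype columns are every non-reserved, non-``phecode_`` column;
    the truth ledger of a table read from disk is empty.
    """
    phe_cols = [c for c in df.columns if c.startswith("phecode_")]
    geno_cols = [c for c in df.columns if c not in _COHORT_RESERVED
                 and not c.startswith("phecode_")]
    missing = _COHORT_RESERVED - set(df.columns)
    if missing:
        raise ConfigError(f"cohort table missing columns: {sorted(missing)}")
    covariates = df[["age", "sex"] + [f"pc{k + 1}" for k in range(10)]].copy()
    return CohortBundle(
        genotypes=df[geno_cols].copy(),
        covariates=covariates,
        exposure=df["exposure"].to_numpy(dtype=float),
        mediator=df["mediator"].to_numpy(dtype=float),
        outcome=df["outcome"].to_numpy(dtype=np.int8),
        phecodes=df[phe_cols].astype(np.int8),
        consumer=df["consumer"].to_numpy(dtype=bool),
        config=config or SimConfig(),
        truth={},
    )
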