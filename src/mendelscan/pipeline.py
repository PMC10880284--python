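"""End-to-end orchestration of the analysis stages.

A single YAML config drives simulation and every downstream stage:
cohort PheWAS, panel-wide MR scan, network-MR mediation, stratified
pleiotropy check, bidirectional MR, and colocalization at two loci.
Outputs are one TSV per tabular stage plus a JSON summary; everything
is deterministic given the seed, and output files carry no wall-clock
information, so a rerun at the same seed is byte-identical. Per-stage
timing goes to the stderr log instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import synthetic
from .exceptions import AnalysisError, ConfigError
from .mediation import run_network_mediation
from .mr import bidirectional_mr, mr_scan_panel
from .phewas import GRSWeights, run_phewas, run_stratified_grs

logger = logging.getLogger(__name__)

ALL_STAGES = ("phewas", "stratified", "mr_scan", "mediation", "bidirectional", "coloc")

_version = "0.1.0"


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run; CLI flags override keys."""

    seed: int = 0
    outdir: str = "mendelscan_run"
    stages: tuple[str, ...] = ALL_STAGES
    #: overrides applied on top of the SimConfig defaults
    sim: dict = field(default_factory=dict)
    min_cases: int = 200
    fdr: float = 0.05
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    coloc_p1: float = coloc_mod.DEFAULT_P1
    coloc_p2: float = coloc_mod.DEFAULT_P2
    coloc_p12: float = coloc_mod.DEFAULT_P12
    coloc_loci: tuple[str, ...] = ("CYP1A2", "AHR")
    coloc_scenario: str = "H4"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if not 0.0 < self.fdr < 1.0:
            raise ConfigError("fdr must be in (0,1)")
        if self.min_cases < 1:
            raise ConfigError("min_cases must be >= 1")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ConfigError("p_threshold must be in (0,1]")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ConfigError("r2_threshold must be in (0,1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "coloc_loci"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def sim_config(self) -> synthetic.SimConfig:
        return synthetic.SimConfig(seed=self.seed, **self.sim)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # a location, not a scientific input
        return json.dumps(d, sort_keys=True, default=list)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


@dataclass
class RunReport:
    """Per-stage results plus provenance; every number traces to a stage file."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def demo_config(seed: int = 0, outdir: str = "mendelscan_demo") -> RunConfig:
    """The all-stages demonstration run at desk scale."""
    return RunConfig(
        seed=seed,
        outdir=outdir,
        sim={
            "n_individuals": 20_000,
            "n_phecodes": 500,
            "n_null_phecodes": 490,
            "panel_size": 249,
            "region_n_snps": 200,
        },
    )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise AnalysisError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Inputs are generated by the synthetic module from the run's seed;
    a stage failure halts the run with a stage-labeled error.
    """
    sim = config.sim_config()
    report = RunReport()
    report.provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": _version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stages": list(config.stages),
    }
    needs_cohort = {"phewas", "stratified"} & set(config.stages)
    cohort = weights = None
    if needs_cohort:
        cohort = synthetic.simulate_cohort(sim)
        weights = GRSWeights.from_summary_stats(
            synthetic.instrument_exposure_table(sim)
        )

    if "phewas" in config.stages:
        report.tables["phewas"] = _stage("phewas")(run_phewas)(
            cohort, weights, min_cases=config.min_cases, fdr=config.fdr
        )
        n_nonconv = int((~report.tables["phewas"]["converged"]).sum()) \
            if len(report.tables["phewas"]) else 0
        if n_nonconv:
            report.warnings.append(f"phewas: {n_nonconv} non-converged fits excluded")
        report.summaries["phewas"] = {
            "n_tested": int(report.tables["phewas"]["converged"].sum())
            if len(report.tables["phewas"]) else 0,
            "n_significant": int(report.tables["phewas"]["significant"].sum())
            if len(report.tables["phewas"]) else 0,
        }

    if "stratified" in config.stages:
        def strat():
            parts = []
            for outcome, typ in (("outcome", "binary"), ("mediator", "continuous")):
                t = run_stratified_grs(cohort, weights, outcome=outcome,
                                       outcome_type=typ)
                t.insert(0, "outcome", outcome)
                parts.append(t)
            return pd.concat(parts, ignore_index=True)
        report.tables["stratified"] = _stage("stratified")(strat)()

    if "mr_scan" in config.stages:
        def scan():
            panel = synthetic.simulate_omics_panel(sim)
            return mr_scan_panel(panel.exposure, panel.outcomes, fdr=config.fdr)
        result = _stage("mr_scan")(scan)()
        report.tables["mr_scan"] = result.table
        if result.failures:
            report.warnings.append(
                f"mr_scan: {len(result.failures)} traits failed harmonization"
            )
        report.summaries["mr_scan"] = {
            "n_traits": len(result.results),
            "n_significant": int(result.table["significant"].sum())
            if "significant" in result.table else 0,
        }

    if "mediation" in config.stages:
        def mediate():
            chain = synthetic.simulate_mediation_chain(sim)
            res = run_network_mediation(
                chain.exposure, chain.mediator, chain.outcome,
                chain.exposure_instruments,
                mediator_ld=chain.mediator_ld,
                p_threshold=config.p_threshold,
                r2_threshold=config.r2_threshold,
            )
            return res.to_dict()
        report.summaries["mediation"] = _stage("mediation")(mediate)()

    if "bidirectional" in config.stages:
        def bidir():
            tabs = synthetic.simulate_bidirectional_tables(sim)
            fwd, rev = bidirectional_mr(
                tabs.trait_a, tabs.trait_b, tabs.instruments_a, tabs.instruments_b
            )
            return {
                "forward": dataclasses.asdict(fwd),
                "reverse": dataclasses.asdict(rev),
            }
        report.summaries["bidirectional"] = _stage("bidirectional")(bidir)()

    if "coloc" in config.stages:
        def run_coloc():
            priors = coloc_mod.ColocPriors(
                p1=config.coloc_p1, p2=config.coloc_p2, p12=config.coloc_p12,
            )
            seeds = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(99,)
            ).generate_state(len(config.coloc_loci)) % (2**31)
            out = {}
            for locus, s in zip(config.coloc_loci, seeds):
                pair = synthetic.simulate_region_pair(
                    sim.with_seed(int(s)), config.coloc_scenario
                )
                out[locus] = coloc_mod.coloc_posteriors(pair, priors).to_dict()
                out[locus]["scenario"] = pair.scenario
            return out
        report.summaries["coloc"] = _stage("coloc")(run_coloc)()

    return report


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_report(report: RunReport, outdir) -> list[Path]:
    """One TSV per tabular stage plus ``summary.json``; stable ordering."""
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise AnalysisError(f"cannot create output directory {out}: {exc}") from exc
    written = []
    for name, table in sorted(report.tables.items()):
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")
        written.append(path)
    summary = {
        "provenance": report.provenance,
        "stage_summaries": report.summaries,
        "stage_files": [p.name for p in written],
        "warnings": report.warnings,
    }
    spath = out / "summary.json"
    with open(spath, "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2, default=_json_default)
        fh.write("\n")
    written.append(spath)
    return written


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_report(outdir) -> RunReport:
    """Load a written report back; inverse of :func:`write_report`."""
    out = Path(outdir)
    spath = out / "summary.json"
    with open(spath) as fh:
        summary = json.load(fh)
    report = RunReport(
        summaries=summary.get("stage_summaries", {}),
        provenance=summary.get("provenance", {}),
        warnings=summary.get("warnings", []),
    )
    for name in summary.get("stage_files", []):
        stage = Path(name).stem
        report.tables[stage] = pd.read_csv(out / name, sep="\t", na_values=["NA"],
                                           keep_default_na=False)
    return report
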