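"""Tabular interchange formats.

Every stage of the pipeline communicates through plain tab-separated
tables: GWAS summary statistics (one variant-trait association per row),
individual-level cohort tables (one row per person), and square LD
correlation matrices. Readers validate on ingestion and reject bad rows
with a recorded reason rather than silently coercing them; writers
serialise floats at full precision so that write-then-read is the
identity on valid tables.

Coordinates are 1-based (GRCh37 convention). Missing values are written
as ``NA``; the effect-allele frequency is the only optional numeric
column. Strand is not encoded — allele complementing is the
harmonization step's job, not the reader's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistics tables.
SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

MANDATORY_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se"]

VALID_ALLELES = frozenset("ACGT")

#: |z_from_p - |beta|/se| tolerance for the p-value consistency check.
#: Published tables round; inconsistency is logged, not fatal.
Z_CONSISTENCY_TOL = 0.05


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``: per-SD units
    for quantitative traits, log odds ratio for binary traits.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str = ""
    pos: int = 0
    eaf: float = math.nan
    pvalue: float = math.nan
    n: float = math.nan

    def zscore(self) -> float:
        return self.beta / self.se

    def with_alleles_swapped(self) -> "SummaryStatRecord":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=1.0 - self.eaf if not math.isnan(self.eaf) else math.nan,
        )


def validate_record(rec: SummaryStatRecord) -> str | None:
    """Return a rejection reason for an invalid record, or None."""
    ea, oa = rec.effect_allele, rec.other_allele
    if not (set(ea) <= VALID_ALLELES and set(oa) <= VALID_ALLELES) or not ea or not oa:
        return "invalid alleles"
    if len(ea) != 1 or len(oa) != 1:
        return "multi-allelic"
    if ea == oa:
        return "degenerate alleles"
    if not math.isfinite(rec.beta):
        return "non-finite beta"
    if not (math.isfinite(rec.se) and rec.se > 0):
        return "non-positive se"
    if not math.isnan(rec.eaf) and not (0.0 < rec.eaf < 1.0):
        return "eaf outside (0,1)"
    if not math.isnan(rec.pvalue):
        if not (0.0 < rec.pvalue <= 1.0):
            return "pvalue outside (0,1]"
        from scipy.stats import norm

        z_from_p = abs(norm.isf(rec.pvalue / 2.0))
        if math.isfinite(z_from_p) and abs(z_from_p - abs(rec.beta) / rec.se) > Z_CONSISTENCY_TOL:
            logger.debug(
                "variant %s: p-value inconsistent with beta/se (z_p=%.3f, |beta|/se=%.3f)",
                rec.variant_id, z_from_p, abs(rec.beta) / rec.se,
            )
    return None


@dataclass
class SummaryStatsTable:
    """Ordered, validated collection of records for one trait."""

    trait_id: str
    records: list[SummaryStatRecord]
    trait_type: str = "quantitative"  # or "case-control"
    units: str = ""
    #: (row index, variant_id, reason) for rows rejected on ingestion.
    rejections: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case-control"):
            raise FormatError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({v for v in ids if ids.count(v) > 1})
            raise FormatError(f"duplicate variant_id in table {self.trait_id!r}: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def get(self, variant_id: str) -> SummaryStatRecord:
        for r in self.records:
            if r.variant_id == variant_id:
                return r
        raise KeyError(variant_id)

    def subset(self, variant_ids: list[str]) -> "SummaryStatsTable":
        """Restrict to the given variants, in the given order."""
        return SummaryStatsTable(
            trait_id=self.trait_id,
            records=[self.get(v) for v in variant_ids],
            trait_type=self.trait_type,
            units=self.units,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.records], columns=SUMMARY_COLUMNS)
        if not len(self.records):
            df = pd.DataFrame(columns=SUMMARY_COLUMNS)
        return df


def _coerce_row(row: pd.Series) -> SummaryStatRecord:
    def _f(key: str) -> float:
        v = row.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "NA" or v == "":
            return math.nan
        return float(v)

    return SummaryStatRecord(
        variant_id=str(row["variant_id"]),
        chrom=str(row.get("chrom", "") or ""),
        pos=int(row["pos"]) if not math.isnan(_f("pos")) else 0,
        effect_allele=str(row["effect_allele"]).upper(),
        other_allele=str(row["other_allele"]).upper(),
        eaf=_f("eaf"),
        beta=_f("beta"),
        se=_f("se"),
        pvalue=_f("pvalue"),
        n=_f("n"),
    )


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
) -> SummaryStatsTable:
    """Read a tab-separated summary-statistics file.

    Parameters
    ----------
    column_map
        Mapping from the file's header names to the canonical names in
        :data:`SUMMARY_COLUMNS`, for files with nonstandard headers.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    except OSError as exc:
        raise FormatError(f"cannot read summary statistics from {path}: {exc}") from exc
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")

    records: list[SummaryStatRecord] = []
    rejections: list[tuple[int, str, str]] = []
    for i, row in df.iterrows():
        try:
            rec = _coerce_row(row)
        except (ValueError, TypeError):
            rejections.append((int(i), str(row.get("variant_id", "?")), "unparseable row"))
            continue
        reason = validate_record(rec)
        if reason is None:
            records.append(rec)
        else:
            rejections.append((int(i), rec.variant_id, reason))
    for i, vid, reason in rejections:
        logger.info("rejected row %d (%s): %s", i, vid, reason)
    table = SummaryStatsTable(
        trait_id=trait_id or str(path),
        records=records,
        trait_type=trait_type,
    )
    table.rejections = rejections
    return table


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table in canonical column order, round-trip safe."""
    df = table.to_frame()
    # repr-precision floats so that read(write(t)) == t exactly
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_ld_matrix(path, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Read a square LD correlation matrix with variant-id header row/column.

    The matrix is checked for symmetry and a unit diagonal (tolerance
    1e-8) and, when ``variant_ids`` is given, subset and reordered to
    those variants.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except OSError as exc:
        raise FormatError(f"cannot read LD matrix from {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("LD matrix row and column variant ids differ")
    m = df.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise FormatError("LD matrix is not symmetric within 1e-8")
    if not np.allclose(np.diag(m), 1.0, atol=1e-8):
        raise FormatError("LD matrix diagonal differs from 1 beyond 1e-8")
    # enforce exact symmetry / unit diagonal after the tolerance check
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    df = pd.DataFrame(m, index=df.index, columns=df.columns)
    if variant_ids is not None:
        missing = [v for v in variant_ids if v not in df.index]
        if missing:
            raise FormatError(f"variants absent from LD matrix: {missing}")
        df = df.loc[variant_ids, variant_ids]
    return df


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t", float_format="%.17g")
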