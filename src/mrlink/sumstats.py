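"""Data model and TSV I/O for GWAS/eQTL summary statistics.

The central containers are :class:`SummaryStatsTable` (one trait, one row
per SNP) and :class:`HarmonizedSet` (exposure/outcome effect pairs aligned
to a shared effect allele — the unit every MR estimator consumes).

Effect sizes for binary traits are on the log-odds scale; quantitative
traits are treated as SD-standardized (this assumption is recorded in run
metadata by the pipeline).

Canonical TSV columns: ``snp, chr, pos, effect_allele, other_allele, eaf,
beta, se, pval, n``. Other headers are handled via a dialect mapping at
read time; written files always use the canonical names.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, EmptyInputError

__all__ = [
    "CANONICAL_COLUMNS",
    "EXCLUSION_REASONS",
    "SnpAssociation",
    "SummaryStatsTable",
    "HarmonizedSet",
    "ExclusionRecord",
    "ParseReport",
    "read_sumstats",
    "write_sumstats",
    "beta_to_or",
]

CANONICAL_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]
_REQUIRED = ["snp", "effect_allele", "other_allele", "beta", "se"]
_VALID_ALLELES = frozenset("ACGT")

#: Closed vocabulary of reasons a SNP can be excluded between the raw
#: exposure table and the final harmonized set.
EXCLUSION_REASONS = frozenset({
    "pval", "weak_instrument", "cis_window", "ld_clump", "maf",
    "palindrome", "exclusion_list", "allele_mismatch", "presso_outlier",
    "missing_in_outcome",
})


def _valid_snp_alleles(ea: str, oa: str) -> bool:
    """Single-nucleotide, distinct, ACGT alleles (indels rejected)."""
    return (
        len(ea) == 1 and len(oa) == 1
        and ea in _VALID_ALLELES and oa in _VALID_ALLELES
        and ea != oa
    )


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is per effect-allele copy: log odds for binary traits, SD
    units for quantitative traits. ``eaf`` and ``n`` may be missing
    (None); operations that need them must fail loudly rather than
    impute.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not _valid_snp_alleles(self.effect_allele, self.other_allele):
            raise ValueError(
                f"{self.snp_id}: invalid allele pair "
                f"({self.effect_allele!r}, {self.other_allele!r})"
            )
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.snp_id}: eaf must lie in (0,1)")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must lie in (0,1]")


@dataclass(frozen=True)
class ExclusionRecord:
    """Why one SNP was dropped at one pipeline stage."""

    snp_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


@dataclass
class ParseReport:
    """Row accounting for one :func:`read_sumstats` call."""

    n_rows: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class SummaryStatsTable:
    """Summary statistics for one trait; one row per SNP.

    Backed by a pandas DataFrame with the canonical columns. ``snp`` is
    unique within a table.
    """

    trait_id: str
    trait_type: str  # "binary" | "quantitative"
    data: pd.DataFrame
    parse_report: ParseReport | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"bad trait_type {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"table missing columns {missing}")
        if self.data["snp"].duplicated().any():
            dups = self.data.loc[self.data["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate snp ids: {dups[:5]}")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def records(self) -> Iterator[SnpAssociation]:
        for row in self.data.itertuples(index=False):
            yield SnpAssociation(
                snp_id=row.snp, chrom=str(row.chr),
                pos=int(row.pos) if pd.notna(row.pos) else 0,
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta=float(row.beta), se=float(row.se), pval=float(row.pval),
                n=None if pd.isna(row.n) else float(row.n),
            )

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStatsTable":
        """Rows for the given SNPs, in this table's order."""
        mask = self.data["snp"].isin(set(snp_ids))
        return SummaryStatsTable(self.trait_id, self.trait_type,
                                 self.data.loc[mask].reset_index(drop=True))


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a shared effect allele.

    ``data`` columns: snp, beta_exp, se_exp, beta_out, se_out, eaf_exp,
    eaf_out. ``provenance`` records every SNP excluded on the way from
    the raw exposure table to this set, each exactly once.
    """

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame
    provenance: list[ExclusionRecord] = field(default_factory=list)

    _COLUMNS = ["snp", "beta_exp", "se_exp", "beta_out", "se_out",
                "eaf_exp", "eaf_out"]

    def __post_init__(self) -> None:
        missing = [c for c in self._COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"harmonized set missing columns {missing}")
        if self.data["snp"].duplicated().any():
            raise ValueError("duplicate snp ids in harmonized set")
        if len(self.data):
            if (self.data["se_exp"] <= 0).any() or (self.data["se_out"] <= 0).any():
                raise ValueError("harmonized set contains non-positive SEs")
        seen = Counter(r.snp_id for r in self.provenance)
        repeats = [s for s, c in seen.items() if c > 1]
        if repeats:
            raise ValueError(f"SNPs with multiple provenance records: {repeats[:5]}")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        d = self.data
        return (d["beta_exp"].to_numpy(float), d["se_exp"].to_numpy(float),
                d["beta_out"].to_numpy(float), d["se_out"].to_numpy(float))

    def drop(self, snp_ids: Sequence[str], reason: str) -> "HarmonizedSet":
        """New set without the given SNPs, exclusions logged."""
        ids = set(snp_ids)
        mask = self.data["snp"].isin(ids)
        new_prov = self.provenance + [
            ExclusionRecord(s, reason) for s in self.data.loc[mask, "snp"]
        ]
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.data.loc[~mask].reset_index(drop=True),
                             new_prov)


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a summary-statistics TSV into a :class:`SummaryStatsTable`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Maps file column names to canonical ones, e.g. ``{"rsid": "snp"}``.
        Canonical names always pass through unchanged.
    trait_id
        Defaults to the file stem.
    trait_type
        "quantitative" or "binary" (log-odds betas).

    Rows with non-numeric beta/se, se <= 0, invalid alleles (including
    indels) or duplicated SNP ids are dropped and counted in the table's
    ``parse_report``. A missing pval column is derived from beta/se under
    a normal approximation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if dialect:
        raw = raw.rename(columns=dict(dialect))
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; "
            f"supply a dialect mapping if the file uses other names"
        )
    report = ParseReport(n_rows=len(raw))
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    df = pd.DataFrame(index=raw.index)
    df["snp"] = raw["snp"].astype(str).str.strip()
    df["chr"] = raw["chr"].astype(str).str.strip() if "chr" in raw else ""
    df["pos"] = pd.to_numeric(raw["pos"], errors="coerce") if "pos" in raw else np.nan
    df["effect_allele"] = raw["effect_allele"].astype(str).str.strip().str.upper()
    df["other_allele"] = raw["other_allele"].astype(str).str.strip().str.upper()
    df["eaf"] = pd.to_numeric(raw["eaf"], errors="coerce") if "eaf" in raw else np.nan
    df["beta"] = pd.to_numeric(raw["beta"], errors="coerce")
    df["se"] = pd.to_numeric(raw["se"], errors="coerce")
    df["pval"] = pd.to_numeric(raw["pval"], errors="coerce") if "pval" in raw else np.nan
    df["n"] = pd.to_numeric(raw["n"], errors="coerce") if "n" in raw else np.nan

    bad_numeric = df["beta"].isna() | df["se"].isna() | (df["se"] <= 0)
    report.dropped["bad_beta_se"] = int(bad_numeric.sum())
    df = df[~bad_numeric]

    ok_alleles = df.apply(
        lambda r: _valid_snp_alleles(r["effect_allele"], r["other_allele"]), axis=1
    ) if len(df) else pd.Series(dtype=bool)
    report.dropped["bad_alleles"] = int((~ok_alleles).sum()) if len(df) else 0
    df = df[ok_alleles] if len(df) else df

    if len(df):
        bad_eaf = df["eaf"].notna() & ~df["eaf"].between(0, 1, inclusive="neither")
        report.dropped["bad_eaf"] = int(bad_eaf.sum())
        df = df[~bad_eaf]

    if len(df):
        # derive missing p-values from the Wald statistic
        need_p = df["pval"].isna()
        if need_p.any():
            z = (df.loc[need_p, "beta"] / df.loc[need_p, "se"]).abs()
            df.loc[need_p, "pval"] = 2 * stats.norm.sf(z)
        df["pval"] = df["pval"].clip(lower=np.nextafter(0, 1), upper=1.0)
        bad_p = ~df["pval"].between(0, 1, inclusive="right")
        report.dropped["bad_pval"] = int(bad_p.sum())
        df = df[~bad_p]

    if len(df):
        dup = df["snp"].duplicated()
        report.dropped["duplicate_snp"] = int(dup.sum())
        df = df[~dup]

    report.n_kept = len(df)
    if report.n_kept == 0:
        raise EmptyInputError(f"{path}: no parseable rows "
                              f"(dropped {report.n_dropped})")
    return SummaryStatsTable(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        data=df[CANONICAL_COLUMNS].reset_index(drop=True),
        parse_report=report,
    )


def write_sumstats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write the canonical-header TSV; round-trips with :func:`read_sumstats`.

    Missing eaf/n/pval values are written as empty cells.
    """
    out = table.data[CANONICAL_COLUMNS].copy()
    # integer positions where present, so round-trips are textual no-ops
    out["pos"] = out["pos"].map(
        lambda v: "" if pd.isna(v) else str(int(v)))
    out["n"] = out["n"].map(
        lambda v: "" if pd.isna(v) else (str(int(v)) if float(v).is_integer() else repr(float(v))))
    for col in ("eaf", "beta", "se", "pval"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


def beta_to_or(beta: float, se: float, level: float = 0.95
               ) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect into (OR, ci_low, ci_high).

    The interval is the Wald interval exp(beta ± z·se) at the given
    two-sided confidence level (default 0.95).
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0,1)")
    z = stats.norm.ppf(0.5 + level / 2)
    return (math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se))
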