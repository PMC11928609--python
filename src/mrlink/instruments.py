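"""Instrument selection and harmonization for two-sample MR.

Implements the conventional filtering cascade for cis-eQTL / GWAS
instruments — association p-value, instrument-strength F, cis window,
MAF, user exclusion list, palindrome removal, then greedy LD clumping —
and the allele harmonization that aligns exposure and outcome effects
onto a shared effect allele.

The filter order is fixed (p → F → cis → MAF → exclusion → palindrome →
clump) so reruns are deterministic; clumping runs last to maximize
retention of the strongest independent signals. Every removal is logged
with a reason from :data:`mrlink.sumstats.EXCLUSION_REASONS`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError
from .sumstats import (
    ExclusionRecord,
    HarmonizedSet,
    SummaryStatsTable,
)

__all__ = [
    "SelectionConfig",
    "LdTable",
    "f_statistic",
    "is_palindromic",
    "select_instruments",
    "harmonize",
    "remove_presso_outliers",
]


@dataclass
class SelectionConfig:
    """Thresholds for the instrument-selection cascade.

    Defaults follow the common drug-target MR convention: association
    p < 1e-5, F > 10, ±100 kb cis window, clumping at r² = 0.3 within
    100 kb, MAF > 0.01, palindromic SNPs removed outright.
    """

    p_threshold: float = 1e-5
    f_threshold: float = 10.0
    cis_window_bp: int = 100_000
    ld_r2: float = 0.3
    ld_window_bp: int = 100_000
    maf_min: float = 0.01
    drop_palindromes: bool = True
    exclusion_list: frozenset[str] = field(default_factory=frozenset)
    #: When True, SNPs without an allele frequency fail the MAF filter;
    #: otherwise they pass with a warning.
    strict_maf: bool = False

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.f_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.ld_r2 <= 1):
            raise ValueError("ld_r2 must lie in (0,1]")
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must lie in (0,0.5)")
        if self.cis_window_bp <= 0 or self.ld_window_bp <= 0:
            raise ValueError("window widths must be positive")
        self.exclusion_list = frozenset(self.exclusion_list)


class LdTable:
    """Sparse symmetric pairwise r² map.

    Pairs not present are taken as r² = 0 (unlinked); self-pairs are
    always 1. Typically loaded from a precomputed reference-panel export
    (TSV: snp_a, snp_b, r2) or emitted by the simulator.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset[str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2 out of range: {r2}")
        if a == b:
            return
        self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdTable":
        df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        table = cls()
        for row in df.itertuples(index=False):
            table.set(row.snp_a, row.snp_b, float(row.r2))
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(
            (tuple(sorted(pair)) + (r2,)) for pair, r2 in self._r2.items()
        )
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False)


def f_statistic(beta, se):
    """Instrument-strength F statistic, (beta/se)².

    Vectorized; F > 10 is the conventional weak-instrument cutoff.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _greedy_clump(df: pd.DataFrame, ld: LdTable, r2_max: float,
                  window_bp: int) -> tuple[list[str], list[str]]:
    """Greedy LD clump: ascending p, keep a SNP iff r² < r2_max with every
    already-kept SNP within the window on the same chromosome.

    Ties in p broken by (chr, pos, snp) for determinism. SNPs without a
    position are treated as within-window of everything on any
    chromosome (conservative).
    """
    order = df.assign(
        _pos_key=df["pos"].fillna(-1),
    ).sort_values(["pval", "chr", "_pos_key", "snp"], kind="stable")
    kept: list[tuple[str, str, float]] = []  # (snp, chr, pos)
    removed: list[str] = []
    for row in order.itertuples(index=False):
        pos = float(row.pos) if pd.notna(row.pos) else None
        linked = False
        for ksnp, kchr, kpos in kept:
            if pos is not None and kpos is not None:
                if str(row.chr) != str(kchr) or abs(pos - kpos) > window_bp:
                    continue
            if ld.r2(row.snp, ksnp) >= r2_max:
                linked = True
                break
        if linked:
            removed.append(row.snp)
        else:
            kept.append((row.snp, str(row.chr), pos))
    return [k[0] for k in kept], removed


def select_instruments(
    exposure: SummaryStatsTable,
    cfg: SelectionConfig,
    ld: LdTable | None = None,
    gene_region: tuple[str, int, int] | None = None,
) -> tuple[SummaryStatsTable, list[ExclusionRecord]]:
    """Apply the full selection cascade to an exposure table.

    Parameters
    ----------
    exposure
        Raw exposure summary statistics.
    cfg
        Thresholds; see :class:`SelectionConfig`.
    ld
        Pairwise r² table for clumping. ``None`` means no LD information:
        every pair is treated as unlinked and clumping is a no-op.
    gene_region
        (chrom, start, end) of the cis gene; when given, only SNPs within
        ``cfg.cis_window_bp`` of [start, end] on that chromosome survive.

    Returns
    -------
    (kept, provenance)
        Kept table in the original row order, and one exclusion record
        per removed SNP. Zero survivors yields an empty table (callers
        decide whether that is fatal).
    """
    if exposure.n_snp == 0:
        raise EmptyResultError("exposure table is empty")
    df = exposure.data.copy()
    provenance: list[ExclusionRecord] = []

    def log_and_drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        for snp in df.loc[mask, "snp"]:
            provenance.append(ExclusionRecord(snp, reason))
        df = df.loc[~mask]

    # 1. association p-value
    log_and_drop(~(df["pval"] < cfg.p_threshold), "pval")

    # 2. instrument strength
    if len(df):
        f = f_statistic(df["beta"], df["se"])
        log_and_drop(pd.Series(~(f > cfg.f_threshold), index=df.index),
                     "weak_instrument")

    # 3. cis window
    if len(df) and gene_region is not None:
        chrom, start, end = gene_region
        lo, hi = start - cfg.cis_window_bp, end + cfg.cis_window_bp
        in_cis = (
            (df["chr"].astype(str) == str(chrom))
            & df["pos"].notna()
            & df["pos"].between(lo, hi)
        )
        log_and_drop(~in_cis, "cis_window")

    # 4. minor allele frequency
    if len(df):
        maf = np.minimum(df["eaf"], 1 - df["eaf"])
        fails = maf < cfg.maf_min
        no_eaf = df["eaf"].isna()
        if no_eaf.any() and not cfg.strict_maf:
            warnings.warn(
                f"{int(no_eaf.sum())} SNP(s) lack eaf; passing the MAF "
                "filter unchecked (set strict_maf to drop them)",
                stacklevel=2,
            )
        fails = fails.fillna(False) | (no_eaf & cfg.strict_maf)
        log_and_drop(fails, "maf")

    # 5. user exclusion list (confounder-associated SNPs etc.)
    if len(df) and cfg.exclusion_list:
        log_and_drop(df["snp"].isin(cfg.exclusion_list), "exclusion_list")

    # 6. palindromes
    if len(df) and cfg.drop_palindromes:
        pal = df.apply(
            lambda r: is_palindromic(r["effect_allele"], r["other_allele"]),
            axis=1,
        )
        log_and_drop(pal, "palindrome")

    # 7. greedy LD clumping
    if len(df) and ld is not None and len(ld):
        _, clumped = _greedy_clump(df, ld, cfg.ld_r2, cfg.ld_window_bp)
        log_and_drop(df["snp"].isin(clumped), "ld_clump")

    kept = SummaryStatsTable(exposure.trait_id, exposure.trait_type,
                             df.reset_index(drop=True))
    return kept, provenance


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    provenance: Iterable[ExclusionRecord] = (),
) -> HarmonizedSet:
    """Align exposure and outcome effects to the exposure's effect allele.

    For each exposure SNP: if the outcome lists the same allele pair the
    row passes through; if effect/other are swapped the outcome beta's
    sign is flipped and eaf_out becomes 1 − eaf_out; incompatible allele
    pairs are dropped (``allele_mismatch``), as are SNPs absent from the
    outcome (``missing_in_outcome``).

    ``provenance`` seeds the harmonized set's exclusion log with records
    from earlier selection stages. Harmonizing an already-aligned pair of
    tables is a no-op on the effect sizes.
    """
    out_idx = outcome.data.set_index("snp")
    rows = []
    prov = list(provenance)
    for r in exposure.data.itertuples(index=False):
        if r.snp not in out_idx.index:
            prov.append(ExclusionRecord(r.snp, "missing_in_outcome"))
            continue
        o = out_idx.loc[r.snp]
        ea_x, oa_x = r.effect_allele, r.other_allele
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        if (ea_x, oa_x) == (ea_y, oa_y):
            beta_out, eaf_out = float(o["beta"]), o["eaf"]
        elif (ea_x, oa_x) == (oa_y, ea_y):
            beta_out = -float(o["beta"])
            eaf_out = 1 - float(o["eaf"]) if pd.notna(o["eaf"]) else np.nan
        else:
            prov.append(ExclusionRecord(r.snp, "allele_mismatch"))
            continue
        rows.append({
            "snp": r.snp,
            "beta_exp": float(r.beta), "se_exp": float(r.se),
            "beta_out": beta_out, "se_out": float(o["se"]),
            "eaf_exp": float(r.eaf) if pd.notna(r.eaf) else np.nan,
            "eaf_out": float(eaf_out) if pd.notna(eaf_out) else np.nan,
        })
    data = pd.DataFrame(
        rows, columns=HarmonizedSet._COLUMNS) if rows else pd.DataFrame(
        columns=HarmonizedSet._COLUMNS)
    h = HarmonizedSet(exposure.trait_id, outcome.trait_id, data, prov)
    if h.n_snp == 0:
        raise EmptyResultError(
            f"no SNPs harmonized between {exposure.trait_id} and "
            f"{outcome.trait_id}")
    return h


def remove_presso_outliers(h: HarmonizedSet, presso) -> HarmonizedSet:
    """Drop rows flagged by an MR-PRESSO run on the same set.

    ``presso`` is a :class:`mrlink.sensitivity.PressoResult` computed on
    ``h``; row order of survivors is preserved and each removal is logged
    with reason ``presso_outlier``.
    """
    if not presso.outlier_indices:
        return h
    bad = [h.data["snp"].iloc[i] for i in sorted(presso.outlier_indices)]
    out = h.drop(bad, "presso_outlier")
    if out.n_snp == 0:
        raise EmptyResultError("MR-PRESSO flagged every instrument")
    return out
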