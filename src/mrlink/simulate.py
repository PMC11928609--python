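"""Synthetic GWAS summary statistics with known causal ground truth.

Emulates the three-cornered drug-target MR design: a cis locus whose
variants instrument a drug target's expression (exposure), a circulating
metabolite partially transmitting the target's effect (mediator), and a
rare binary disease (outcome). Every dataset is generated at the
summary level — no individual-level genotypes — with standard errors
implied by the GWAS sample sizes, so the whole pipeline (selection,
harmonization, estimation, diagnostics, mediation) can run end to end
against a :class:`TruthFile` oracle.

Structure generated per scenario:

* ``n_snp`` instrument blocks plus null blocks in the exposure cis
  region; within a block all SNPs share the true effect and their
  sampling noise is correlated, which is what LD clumping must undo.
* ``n_med_snp`` mediator-specific instruments at a second locus: they
  move the mediator directly (effect δ_j) and the outcome only through
  it (β2·δ_j), giving the mediator its own valid instrument set for the
  second mediation step.
* True effects follow the path model
  mediator = β1·γ, outcome = β_direct·γ + β2·mediator (+ pleiotropy),
  so the total exposure→outcome slope is β_direct + β1·β2.
* Quantitative-trait SEs are 1/√(2·n·eaf·(1−eaf)) (SD-standardized
  trait); the binary outcome uses √(1/(n·v·2·eaf·(1−eaf))) with case
  fraction v, matching the effective-sample-size behaviour of a
  logistic GWAS of a rare disease.
* Optional horizontal pleiotropy (fraction π of instrument blocks get a
  direct outcome and/or mediator effect ~ N(μα, σα)), palindromic
  allele pairs, and randomly swapped allele order in the non-exposure
  tables (exercises harmonization).

The default scenario is calibrated to a probucol/ABCA1-like study:
exposure GWAS n = 31,684, outcome GWAS n = 317,252 with a rare-disease
case fraction, true step effects OR 0.917 (exposure→mediator) and
OR 2.0499 (mediator→outcome), total effect OR 0.4957, and 30
independent cis instruments with mean F well above the weak-instrument
threshold.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .instruments import LdTable
from .sumstats import (
    CANONICAL_COLUMNS,
    HarmonizedSet,
    SummaryStatsTable,
    write_sumstats,
)

__all__ = [
    "SimScenario",
    "TruthFile",
    "simulate_triplet",
    "simulate_harmonized_sets",
    "simulate_mediator_battery",
    "calibrated_scenario",
    "null_scenario",
    "write_triplet",
]

_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimScenario:
    """Parameters of one synthetic study.

    The defaults are the study conditions every calibration test runs
    under; see the methods note for the rationale behind each value.
    """

    seed: int = 0
    n_snp: int = 30                #: exposure instrument blocks
    n_null_snp: int = 200          #: null SNPs in the exposure cis region
    n_med_snp: int = 30            #: mediator-specific instruments
    gene_region: tuple[str, int, int] = ("1", 1_000_000, 1_150_000)
    med_region: tuple[str, int, int] = ("2", 50_000_000, 50_150_000)
    n_exp: int = 31_684
    n_med: int = 118_000
    n_out: int = 317_252
    case_fraction: float = 0.001   #: outcome cases / total (rare disease)
    beta1: float = math.log(0.917)
    beta2: float = math.log(2.0499)
    beta_direct: float = field(default=None)  # type: ignore[assignment]
    #: (mean |γ|, sd) of instrument effects on expression, SD units
    instrument_strength: tuple[float, float] = (0.06, 0.015)
    #: (mean |δ|, sd) of mediator-specific instrument effects
    med_instrument_strength: tuple[float, float] = (0.05, 0.010)
    #: (fraction π, mean μα, sd σα) of pleiotropic direct effects
    pleiotropy: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: (block size, within-block r²); size 1 = independent SNPs
    ld_blocks: tuple[int, float] = (1, 0.8)
    palindrome_fraction: float = 0.0
    #: probability the mediator/outcome tables list the allele pair in
    #: swapped order (beta sign flipped accordingly)
    allele_swap_fraction: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.beta_direct is None:
            # calibrate so the total equals the headline protective OR
            self.beta_direct = math.log(0.4957) - self.beta1 * self.beta2
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be >= 1")
        if min(self.n_exp, self.n_med, self.n_out) <= 0:
            raise ConfigurationError("sample sizes must be positive")
        if not (0 <= self.pleiotropy[0] <= 1):
            raise ConfigurationError("pleiotropy fraction must lie in [0,1]")
        if not (0 < self.ld_blocks[1] <= 1):
            raise ConfigurationError("within-block r2 must lie in (0,1]")
        if not (0 < self.case_fraction < 1):
            raise ConfigurationError("case_fraction must lie in (0,1)")
        if not (0 < self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo < hi <= 0.5")

    @property
    def total(self) -> float:
        """True total exposure→outcome effect, β_direct + β1·β2."""
        return self.beta_direct + self.beta1 * self.beta2

    @property
    def proportion_mediated_pct(self) -> float:
        """True mediated share, 100·β1β2/total (undefined at total = 0)."""
        if self.total == 0:
            return math.nan
        return 100.0 * self.beta1 * self.beta2 / self.total


@dataclass
class TruthFile:
    """Ground truth for one simulated triplet (the oracle for tests).

    ``per_snp`` columns: snp, gamma (true exposure effect), delta (true
    mediator-specific effect), alpha_med, alpha_out (pleiotropic
    effects), block, is_instrument, is_med_instrument.
    """

    beta1: float
    beta2: float
    beta_direct: float
    total: float
    proportion_mediated_pct: float
    per_snp: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta1": self.beta1, "beta2": self.beta2,
            "beta_direct": self.beta_direct, "total": self.total,
            "proportion_mediated_pct": self.proportion_mediated_pct,
            "per_snp": self.per_snp.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthFile":
        payload = json.loads(Path(path).read_text())
        per_snp = pd.DataFrame(payload.pop("per_snp"))
        return cls(per_snp=per_snp, **payload)


def _se_quantitative(n: int, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _se_binary(n: int, v: float, eaf: np.ndarray) -> np.ndarray:
    return np.sqrt(1.0 / (n * v * 2.0 * eaf * (1.0 - eaf)))


def _block_noise(rng: np.random.Generator, se: np.ndarray,
                 blocks: np.ndarray, r: float) -> np.ndarray:
    """Noise with pairwise correlation r within each block label."""
    z = rng.standard_normal(se.size)
    if r <= 0:
        return se * z
    shared = rng.standard_normal(int(blocks.max()) + 1)
    return se * (math.sqrt(r) * shared[blocks] + math.sqrt(1 - r) * z)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _draw_alleles(rng: np.random.Generator, n: int, palindrome_fraction: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pal = rng.random(n) < palindrome_fraction
    for i in range(n):
        pool = _PALINDROMIC if pal[i] else _NON_PALINDROMIC
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa


def _layout(s: SimScenario, rng: np.random.Generator) -> pd.DataFrame:
    """Per-SNP static layout: ids, positions, blocks, alleles, eaf, truth."""
    block_size, _ = s.ld_blocks
    n_null_blocks = math.ceil(s.n_null_snp / block_size) if s.n_null_snp else 0
    n_exp_blocks = s.n_snp + n_null_blocks
    rows = []
    chrom, start, end = s.gene_region
    block_starts = np.sort(rng.integers(start, end, size=n_exp_blocks))
    block_is_instr = np.zeros(n_exp_blocks, bool)
    block_is_instr[rng.permutation(n_exp_blocks)[:s.n_snp]] = True
    snp_counter = 0
    for b in range(n_exp_blocks):
        for j in range(block_size):
            snp_counter += 1
            rows.append({
                "snp": f"rs{100000 + snp_counter}",
                "chr": str(chrom),
                "pos": int(block_starts[b]) + 100 * j,
                "block": b,
                "is_instrument": bool(block_is_instr[b]),
                "is_med_instrument": False,
            })
    mchrom, mstart, mend = s.med_region
    mpos = np.sort(rng.integers(mstart, mend, size=s.n_med_snp))
    for i in range(s.n_med_snp):
        snp_counter += 1
        rows.append({
            "snp": f"rs{100000 + snp_counter}",
            "chr": str(mchrom),
            "pos": int(mpos[i]),
            "block": n_exp_blocks + i,
            "is_instrument": False,
            "is_med_instrument": True,
        })
    df = pd.DataFrame(rows)
    n = len(df)
    df["eaf"] = rng.uniform(*s.maf_range, size=n)
    ea, oa = _draw_alleles(rng, n, s.palindrome_fraction)
    df["effect_allele"], df["other_allele"] = ea, oa

    # true effects: shared within a block
    mean_g, sd_g = s.instrument_strength
    gamma_block = np.zeros(n_exp_blocks + s.n_med_snp)
    signs = rng.choice([-1.0, 1.0], size=n_exp_blocks)
    mags = np.abs(rng.normal(mean_g, sd_g, size=n_exp_blocks))
    gamma_block[:n_exp_blocks] = np.where(block_is_instr, signs * mags, 0.0)
    mean_d, sd_d = s.med_instrument_strength
    delta_block = np.zeros_like(gamma_block)
    delta_block[n_exp_blocks:] = (
        rng.choice([-1.0, 1.0], size=s.n_med_snp)
        * np.abs(rng.normal(mean_d, sd_d, size=s.n_med_snp)))

    pi, mu_a, sd_a = s.pleiotropy
    alpha_med_block = np.zeros_like(gamma_block)
    alpha_out_block = np.zeros_like(gamma_block)
    if pi > 0:
        # "directional" means relative to the exposure-raising allele:
        # align each pleiotropic effect with sign(γ) so a nonzero mean
        # survives the βX >= 0 orientation that Egger regression applies
        instr_blocks = np.flatnonzero(block_is_instr)
        orient = np.sign(gamma_block[instr_blocks])
        chosen = rng.random(instr_blocks.size) < pi
        alpha_out_block[instr_blocks[chosen]] = (
            orient[chosen] * rng.normal(mu_a, sd_a, size=int(chosen.sum())))
        chosen_m = rng.random(instr_blocks.size) < pi
        alpha_med_block[instr_blocks[chosen_m]] = (
            orient[chosen_m] * rng.normal(mu_a, sd_a, size=int(chosen_m.sum())))

    df["gamma"] = gamma_block[df["block"]]
    df["delta"] = delta_block[df["block"]]
    df["alpha_med"] = alpha_med_block[df["block"]]
    df["alpha_out"] = alpha_out_block[df["block"]]
    return df


def _true_effects(s: SimScenario, layout: pd.DataFrame
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    gamma = layout["gamma"].to_numpy()
    delta = layout["delta"].to_numpy()
    true_exp = gamma
    true_med = s.beta1 * gamma + layout["alpha_med"].to_numpy() + delta
    true_out = (s.beta_direct * gamma + s.beta2 * true_med
                + layout["alpha_out"].to_numpy())
    return true_exp, true_med, true_out


def _observe(s: SimScenario, rng: np.random.Generator, layout: pd.DataFrame,
             true_beta: np.ndarray, se: np.ndarray, trait_id: str,
             trait_type: str, n_sample: int,
             swap_alleles: bool) -> SummaryStatsTable:
    _, r2 = s.ld_blocks
    r = math.sqrt(r2) if s.ld_blocks[0] > 1 else 0.0
    beta = true_beta + _block_noise(rng, se, layout["block"].to_numpy(), r)
    df = pd.DataFrame({
        "snp": layout["snp"], "chr": layout["chr"], "pos": layout["pos"],
        "effect_allele": layout["effect_allele"],
        "other_allele": layout["other_allele"],
        "eaf": layout["eaf"], "beta": beta, "se": se,
        "pval": _pvals(beta, se), "n": float(n_sample),
    })
    if swap_alleles and s.allele_swap_fraction > 0:
        flip = rng.random(len(df)) < s.allele_swap_fraction
        df.loc[flip, ["effect_allele", "other_allele"]] = (
            df.loc[flip, ["other_allele", "effect_allele"]].to_numpy())
        df.loc[flip, "beta"] = -df.loc[flip, "beta"]
        df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    return SummaryStatsTable(trait_id, trait_type,
                             df[CANONICAL_COLUMNS].reset_index(drop=True))


def _ld_table(s: SimScenario, layout: pd.DataFrame) -> LdTable:
    ld = LdTable()
    _, r2 = s.ld_blocks
    for _, grp in layout.groupby("block"):
        ids = grp["snp"].tolist()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ld.set(ids[i], ids[j], r2)
    return ld


def simulate_triplet(s: SimScenario, seed: int | None = None
                     ) -> tuple[SummaryStatsTable, SummaryStatsTable,
                                SummaryStatsTable, LdTable, TruthFile]:
    """Generate one (exposure, mediator, outcome) summary-statistics set.

    Returns the three tables (every SNP appears in all three), the
    pairwise LD table implied by the block structure, and the truth
    oracle. Identical ``seed`` → identical output, bit for bit.
    """
    rng = np.random.default_rng(s.seed if seed is None else seed)
    layout = _layout(s, rng)
    true_exp, true_med, true_out = _true_effects(s, layout)
    eaf = layout["eaf"].to_numpy()
    se_x = _se_quantitative(s.n_exp, eaf)
    se_m = _se_quantitative(s.n_med, eaf)
    se_y = _se_binary(s.n_out, s.case_fraction, eaf)
    exposure = _observe(s, rng, layout, true_exp, se_x, "exposure",
                        "quantitative", s.n_exp, swap_alleles=False)
    mediator = _observe(s, rng, layout, true_med, se_m, "mediator",
                        "quantitative", s.n_med, swap_alleles=True)
    outcome = _observe(s, rng, layout, true_out, se_y, "outcome",
                       "binary", s.n_out, swap_alleles=True)
    truth = TruthFile(
        beta1=s.beta1, beta2=s.beta2, beta_direct=s.beta_direct,
        total=s.total, proportion_mediated_pct=s.proportion_mediated_pct,
        per_snp=layout[["snp", "gamma", "delta", "alpha_med", "alpha_out",
                        "block", "is_instrument", "is_med_instrument"]].copy(),
    )
    return exposure, mediator, outcome, _ld_table(s, layout), truth


def simulate_harmonized_sets(s: SimScenario, seed: int | None = None
                             ) -> tuple[dict[str, HarmonizedSet], TruthFile]:
    """Fast path: pre-harmonized instrument sets for the three contrasts.

    Skips allele bookkeeping, null SNPs and file I/O, returning
    ready-to-estimate sets keyed ``"total"`` (exposure instruments vs
    outcome), ``"step1"`` (exposure instruments vs mediator) and
    ``"step2"`` (mediator-specific instruments vs outcome). Used by the
    replicated calibration studies, where only estimator behaviour is
    under test.
    """
    rng = np.random.default_rng(s.seed if seed is None else seed)
    fast = dataclasses.replace(s, n_null_snp=0, palindrome_fraction=0.0,
                               allele_swap_fraction=0.0)
    layout = _layout(fast, rng)
    true_exp, true_med, true_out = _true_effects(fast, layout)
    eaf = layout["eaf"].to_numpy()
    se_x = _se_quantitative(fast.n_exp, eaf)
    se_m = _se_quantitative(fast.n_med, eaf)
    se_y = _se_binary(fast.n_out, fast.case_fraction, eaf)
    r = math.sqrt(fast.ld_blocks[1]) if fast.ld_blocks[0] > 1 else 0.0
    blocks = layout["block"].to_numpy()
    bx = true_exp + _block_noise(rng, se_x, blocks, r)
    bm = true_med + _block_noise(rng, se_m, blocks, r)
    by = true_out + _block_noise(rng, se_y, blocks, r)

    is_instr = layout["is_instrument"].to_numpy()
    is_med = layout["is_med_instrument"].to_numpy()

    def build(mask, beta_e, se_e, beta_o, se_o, exp_id, out_id):
        idx = np.flatnonzero(mask)
        data = pd.DataFrame({
            "snp": layout["snp"].to_numpy()[idx],
            "beta_exp": beta_e[idx], "se_exp": se_e[idx],
            "beta_out": beta_o[idx], "se_out": se_o[idx],
            "eaf_exp": eaf[idx], "eaf_out": eaf[idx],
        })
        return HarmonizedSet(exp_id, out_id, data)

    sets = {
        "total": build(is_instr, bx, se_x, by, se_y, "exposure", "outcome"),
        "step1": build(is_instr, bx, se_x, bm, se_m, "exposure", "mediator"),
        "step2": build(is_med, bm, se_m, by, se_y, "mediator", "outcome"),
    }
    truth = TruthFile(
        beta1=fast.beta1, beta2=fast.beta2, beta_direct=fast.beta_direct,
        total=fast.total,
        proportion_mediated_pct=fast.proportion_mediated_pct,
        per_snp=layout[["snp", "gamma", "delta", "alpha_med", "alpha_out",
                        "block", "is_instrument", "is_med_instrument"]].copy(),
    )
    return sets, truth


def simulate_mediator_battery(s: SimScenario, n_traits: int = 123,
                              n_true: int = 36, n_positive: int = 6,
                              seed: int | None = None
                              ) -> tuple[SummaryStatsTable,
                                         dict[str, SummaryStatsTable],
                                         dict[str, float]]:
    """A battery of candidate mediator GWASs for screening studies.

    ``n_true`` traits receive a real exposure→mediator effect whose
    magnitude equals |β1| of the scenario (``n_positive`` of them with
    positive sign, the rest negative); the remaining traits are null.
    Only the exposure-region SNPs are emitted (step-1 screening needs
    nothing else). Returns (exposure table from the same SNP layout,
    mediator tables keyed by trait id, true β1 per trait).
    """
    if not (0 <= n_true <= n_traits and 0 <= n_positive <= n_true):
        raise ConfigurationError("need 0 <= n_positive <= n_true <= n_traits")
    rng = np.random.default_rng(s.seed if seed is None else seed)
    base = dataclasses.replace(s, n_med_snp=0, allele_swap_fraction=0.0)
    layout = _layout(base, rng)
    eaf = layout["eaf"].to_numpy()
    se_x = _se_quantitative(s.n_exp, eaf)
    se_m = _se_quantitative(s.n_med, eaf)
    gamma = layout["gamma"].to_numpy()
    exposure = _observe(base, rng, layout, gamma, se_x, "exposure",
                        "quantitative", s.n_exp, swap_alleles=False)
    mag = abs(s.beta1)
    signs = np.concatenate([np.ones(n_positive), -np.ones(n_true - n_positive)])
    true_b1 = np.concatenate([mag * signs, np.zeros(n_traits - n_true)])
    true_b1 = true_b1[rng.permutation(n_traits)]
    tables: dict[str, SummaryStatsTable] = {}
    truth: dict[str, float] = {}
    for t in range(n_traits):
        trait_id = f"metabolite_{t + 1:03d}"
        tbl = _observe(base, rng, layout, true_b1[t] * gamma, se_m,
                       trait_id, "quantitative", s.n_med, swap_alleles=False)
        tables[trait_id] = tbl
        truth[trait_id] = float(true_b1[t])
    return exposure, tables, truth


def calibrated_scenario(seed: int = 0) -> SimScenario:
    """The calibrated default scenario (see the module docstring)."""
    return SimScenario(seed=seed)


def null_scenario(seed: int = 0) -> SimScenario:
    """All causal paths zero: for type-I-error studies."""
    return SimScenario(seed=seed, beta1=0.0, beta2=0.0, beta_direct=0.0)


def write_triplet(out_dir: str | Path, exposure: SummaryStatsTable,
                  mediator: SummaryStatsTable, outcome: SummaryStatsTable,
                  ld: LdTable, truth: TruthFile) -> None:
    """Write exposure.tsv, mediator.tsv, outcome.tsv, ld.tsv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sumstats(exposure, out / "exposure.tsv")
    write_sumstats(mediator, out / "mediator.tsv")
    write_sumstats(outcome, out / "outcome.tsv")
    ld.to_tsv(out / "ld.tsv")
    truth.to_json(out / "truth.json")
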