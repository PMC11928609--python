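"""Univariable two-sample MR estimators.

Given a harmonized set of L instruments with exposure effects βX_j (SE
seX_j) and outcome effects βY_j (SE seY_j), every estimator here targets
the same causal slope β in βY_j ≈ β·βX_j, under different robustness
assumptions:

* Wald ratio — single instrument, βY/βX.
* IVW — inverse-variance-weighted meta-analysis of ratios, equivalent to
  zero-intercept weighted regression of βY on βX with weights seY⁻².
  The random-effects variant inflates the SE by a multiplicative
  overdispersion factor √(Q/(L−1)), floored at 1 (no underdispersion
  credit), so FE and RE coincide when Q ≤ df.
* MR-Egger — the same regression with a free intercept; a nonzero
  intercept indicates directional pleiotropy and the slope is a
  bias-adjusted estimate. Inference uses t(L−2); rows are oriented so
  βX_j ≥ 0 before fitting.
* Weighted median — consistent when instruments carrying ≥ 50% of the
  weight are valid; SE by parametric bootstrap.
* Simple/weighted mode — kernel-density mode of the ratio estimates
  (ZEMPA assumption: the largest homogeneous cluster is valid); SE from
  the median absolute deviation of bootstrap replicates.

IVW/Wald/median/mode p-values use the normal; Egger uses t(L−2) — the
mixed convention of standard MR software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .sumstats import HarmonizedSet, beta_to_or

__all__ = [
    "MrEstimate",
    "EggerIntercept",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimators",
    "run_all_methods",
    "METHOD_ORDER",
]

#: Row order of the five-method table (matches common reporting order).
METHOD_ORDER = ["egger", "weighted_median", "ivw_re", "simple_mode",
                "weighted_mode"]


def _norm_p(z: float) -> float:
    return float(min(1.0, max(2 * stats.norm.sf(abs(z)), 5e-324)))


@dataclass(frozen=True)
class MrEstimate:
    """One causal-effect estimate (one row of a results table)."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_ci: tuple[float, float, float]  # (OR, low, high) at 95%

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int,
                     pval: float | None = None, level: float = 0.95
                     ) -> "MrEstimate":
        if se <= 0:
            raise ValueError("se must be > 0")
        if pval is None:
            pval = _norm_p(beta / se)
        return cls(method=method, beta=float(beta), se=float(se),
                   pval=float(pval), n_snp=int(n_snp),
                   or_ci=beta_to_or(beta, se, level))


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept term: the average directional pleiotropy."""

    intercept: float
    se: float
    pval: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be > 0")


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float,
               se_out: float) -> MrEstimate:
    """Single-instrument causal estimate βY/βX with first-order SE seY/|βX|.

    The first-order SE ignores uncertainty in βX; adequate for the
    strong instruments (F > 10) this pipeline selects.
    """
    if beta_exp == 0:
        raise UndefinedRatioError("Wald ratio undefined for beta_exp = 0")
    if se_out <= 0:
        raise ValueError("se_out must be > 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MrEstimate.from_beta_se("wald_ratio", beta, se, 1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, se_out: np.ndarray
              ) -> tuple[float, float, float]:
    """(beta, se_fe, Q) for fixed-effect IVW."""
    w = se_out ** -2.0
    denom = float(np.sum(w * bx * bx))
    if denom <= 0:
        raise ValueError("all exposure betas are zero; IVW undefined")
    beta = float(np.sum(w * bx * by)) / denom
    se_fe = denom ** -0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fe, q


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MrEstimate:
    """Inverse-variance-weighted estimate over ≥ 2 instruments.

    Equals the weighted-least-squares solution of βY = β·βX (no
    intercept) with weights seY⁻². With ``random_effects`` the SE is
    multiplied by max(1, √(Q/(L−1))) where Q is Cochran's statistic.
    """
    L = h.n_snp
    if L < 2:
        raise InsufficientInstrumentsError(
            "IVW needs >= 2 instruments; use wald_ratio for a single SNP")
    bx, _, by, se_out = h.arrays()
    beta, se_fe, q = _ivw_core(bx, by, se_out)
    scale = max(1.0, math.sqrt(q / (L - 1))) if random_effects else 1.0
    se = se_fe * scale
    method = "ivw_re" if random_effects else "ivw_fe"
    return MrEstimate.from_beta_se(method, beta, se, L)


def egger(h: HarmonizedSet) -> tuple[MrEstimate, EggerIntercept]:
    """MR-Egger regression: slope (causal estimate) and intercept.

    Rows are oriented so βX_j ≥ 0 (both signs flipped when βX_j < 0;
    ratio estimates are invariant but the intercept is only identified
    under a fixed orientation). Weighted regression βY = α + β·βX with
    weights seY⁻²; SEs carry a multiplicative overdispersion factor
    max(1, √(Q_resid/(L−2))); both p-values from t(L−2).
    """
    L = h.n_snp
    if L < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    bx, _, by, se_out = h.arrays()
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = se_out ** -2.0
    X = np.column_stack([np.ones(L), bx])
    xtwx = X.T @ (w[:, None] * X)
    try:
        cov_unscaled = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        raise ValueError("degenerate design: exposure betas are constant")
    coef = cov_unscaled @ (X.T @ (w * by))
    resid = by - X @ coef
    q_resid = float(np.sum(w * resid ** 2))
    scale2 = max(1.0, q_resid / (L - 2))
    se_a, se_b = np.sqrt(np.diag(cov_unscaled) * scale2)
    df = L - 2
    p_slope = float(2 * stats.t.sf(abs(coef[1] / se_b), df))
    p_int = float(2 * stats.t.sf(abs(coef[0] / se_a), df))
    slope = MrEstimate.from_beta_se("egger", float(coef[1]), float(se_b), L,
                                    pval=p_slope)
    intercept = EggerIntercept(float(coef[0]), float(se_a), p_int)
    return slope, intercept


def _ratio_arrays(bx: np.ndarray, by: np.ndarray, se_out: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates and their first-order inverse variances."""
    r = by / bx
    w = bx ** 2 / se_out ** 2  # 1 / (seY²/βX²)
    return r, w


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios r with weights w (sum 1)."""
    order = np.argsort(r, kind="stable")
    r_s, w_s = r[order], w[order]
    s = np.cumsum(w_s) - w_s / 2
    return float(np.interp(0.5, s, r_s))


def _parametric_bootstrap(bx, se_exp, by, se_out, n_boot, rng):
    """(n_boot, L) draws of (bx*, by*) under the fitted normals."""
    bxs = rng.normal(bx, se_exp, size=(n_boot, bx.size))
    bys = rng.normal(by, se_out, size=(n_boot, by.size))
    return bxs, bys


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Valid as long as instruments carrying at least half of the total
    inverse-variance weight satisfy the MR assumptions.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError(
            "weighted median needs >= 3 instruments")
    bx, se_exp, by, se_out = h.arrays()
    if np.any(bx == 0):
        raise ValueError("zero exposure beta makes a ratio undefined")
    r, w = _ratio_arrays(bx, by, se_out)
    w = w / w.sum()
    est = _weighted_median_point(r, w)
    rng = np.random.default_rng(seed)
    bxs, bys = _parametric_bootstrap(bx, se_exp, by, se_out, n_boot, rng)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        bxk = bxs[k]
        bxk = np.where(bxk == 0, np.finfo(float).tiny, bxk)
        rk, wk = _ratio_arrays(bxk, bys[k], se_out)
        boots[k] = _weighted_median_point(rk, wk / wk.sum())
    se = float(np.std(boots, ddof=1))
    return MrEstimate.from_beta_se("weighted_median", est, se, h.n_snp)


def _mode_point(r: np.ndarray, w: np.ndarray, bandwidth_factor: float
                ) -> float:
    """Argmax of a Gaussian KDE over ratios with kernel weights w.

    Bandwidth h = φ·0.9·min(sd, IQR/1.349)·L^(−1/5), the modified
    Silverman rule; if one spread measure is zero the other is used, and
    if both are zero (all ratios identical) the common ratio is returned.
    """
    L = r.size
    sd = float(np.std(r, ddof=1)) if L > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(r, [75, 25]))) / 1.349
    candidates = [s for s in (sd, iqr) if s > 0]
    if not candidates:
        return float(r[0])
    h = bandwidth_factor * 0.9 * min(candidates) * L ** (-0.2)
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 1000)
    dens = (w[None, :] *
            np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimators(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                    weighted: bool = False, n_boot: int = 1000,
                    seed: int | None = None) -> MrEstimate:
    """Simple or weighted mode-based estimator.

    The simple mode weights every ratio's kernel equally; the weighted
    variant weights each kernel by its normalized inverse-variance
    weight. The SE is 1.4826 × the median absolute deviation of the
    parametric-bootstrap replicates (robust to the mode's discreteness).
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError(
            "mode estimators need >= 3 instruments")
    bx, se_exp, by, se_out = h.arrays()
    if np.any(bx == 0):
        raise ValueError("zero exposure beta makes a ratio undefined")
    r, w_iv = _ratio_arrays(bx, by, se_out)
    L = r.size

    def kernel_weights(w_raw: np.ndarray) -> np.ndarray:
        if weighted:
            return w_raw / w_raw.sum()
        return np.full(L, 1.0 / L)

    est = _mode_point(r, kernel_weights(w_iv), bandwidth_factor)
    rng = np.random.default_rng(seed)
    bxs, bys = _parametric_bootstrap(bx, se_exp, by, se_out, n_boot, rng)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        bxk = np.where(bxs[k] == 0, np.finfo(float).tiny, bxs[k])
        rk, wk = _ratio_arrays(bxk, bys[k], se_out)
        boots[k] = _mode_point(rk, kernel_weights(wk), bandwidth_factor)
    mad = float(np.median(np.abs(boots - np.median(boots))))
    se = 1.4826 * mad
    if se <= 0:  # degenerate bootstrap; fall back to spread
        se = max(float(np.std(boots, ddof=1)), np.finfo(float).tiny)
    method = "weighted_mode" if weighted else "simple_mode"
    return MrEstimate.from_beta_se(method, est, se, L)


def run_all_methods(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None,
                    bandwidth_factor: float = 1.0) -> list[MrEstimate]:
    """The standard method battery for one exposure–outcome pair.

    One instrument → Wald ratio only; two → IVW only; three or more →
    MR-Egger, weighted median, random-effects IVW, simple mode, weighted
    mode, in that fixed row order.
    """
    L = h.n_snp
    if L < 1:
        raise InsufficientInstrumentsError("empty harmonized set")
    if L == 1:
        row = h.data.iloc[0]
        return [wald_ratio(row["beta_exp"], row["se_exp"],
                           row["beta_out"], row["se_out"])]
    if L == 2:
        return [ivw(h, random_effects=True)]
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    slope, _ = egger(h)
    return [
        slope,
        weighted_median(h, n_boot=n_boot, seed=seeds[0]),
        ivw(h, random_effects=True),
        mode_estimators(h, bandwidth_factor, weighted=False,
                        n_boot=n_boot, seed=seeds[1]),
        mode_estimators(h, bandwidth_factor, weighted=True,
                        n_boot=n_boot, seed=seeds[2]),
    ]
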