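"""Heterogeneity, pleiotropy and influence diagnostics.

Covers the standard MR sensitivity battery: Cochran's Q with the Q-based
I² (labelled ``q_i2`` in outputs, to distinguish it from the I²GX
instrument-strength metric, which is not implemented), the MR-Egger
intercept (exposed by :func:`mrlink.uvmr.egger`), the MR-PRESSO
resampling framework (global RSS test, per-SNP outlier tests with
Bonferroni adjustment, optional distortion test), leave-one-out
re-estimation, and a plot-ready funnel export.

All Monte-Carlo p-values use add-one smoothing, (1 + count)/(n_sim + 1),
so they are strictly positive, and are bit-reproducible given
(seed, n_sim).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .sumstats import HarmonizedSet
from .uvmr import MrEstimate, ivw

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "cochran_q",
    "presso",
    "leave_one_out",
    "funnel_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic with its Q-based I²."""

    q: float
    df: int
    pval: float
    i2: float  # percentage in [0, 100]

    @classmethod
    def from_q(cls, q: float, df: int) -> "HeterogeneityResult":
        if q < 0 or df < 1:
            raise ValueError("need q >= 0 and df >= 1")
        pval = float(stats.chi2.sf(q, df))
        i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
        return cls(q=float(q), df=int(df), pval=pval, i2=i2)


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO output: global test, outliers, optional distortion test."""

    rss_obs: float
    global_pval: float
    outlier_indices: frozenset[int]
    per_snp_pvals: tuple[float, ...]  # Bonferroni-adjusted
    n_sim: int
    seed: int | None
    distortion_pval: float | None = None


def cochran_q(h: HarmonizedSet, beta_hat: float) -> HeterogeneityResult:
    """Cochran's Q about a causal estimate.

    Q = Σ seY_j⁻² (βY_j − β̂·βX_j)² on L−1 degrees of freedom; the
    p-value is the upper chi-square tail. I² = max(0, (Q−df)/Q)·100.
    """
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    bx, _, by, se_out = h.arrays()
    q = float(np.sum(se_out ** -2.0 * (by - beta_hat * bx) ** 2))
    return HeterogeneityResult.from_q(q, h.n_snp - 1)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope with each observation left out, vectorized.

    Works on 1-D arrays or (n_sim, L) matrices along the last axis.
    """
    num = (w * bx * by).sum(axis=-1, keepdims=True) - w * bx * by
    den = (w * bx * bx).sum(axis=-1, keepdims=True) - w * bx * bx
    return num / den


def presso(h: HarmonizedSet, n_sim: int = 1000, seed: int | None = None,
           alpha: float = 0.05, distortion: bool = False) -> PressoResult:
    """MR-PRESSO: resampling-based global pleiotropy and outlier tests.

    For each SNP j the leave-one-out fixed-effect IVW slope β̂(−j) gives
    an expected outcome effect β̂(−j)·βX_j; the observed residual sum of
    squares RSS = Σ_j seY_j⁻² (βY_j − β̂(−j)·βX_j)² is compared against
    ``n_sim`` replicates in which βX_j* ~ N(βX_j, seX_j) and
    βY_j* ~ N(β̂(−j)·βX_j, seY_j), with the leave-one-out slopes
    recomputed on each replicate. Per-SNP contributions are tested the
    same way and Bonferroni-multiplied by L; a SNP is an outlier when
    its adjusted p falls below ``alpha``.

    The optional distortion test compares the change in the IVW estimate
    after removing the outliers to the changes from removing random
    subsets of the same size.
    """
    L = h.n_snp
    if L < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a usable resolution")
    bx, se_exp, by, se_out = h.arrays()
    w = se_out ** -2.0

    beta_loo = _loo_slopes(bx, by, w)
    d_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(d_obs.sum())

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, se_exp, size=(n_sim, L))
    by_star = rng.normal(beta_loo * bx, se_out, size=(n_sim, L))
    beta_loo_star = _loo_slopes(bx_star, by_star, w)
    d_star = w * (by_star - beta_loo_star * bx_star) ** 2
    rss_star = d_star.sum(axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    raw_p = (1 + (d_star >= d_obs).sum(axis=0)) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * L)
    outliers = frozenset(int(i) for i in np.flatnonzero(adj_p < alpha))

    distortion_pval = None
    if distortion and outliers:
        k = len(outliers)
        if k < L - 1:
            keep = np.setdiff1d(np.arange(L), np.fromiter(outliers, int))
            beta_all, _, _ = _ivw_fe(bx, by, w)
            beta_wo, _, _ = _ivw_fe(bx[keep], by[keep], w[keep])
            obs_diff = abs(beta_all - beta_wo)
            diffs = np.empty(n_sim)
            for t in range(n_sim):
                drop = rng.choice(L, size=k, replace=False)
                kp = np.setdiff1d(np.arange(L), drop)
                b, _, _ = _ivw_fe(bx[kp], by[kp], w[kp])
                diffs[t] = abs(beta_all - b)
            distortion_pval = float(
                (1 + np.sum(diffs >= obs_diff)) / (n_sim + 1))

    return PressoResult(
        rss_obs=rss_obs, global_pval=global_pval,
        outlier_indices=outliers,
        per_snp_pvals=tuple(float(p) for p in adj_p),
        n_sim=n_sim, seed=seed, distortion_pval=distortion_pval,
    )


def _ivw_fe(bx, by, w):
    den = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / den
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, den ** -0.5, q


def leave_one_out(h: HarmonizedSet) -> pd.DataFrame:
    """Leave-one-out influence table.

    One random-effects IVW per sequentially dropped SNP plus an ``all``
    row; the returned frame carries ``attrs['stable']`` = False when any
    single drop flips the sign of the estimate or moves its p-value
    across 0.05.
    """
    L = h.n_snp
    if L < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    full = ivw(h, random_effects=True)
    rows = []
    stable = True
    for i in range(L):
        sub = HarmonizedSet(h.exposure_id, h.outcome_id,
                            h.data.drop(index=i))
        est = ivw(sub, random_effects=True)
        rows.append({"dropped_snp": h.data["snp"].iloc[i],
                     "beta": est.beta, "se": est.se, "pval": est.pval})
        if np.sign(est.beta) != np.sign(full.beta) or \
                (est.pval < 0.05) != (full.pval < 0.05):
            stable = False
    rows.append({"dropped_snp": "all", "beta": full.beta, "se": full.se,
                 "pval": full.pval})
    out = pd.DataFrame(rows)
    out.attrs["stable"] = stable
    return out


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios with precision 1/se_ratio = |βX|/seY.

    Plot-ready export: a symmetric scatter of ratio against precision
    indicates no small-instrument (publication-bias-like) asymmetry.
    """
    if h.n_snp < 1:
        return pd.DataFrame(columns=["snp", "wald_ratio", "precision"])
    bx, _, by, se_out = h.arrays()
    return pd.DataFrame({
        "snp": h.data["snp"],
        "wald_ratio": by / bx,
        "precision": np.abs(bx) / se_out,
    })


def sensitivity_report(h: HarmonizedSet, beta_hat: float,
                       n_sim: int = 1000, seed: int | None = None,
                       alpha: float = 0.05) -> dict:
    """Bundle Q/I², Egger intercept and the PRESSO global test.

    Convenience wrapper used by the pipeline to build the diagnostics
    columns of a results table.
    """
    from .uvmr import egger  # local import avoids cycle at module load

    het = cochran_q(h, beta_hat)
    out = {
        "q": het.q, "q_df": het.df, "q_pval": het.pval, "q_i2": het.i2,
    }
    if h.n_snp >= 3:
        _, intercept = egger(h)
        out.update(egger_intercept=intercept.intercept,
                   egger_se=intercept.se, egger_pval=intercept.pval)
    else:
        out.update(egger_intercept=np.nan, egger_se=np.nan,
                   egger_pval=np.nan)
    if h.n_snp >= 4:
        pr = presso(h, n_sim=n_sim, seed=seed, alpha=alpha)
        out["presso_global_p"] = pr.global_pval
        out["presso_n_outliers"] = len(pr.outlier_indices)
    else:
        out["presso_global_p"] = np.nan
        out["presso_n_outliers"] = 0
    return out
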