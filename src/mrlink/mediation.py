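"""Two-step mediation MR and multivariable (MVMR) adjustment.

Two-step mediation decomposes a total exposure→outcome effect into the
product-of-coefficients indirect path through one mediator:

    mediated = β1·β2            (exposure→mediator × mediator→outcome)
    direct   = total − mediated (defined by subtraction)
    proportion mediated (%) = 100 · mediated / total

Variances propagate by the first-order delta method with zero
cross-covariances — the three coefficients come from two-sample
contrasts on distinct instrument sets, though the shared outcome GWAS
between step 2 and the total effect makes this an approximation (see the
methods note).

MVMR regresses outcome betas jointly on several exposures' betas
(weights seY⁻², no intercept), giving each exposure's effect conditional
on the others; attenuation of the drug-target effect after conditioning
on a mediator is evidence the mediator carries the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientInstrumentsError,
    SingularDesignError,
    UndefinedProportionError,
)
from .uvmr import MrEstimate

__all__ = [
    "MediationResult",
    "MvmrEstimate",
    "MvmrSet",
    "two_step_mediation",
    "mvmr_ivw",
    "mvmr_harmonize",
    "screen_mediators",
]


@dataclass(frozen=True)
class MediationResult:
    """Product-of-coefficients decomposition for one mediator.

    All effects are on the log(OR) scale for a binary outcome. The
    identity ``mediated + direct == total`` holds to machine precision
    because ``direct`` is defined by subtraction.
    """

    mediator_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    total: float
    se_total: float
    mediated: float
    se_mediated: float
    direct: float
    proportion_pct: float
    proportion_ci: tuple[float, float]
    level: float = 0.95


@dataclass(frozen=True)
class MvmrEstimate:
    """One exposure's effect conditional on the other MVMR exposures."""

    exposure_id: str
    beta: float
    se: float
    pval: float
    n_snp: int


@dataclass
class MvmrSet:
    """Joint harmonized set: per-SNP betas for k exposures, one outcome.

    ``data`` columns: snp, beta_x_<exposure_id> / se_x_<exposure_id> per
    exposure, beta_out, se_out. Instruments are the union of the
    exposures' selected SNPs, all aligned to a shared effect allele.
    """

    exposure_ids: list[str]
    outcome_id: str
    data: pd.DataFrame

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X = np.column_stack([
            self.data[f"beta_x_{e}"].to_numpy(float)
            for e in self.exposure_ids
        ])
        return (X, self.data["beta_out"].to_numpy(float),
                self.data["se_out"].to_numpy(float))


def two_step_mediation(step1: MrEstimate, step2: MrEstimate,
                       total: MrEstimate, mediator_id: str = "",
                       level: float = 0.95) -> MediationResult:
    """Decompose a total effect through one mediator.

    Parameters
    ----------
    step1
        Exposure→mediator estimate (β1).
    step2
        Mediator→outcome estimate (β2), from the mediator's own
        instruments.
    total
        Exposure→outcome estimate; must be nonzero.

    The mediated effect is β1·β2 with delta-method variance
    β1²·se2² + β2²·se1²; the proportion mediated is 100·β1β2/total with
    delta-method variance (100/total)²·var(mediated) +
    (100·mediated/total²)²·var(total), all cross-covariances zero.
    """
    b1, s1 = step1.beta, step1.se
    b2, s2 = step2.beta, step2.se
    bt, st = total.beta, total.se
    if bt == 0:
        raise UndefinedProportionError(
            "proportion mediated undefined for a zero total effect")
    mediated = b1 * b2
    var_med = b1 ** 2 * s2 ** 2 + b2 ** 2 * s1 ** 2
    direct = bt - mediated
    prop = 100.0 * mediated / bt
    var_prop = (100.0 / bt) ** 2 * var_med + \
        (100.0 * mediated / bt ** 2) ** 2 * st ** 2
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var_prop)
    return MediationResult(
        mediator_id=mediator_id,
        beta1=b1, se1=s1, beta2=b2, se2=s2,
        total=bt, se_total=st,
        mediated=mediated, se_mediated=math.sqrt(var_med),
        direct=direct,
        proportion_pct=prop,
        proportion_ci=(prop - half, prop + half),
        level=level,
    )


def mvmr_harmonize(exposures, outcome) -> MvmrSet:
    """Build a joint MVMR set from per-exposure harmonized-style tables.

    ``exposures`` is a list of :class:`mrlink.sumstats.SummaryStatsTable`
    (already instrument-selected); SNPs are the union across exposures,
    restricted to SNPs present in every exposure table and the outcome
    (complete-case — missing exposure betas are not imputed as zero).
    Alleles are aligned to the first exposure's effect allele via
    :func:`mrlink.instruments.harmonize` semantics.
    """
    from .instruments import harmonize  # deferred: avoids import cycle

    first = exposures[0]
    union_ids: list[str] = []
    for t in exposures:
        for s in t.data["snp"]:
            if s not in union_ids:
                union_ids.append(s)
    # complete cases only
    keep = [s for s in union_ids
            if all(s in set(t.data["snp"]) for t in exposures)
            and s in set(outcome.data["snp"])]
    if not keep:
        raise InsufficientInstrumentsError("no shared SNPs across exposures")
    base = first.subset(keep)
    h_out = harmonize(base, outcome)
    frame = h_out.data[["snp", "beta_out", "se_out"]].copy()
    frame[f"beta_x_{first.trait_id}"] = h_out.data["beta_exp"].to_numpy()
    frame[f"se_x_{first.trait_id}"] = h_out.data["se_exp"].to_numpy()
    for t in exposures[1:]:
        h_t = harmonize(base, t)
        aligned = h_t.data.set_index("snp").reindex(frame["snp"])
        frame[f"beta_x_{t.trait_id}"] = aligned["beta_out"].to_numpy()
        frame[f"se_x_{t.trait_id}"] = aligned["se_out"].to_numpy()
    frame = frame.dropna().reset_index(drop=True)
    return MvmrSet([t.trait_id for t in exposures], outcome.trait_id, frame)


def mvmr_ivw(m: MvmrSet) -> list[MvmrEstimate]:
    """Multivariable IVW: weighted multiple regression without intercept.

    βY = Σ_e β_e·βX_e with weights seY⁻²; SEs carry a multiplicative
    overdispersion factor max(1, √(Q_resid/(L−k))) and p-values use the
    normal. Requires L > k + 1 instruments and a full-rank design.
    """
    X, by, se_out = m.design()
    L, k = X.shape
    if L <= k + 1:
        raise InsufficientInstrumentsError(
            f"MVMR with {k} exposures needs more than {k + 1} instruments")
    # an all-zero exposure column carries no information: its conditional
    # effect is exactly null and it is excluded from the fit (rather than
    # making the design singular)
    nonzero = [j for j in range(k) if np.any(X[:, j] != 0)]
    Xf = X[:, nonzero]
    kf = len(nonzero)
    if kf == 0 or np.linalg.matrix_rank(Xf) < kf:
        raise SingularDesignError("exposure beta columns are collinear")
    w = se_out ** -2.0
    xtwx = Xf.T @ (w[:, None] * Xf)
    try:
        cov_unscaled = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        raise SingularDesignError("exposure beta columns are collinear")
    coef = cov_unscaled @ (Xf.T @ (w * by))
    resid = by - Xf @ coef
    q_resid = float(np.sum(w * resid ** 2))
    scale2 = max(1.0, q_resid / (L - kf))
    ses = np.sqrt(np.diag(cov_unscaled) * scale2)
    out = []
    fit_pos = {j: i for i, j in enumerate(nonzero)}
    for j, e in enumerate(m.exposure_ids):
        if j in fit_pos:
            b, s = float(coef[fit_pos[j]]), float(ses[fit_pos[j]])
            p = float(min(1.0, 2 * stats.norm.sf(abs(b / s))))
        else:
            b, s, p = 0.0, math.inf, 1.0
        out.append(MvmrEstimate(exposure_id=e, beta=b, se=s, pval=p,
                                n_snp=L))
    return out


def screen_mediators(step1_results: dict[str, MrEstimate],
                     alpha: float = 0.05,
                     correction: str | None = None) -> dict:
    """Select mediators whose step-1 effect is significant.

    ``correction`` may be None (per-test alpha, the conventional choice
    in this workflow), "bonferroni", or "bh" (Benjamini–Hochberg).
    Returns a dict with ``selected`` (ids, input order preserved),
    ``n_selected``, ``n_positive`` and ``n_negative`` among the selected.
    """
    ids = list(step1_results)
    pvals = np.array([step1_results[i].pval for i in ids])
    m = len(ids)
    if correction is None:
        keep = pvals < alpha
    elif correction == "bonferroni":
        keep = pvals < alpha / m
    elif correction == "bh":
        order = np.argsort(pvals)
        keep = np.zeros(m, bool)
        thresh = alpha * (np.arange(1, m + 1)) / m
        ok = pvals[order] <= thresh
        if ok.any():
            cutoff = np.max(np.flatnonzero(ok))
            keep[order[:cutoff + 1]] = True
    else:
        raise ValueError(f"unknown correction {correction!r}")
    selected = [i for i, k in zip(ids, keep) if k]
    betas = [step1_results[i].beta for i in selected]
    return {
        "selected": selected,
        "n_selected": len(selected),
        "n_positive": sum(b > 0 for b in betas),
        "n_negative": sum(b < 0 for b in betas),
    }
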