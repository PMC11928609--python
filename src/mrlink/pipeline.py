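"""End-to-end workflows chaining selection → harmonization → estimation.

Two entry points mirror the two analysis arms of a drug-target mediation
study:

* :func:`run_uvmr` — one exposure against one outcome: instrument
  selection, harmonization, MR-PRESSO outlier removal, the five-method
  estimator battery, and the sensitivity suite.
* :func:`run_mediation` — step-1 UVMR of the exposure on every candidate
  mediator, significance screening, step-2 UVMR of each surviving
  mediator on the outcome (using the mediator's own instruments),
  product-of-coefficients mediation with delta-method intervals, and an
  MVMR model conditioning the exposure on the top mediator.

Every run writes TSV result tables plus a JSON manifest (input
checksums, config, seeds, per-stage filter counts) so reruns with the
same manifest are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import (
    ConfigurationError,
    EmptyResultError,
    InsufficientInstrumentsError,
)
from .instruments import (
    LdTable,
    SelectionConfig,
    harmonize,
    remove_presso_outliers,
    select_instruments,
)
from .mediation import (
    mvmr_harmonize,
    mvmr_ivw,
    screen_mediators,
    two_step_mediation,
)
from .sensitivity import funnel_data, leave_one_out, presso, sensitivity_report
from .sumstats import HarmonizedSet, SummaryStatsTable, read_sumstats
from .uvmr import ivw, run_all_methods, wald_ratio

logger = logging.getLogger("mrlink")

__all__ = ["RunConfig", "run_uvmr", "run_mediation"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    exposure: str
    outcome: str
    mediators: list[str] = field(default_factory=list)
    ld: str | None = None
    exclusion_list: str | None = None
    gene_region: tuple[str, int, int] | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    alpha: float = 0.05
    screen_correction: str | None = None
    level: float = 0.95
    out_dir: str = "mrlink_out"
    dialect: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sel = raw.pop("selection", {})
        if isinstance(sel, dict):
            if "exclusion_list" in sel:
                sel["exclusion_list"] = frozenset(sel["exclusion_list"])
            sel = SelectionConfig(**sel)
        region = raw.pop("gene_region", None)
        if region is not None:
            region = (str(region[0]), int(region[1]), int(region[2]))
        try:
            cfg = cls(selection=sel, gene_region=region, **raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from None
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("exposure", "outcome"):
            p = getattr(self, name)
            if not p:
                raise ConfigurationError(f"config field {name!r} is required")
            if not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        for p in list(self.mediators) + [self.ld, self.exclusion_list]:
            if p and not Path(p).exists():
                raise ConfigurationError(f"path does not exist: {p}")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]


def _load_exclusions(path: str | None) -> frozenset[str]:
    if not path:
        return frozenset()
    lines = Path(path).read_text().splitlines()
    return frozenset(s.strip() for s in lines if s.strip())


def _estimates_frame(exposure_id: str, outcome_id: str, estimates
                     ) -> pd.DataFrame:
    rows = []
    for e in estimates:
        orr, lo, hi = e.or_ci
        rows.append({
            "exposure": exposure_id, "outcome": outcome_id,
            "method": e.method, "n_snp": e.n_snp, "beta": e.beta,
            "se": e.se, "pval": e.pval, "or": orr, "ci_low": lo,
            "ci_high": hi,
        })
    return pd.DataFrame(rows)


def _prepare_exposure_instruments(cfg: RunConfig
                                  ) -> tuple[SummaryStatsTable, list]:
    exposure = read_sumstats(cfg.exposure, dialect=cfg.dialect)
    sel = cfg.selection
    if cfg.exclusion_list:
        sel = dataclasses.replace(
            sel, exclusion_list=sel.exclusion_list
            | _load_exclusions(cfg.exclusion_list))
    ld = LdTable.from_tsv(cfg.ld) if cfg.ld else None
    kept, prov = select_instruments(exposure, sel, ld, cfg.gene_region)
    if kept.n_snp == 0:
        raise EmptyResultError(
            "no exposure instruments survived selection; removal counts: "
            + json.dumps(Counter(r.reason for r in prov)))
    return kept, prov


def _harmonize_and_clean(kept: SummaryStatsTable, outcome: SummaryStatsTable,
                         prov: list, cfg: RunConfig, presso_seed: int
                         ) -> tuple[HarmonizedSet, dict]:
    h = harmonize(kept, outcome, provenance=prov)
    presso_info: dict = {"applied": False}
    if h.n_snp >= 4:
        pr = presso(h, n_sim=cfg.n_sim, seed=presso_seed, alpha=cfg.alpha)
        presso_info = {"applied": True, "global_pval": pr.global_pval,
                       "n_outliers": len(pr.outlier_indices)}
        if pr.outlier_indices:
            h = remove_presso_outliers(h, pr)
    return h, presso_info


def _one_pair_uvmr(kept, outcome, prov, cfg, seeds) -> dict:
    h, presso_info = _harmonize_and_clean(kept, outcome, prov, cfg, seeds[0])
    estimates = run_all_methods(h, n_boot=cfg.n_boot, seed=seeds[1])
    primary = next((e for e in estimates if e.method in ("ivw_re", "wald_ratio")),
                   estimates[0])
    sens = None
    if h.n_snp >= 2:
        sens = sensitivity_report(h, primary.beta, n_sim=cfg.n_sim,
                                  seed=seeds[2], alpha=cfg.alpha)
    return {"harmonized": h, "estimates": estimates, "primary": primary,
            "sensitivity": sens, "presso": presso_info}


def run_uvmr(cfg: RunConfig) -> dict:
    """Univariable MR of one exposure on one outcome; writes result tables.

    Outputs in ``cfg.out_dir``: estimates.tsv, sensitivity.tsv,
    leave_one_out.tsv, funnel.tsv, manifest.json.
    """
    t0 = time.monotonic()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(cfg.seed, 3)
    kept, prov = _prepare_exposure_instruments(cfg)
    outcome = read_sumstats(cfg.outcome, dialect=cfg.dialect,
                            trait_type="binary")
    res = _one_pair_uvmr(kept, outcome, prov, cfg, seeds)
    h = res["harmonized"]

    est_frame = _estimates_frame(h.exposure_id, h.outcome_id, res["estimates"])
    est_frame.to_csv(out / "estimates.tsv", sep="\t", index=False)
    if res["sensitivity"] is not None:
        sens_frame = pd.DataFrame([{"exposure": h.exposure_id,
                                    "outcome": h.outcome_id,
                                    **res["sensitivity"]}])
        sens_frame.to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    if h.n_snp >= 3:
        leave_one_out(h).to_csv(out / "leave_one_out.tsv", sep="\t",
                                index=False)
    funnel_data(h).to_csv(out / "funnel.tsv", sep="\t", index=False)

    manifest = {
        "tool": {"name": "mrlink", "version": __version__},
        "command": "uvmr",
        "seed": cfg.seed, "stage_seeds": seeds,
        "inputs": {"exposure": _sha256(cfg.exposure),
                   "outcome": _sha256(cfg.outcome)},
        "config": _config_dict(cfg),
        "filter_counts": dict(Counter(r.reason for r in h.provenance)),
        "n_instruments": h.n_snp,
        "presso": res["presso"],
        "beta_scale": "log-odds (binary outcome); quantitative betas "
                      "treated as SD units",
        "runtime_s": round(time.monotonic() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    logger.info("uvmr: %d instruments, primary beta %.4f (%.1fs)",
                h.n_snp, res["primary"].beta, manifest["runtime_s"])
    return res


def _select_mediator_instruments(mediator: SummaryStatsTable, cfg: RunConfig,
                                 ld: LdTable | None):
    """Instrument selection for a mediator GWAS (no cis restriction)."""
    return select_instruments(mediator, cfg.selection, ld, gene_region=None)


def run_mediation(cfg: RunConfig) -> dict:
    """Two-step mediation plus MVMR; writes mediation and MVMR tables.

    Outputs in ``cfg.out_dir``: step1_estimates.tsv, step2_estimates.tsv,
    mediation.tsv, mvmr.tsv, manifest.json. An empty mediation table
    (no mediator survives both screens) is a valid, zero-exit result.
    """
    t0 = time.monotonic()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.mediators:
        raise ConfigurationError("mediation requires at least one mediator table")
    n_med = len(cfg.mediators)
    seeds = _spawn_seeds(cfg.seed, 4 + 2 * n_med)
    ld = LdTable.from_tsv(cfg.ld) if cfg.ld else None

    exposure_kept, exp_prov = _prepare_exposure_instruments(cfg)
    outcome = read_sumstats(cfg.outcome, dialect=cfg.dialect,
                            trait_type="binary")
    exposure_full = read_sumstats(cfg.exposure, dialect=cfg.dialect)

    # total effect: exposure -> outcome
    total_res = _one_pair_uvmr(exposure_kept, outcome, list(exp_prov), cfg,
                               seeds[:3])
    total = total_res["primary"]

    # step 1: exposure -> each mediator, with the exposure's instruments
    mediator_tables: dict[str, SummaryStatsTable] = {}
    step1: dict[str, Any] = {}
    step1_rows = []
    for path in cfg.mediators:
        med = read_sumstats(path, dialect=cfg.dialect)
        mediator_tables[med.trait_id] = med
        try:
            h1 = harmonize(exposure_kept, med, provenance=list(exp_prov))
            est1 = (ivw(h1) if h1.n_snp >= 2 else
                    wald_ratio(*h1.data.iloc[0][["beta_exp", "se_exp",
                                                 "beta_out", "se_out"]]))
        except (EmptyResultError, InsufficientInstrumentsError) as exc:
            logger.warning("step 1 failed for %s: %s", med.trait_id, exc)
            continue
        step1[med.trait_id] = est1
        step1_rows.append(_estimates_frame("exposure", med.trait_id, [est1]))
    pd.concat(step1_rows, ignore_index=True).to_csv(
        out / "step1_estimates.tsv", sep="\t", index=False) if step1_rows \
        else _empty_estimates(out / "step1_estimates.tsv")

    screen = screen_mediators(step1, alpha=cfg.alpha,
                              correction=cfg.screen_correction)
    logger.info("screen: %d/%d mediators pass step 1 (%d up, %d down)",
                screen["n_selected"], len(step1), screen["n_positive"],
                screen["n_negative"])

    # step 2 + mediation per surviving mediator
    step2_rows, mediation_rows = [], []
    step2: dict[str, Any] = {}
    mediations: dict[str, Any] = {}
    for i, med_id in enumerate(screen["selected"]):
        med = mediator_tables[med_id]
        s_presso, s_boot = seeds[4 + 2 * i], seeds[5 + 2 * i]
        try:
            med_kept, med_prov = _select_mediator_instruments(med, cfg, ld)
            if med_kept.n_snp == 0:
                raise EmptyResultError("no instruments for mediator")
            res2 = _one_pair_uvmr(med_kept, outcome, med_prov, cfg,
                                  [s_presso, s_boot, s_presso])
        except (EmptyResultError, InsufficientInstrumentsError) as exc:
            logger.warning("step 2 failed for %s: %s", med_id, exc)
            continue
        est2 = res2["primary"]
        step2[med_id] = res2
        step2_rows.append(_estimates_frame(med_id, "outcome",
                                           res2["estimates"]))
        m = two_step_mediation(step1[med_id], est2, total,
                               mediator_id=med_id, level=cfg.level)
        mediations[med_id] = m
        mediation_rows.append({
            "mediator": med_id, "mediating_effect": m.mediated,
            "direct_effect": m.direct, "total_effect": m.total,
            "proportion_pct": m.proportion_pct,
            "ci_low": m.proportion_ci[0], "ci_high": m.proportion_ci[1],
        })
    if step2_rows:
        pd.concat(step2_rows, ignore_index=True).to_csv(
            out / "step2_estimates.tsv", sep="\t", index=False)
    else:
        _empty_estimates(out / "step2_estimates.tsv")
    med_frame = pd.DataFrame(
        mediation_rows, columns=["mediator", "mediating_effect",
                                 "direct_effect", "total_effect",
                                 "proportion_pct", "ci_low", "ci_high"])
    med_frame.to_csv(out / "mediation.tsv", sep="\t", index=False)
    if not mediation_rows:
        logger.warning("no mediator survived both screens; mediation table "
                       "is empty")

    # MVMR: exposure conditioned on the top mediator (smallest step-2 p)
    mvmr_rows = []
    mvmr_estimates = None
    if step2:
        top = min(step2, key=lambda k: step2[k]["primary"].pval)
        med_full = mediator_tables[top]
        union = list(dict.fromkeys(
            list(exposure_kept.data["snp"])
            + list(step2[top]["harmonized"].data["snp"])))
        try:
            joint = mvmr_harmonize(
                [exposure_full.subset(union), med_full.subset(union)],
                outcome)
            mvmr_estimates = mvmr_ivw(joint)
            for e in mvmr_estimates:
                adj = [x for x in joint.exposure_ids if x != e.exposure_id]
                mvmr_rows.append({
                    "exposure": e.exposure_id,
                    "adjustment": ";".join(adj), "outcome": joint.outcome_id,
                    "beta": e.beta, "se": e.se, "pval": e.pval,
                })
        except (EmptyResultError, InsufficientInstrumentsError) as exc:
            logger.warning("MVMR skipped: %s", exc)
    pd.DataFrame(mvmr_rows, columns=["exposure", "adjustment", "outcome",
                                     "beta", "se", "pval"]).to_csv(
        out / "mvmr.tsv", sep="\t", index=False)

    manifest = {
        "tool": {"name": "mrlink", "version": __version__},
        "command": "mediate",
        "seed": cfg.seed, "stage_seeds": seeds,
        "inputs": {"exposure": _sha256(cfg.exposure),
                   "outcome": _sha256(cfg.outcome),
                   "mediators": {Path(p).name: _sha256(p)
                                 for p in cfg.mediators}},
        "config": _config_dict(cfg),
        "screen": {k: v for k, v in screen.items() if k != "selected"},
        "n_mediation_rows": len(mediation_rows),
        "beta_scale": "log-odds (binary outcome); quantitative betas "
                      "treated as SD units",
        "runtime_s": round(time.monotonic() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return {"total": total, "step1": step1, "step2": step2,
            "screen": screen, "mediation": mediations,
            "mvmr": mvmr_estimates}


def _empty_estimates(path: Path) -> None:
    pd.DataFrame(columns=["exposure", "outcome", "method", "n_snp", "beta",
                          "se", "pval", "or", "ci_low", "ci_high"]
                 ).to_csv(path, sep="\t", index=False)


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["selection"]["exclusion_list"] = sorted(
        d["selection"]["exclusion_list"])
    return d
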