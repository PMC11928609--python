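"""Shared fixtures: small harmonized sets, simulated files, and the
replicated calibration runs reused across estimator-calibration tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrlink import (
    HarmonizedSet,
    ivw,
    null_scenario,
    calibrated_scenario,
    simulate_harmonized_sets,
)
from mrlink.uvmr import egger

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_harmonized(bx, se_exp, by, se_out, exposure_id="exp",
                    outcome_id="out") -> HarmonizedSet:
    """Build a HarmonizedSet from plain arrays (test convenience)."""
    bx = np.asarray(bx, float)
    n = bx.size
    data = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(n)],
        "beta_exp": bx, "se_exp": np.asarray(se_exp, float),
        "beta_out": np.asarray(by, float),
        "se_out": np.asarray(se_out, float),
        "eaf_exp": np.full(n, 0.3), "eaf_out": np.full(n, 0.3),
    })
    return HarmonizedSet(exposure_id, outcome_id, data)


def random_harmonized(seed: int, n: int = 20) -> HarmonizedSet:
    """A generic random instrument set (no causal structure implied)."""
    rng = np.random.default_rng(seed)
    return make_harmonized(
        bx=rng.normal(0.1, 0.05, n),
        se_exp=rng.uniform(0.005, 0.02, n),
        by=rng.normal(0.0, 0.1, n),
        se_out=rng.uniform(0.05, 0.2, n),
    )


@pytest.fixture(scope="session")
def calibrated_replicates():
    """500 seeded calibrated-scenario replicates: per-replicate IVW on the total
    exposure→outcome contrast, plus the shared truth."""
    scenario = calibrated_scenario()
    estimates = []
    truth = None
    for k in range(500):
        sets, truth = simulate_harmonized_sets(scenario, seed=1_000 + k)
        estimates.append(ivw(sets["total"]))
    return estimates, truth


@pytest.fixture(scope="session")
def null_replicates():
    """500 seeded null-scenario replicates: IVW p-values and Egger
    intercept p-values on the total contrast."""
    scenario = null_scenario()
    ivw_p, egger_p = [], []
    for k in range(500):
        sets, _ = simulate_harmonized_sets(scenario, seed=50_000 + k)
        ivw_p.append(ivw(sets["total"]).pval)
        egger_p.append(egger(sets["total"])[1].pval)
    return np.array(ivw_p), np.array(egger_p)


@pytest.fixture()
def triplet_dir(tmp_path):
    """A simulated triplet written to disk (seed 11)."""
    from mrlink import simulate_triplet
    from mrlink.simulate import write_triplet

    scenario = calibrated_scenario(seed=11)
    exposure, mediator, outcome, ld, truth = simulate_triplet(scenario)
    out = tmp_path / "triplet"
    write_triplet(out, exposure, mediator, outcome, ld, truth)
    return out, truth
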