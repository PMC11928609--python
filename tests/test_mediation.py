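"""Two-step mediation decomposition, MVMR and mediator screening."""

import dataclasses
import math

import numpy as np
import pytest

from mrlink import (
    ivw,
    mvmr_harmonize,
    mvmr_ivw,
    calibrated_scenario,
    screen_mediators,
    simulate_harmonized_sets,
    simulate_mediator_battery,
    two_step_mediation,
)
from mrlink.exceptions import (
    SingularDesignError,
    UndefinedProportionError,
)
from mrlink.instruments import harmonize
from mrlink.mediation import MvmrSet
from mrlink.uvmr import MrEstimate

from conftest import make_harmonized

import pandas as pd


def est(beta, se, method="ivw_re", n=10):
    return MrEstimate.from_beta_se(method, beta, se, n)


class TestTwoStepMediation:
    def test_null_mediator_path(self):
        m = two_step_mediation(est(0.0, 0.1), est(0.5, 0.1),
                               est(-0.7, 0.2))
        assert m.mediated == 0.0
        assert m.direct == m.total
        assert m.proportion_pct == 0.0

    def test_decomposition_identity_exact(self):
        """direct = total - mediated holds to machine precision; with
        mediated -0.0730 and total -0.7018 the direct effect is -0.6288."""
        m = two_step_mediation(est(-0.0730, 0.01), est(1.0, 0.2),
                               est(-0.7018, 0.29))
        assert m.mediated == pytest.approx(-0.0730, abs=1e-15)
        assert m.direct == pytest.approx(-0.6288, abs=1e-12)
        assert m.mediated + m.direct == m.total  # exact, by construction

    def test_proportion_from_reported_effects(self):
        m = two_step_mediation(est(-0.0730, 0.01), est(1.0, 0.2),
                               est(-0.7018, 0.29))
        assert m.proportion_pct == pytest.approx(10.40, abs=0.05)

    def test_zero_total_raises(self):
        with pytest.raises(UndefinedProportionError):
            two_step_mediation(est(0.1, 0.1), est(0.1, 0.1),
                               est(1e-300 * 0, 0.1))

    def test_log_scale_consistency(self):
        """Feeding the same effects after an exp/log round trip of the
        ORs leaves the proportion unchanged."""
        b1, b2, bt = -0.0866, 0.7178, -0.7018
        m1 = two_step_mediation(est(b1, 0.016), est(b2, 0.35),
                                est(bt, 0.29))
        m2 = two_step_mediation(
            est(math.log(math.exp(b1)), 0.016),
            est(math.log(math.exp(b2)), 0.35),
            est(math.log(math.exp(bt)), 0.29))
        assert m1.proportion_pct == pytest.approx(m2.proportion_pct)

    def test_delta_ci_matches_monte_carlo_oracle(self):
        """Delta-method interval for the proportion agrees with a
        100,000-draw Monte-Carlo percentile interval (sampling the three
        coefficients from their normals) to within 10% of the interval
        width, on the drug-target effect scale with a well-estimated
        total effect (the regime where the linearization is valid)."""
        b1, s1 = -0.0866, 0.016
        b2, s2 = 0.7178, 0.25
        bt, st = -0.7018, 0.05
        m = two_step_mediation(est(b1, s1), est(b2, s2), est(bt, st))
        rng = np.random.default_rng(123)
        n = 100_000
        props = (100 * rng.normal(b1, s1, n) * rng.normal(b2, s2, n)
                 / rng.normal(bt, st, n))
        mc_lo, mc_hi = np.percentile(props, [2.5, 97.5])
        width = mc_hi - mc_lo
        assert m.proportion_ci[0] == pytest.approx(mc_lo, abs=0.1 * width)
        assert m.proportion_ci[1] == pytest.approx(mc_hi, abs=0.1 * width)


class TestMvmr:
    def _mvmr_set(self, X, by, se_out, ids=("e1", "e2")):
        n, k = X.shape
        data = pd.DataFrame({"snp": [f"rs{i}" for i in range(n)],
                             "beta_out": by, "se_out": se_out})
        for j, e in enumerate(ids):
            data[f"beta_x_{e}"] = X[:, j]
            data[f"se_x_{e}"] = 0.01
        return MvmrSet(list(ids), "out", data)

    def test_matches_normal_equation_oracle(self):
        """Hand-built 4-SNP, 2-exposure system: coefficients equal the
        weighted normal-equation solution."""
        X = np.array([[1.0, 0.5], [2.0, 0.1], [0.5, 1.5], [1.2, 0.7]])
        by = np.array([0.9, 1.5, 1.8, 1.3])
        se_out = np.array([0.5, 0.4, 0.6, 0.5])
        w = se_out ** -2
        oracle = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
        out = mvmr_ivw(self._mvmr_set(X, by, se_out))
        assert out[0].beta == pytest.approx(oracle[0], abs=1e-12)
        assert out[1].beta == pytest.approx(oracle[1], abs=1e-12)

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        X = rng.normal(0.1, 0.05, (12, 2))
        by = rng.normal(0, 0.2, 12)
        se_out = rng.uniform(0.1, 0.3, 12)
        fit = sm.WLS(by, X, weights=se_out ** -2).fit()
        out = mvmr_ivw(self._mvmr_set(X, by, se_out))
        np.testing.assert_allclose([o.beta for o in out], fit.params,
                                   atol=1e-12)

    def test_nested_model_reduces_to_univariable(self):
        """A second exposure with all-zero betas drops out: the first
        exposure's estimate equals its univariable IVW."""
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.15, 10)
        se_out = np.full(10, 0.1)
        by = -0.5 * bx + rng.normal(0, se_out)
        X = np.column_stack([bx, np.zeros(10)])
        out = mvmr_ivw(self._mvmr_set(X, by, se_out))
        h = make_harmonized(bx, np.full(10, 0.01), by, se_out)
        uni = ivw(h, random_effects=True)
        assert out[0].beta == pytest.approx(uni.beta, abs=1e-12)
        assert out[1].beta == 0.0
        assert out[1].pval == 1.0

    def test_collinear_design_raises(self):
        X = np.column_stack([np.ones(6) * 0.1, np.ones(6) * 0.2])
        with pytest.raises(SingularDesignError):
            mvmr_ivw(self._mvmr_set(X, np.zeros(6), np.full(6, 0.1)))

    def test_full_transmission_attenuates_exposure(self):
        """When the mediator fully transmits the exposure effect
        (beta_direct = 0), conditioning on it pulls the exposure's MVMR
        effect toward zero while the univariable total stays negative."""
        # all of the headline total effect flows through the mediator:
        # beta_direct = 0 and beta1*beta2 = ln(0.4957)
        s = dataclasses.replace(
            calibrated_scenario(), beta_direct=0.0,
            beta2=math.log(0.4957) / math.log(0.917))
        cond, total_betas = [], []
        for k in range(40):
            sets, tr = simulate_harmonized_sets(s, seed=600 + k)
            ht, h1 = sets["total"], sets["step1"]
            h2 = sets["step2"]
            # joint design over exposure + mediator instruments
            bx = np.concatenate([ht.data["beta_exp"],
                                 np.zeros(h2.n_snp)])
            bm = np.concatenate([h1.data["beta_out"],
                                 h2.data["beta_exp"]])
            by = np.concatenate([ht.data["beta_out"],
                                 h2.data["beta_out"]])
            se_out = np.concatenate([ht.data["se_out"],
                                     h2.data["se_out"]])
            X = np.column_stack([bx, bm])
            data = pd.DataFrame({
                "snp": [f"rs{i}" for i in range(len(by))],
                "beta_out": by, "se_out": se_out,
                "beta_x_exp": X[:, 0], "se_x_exp": 0.01,
                "beta_x_med": X[:, 1], "se_x_med": 0.01,
            })
            out = mvmr_ivw(MvmrSet(["exp", "med"], "out", data))
            cond.append(out[0].beta)
            total_betas.append(ivw(ht).beta)
        assert np.mean(total_betas) < -0.4  # univariable total negative
        assert abs(np.mean(cond)) < abs(np.mean(total_betas)) / 2


class TestScreening:
    def test_all_nonsignificant_empty(self):
        res = screen_mediators({"m1": est(0.1, 0.3, n=5),
                                "m2": est(-0.1, 0.3, n=5)}, alpha=0.05)
        assert res["selected"] == []

    def test_alpha_one_keeps_all(self):
        res = screen_mediators({"m1": est(0.1, 0.3), "m2": est(-0.1, 0.3)},
                               alpha=1.0)
        assert res["n_selected"] == 2
        assert res["n_positive"] == 1 and res["n_negative"] == 1

    def test_battery_recovery(self):
        """123 simulated metabolite GWASs, 36 with real effects at the
        calibrated effect/SE regime: screening at alpha 0.05 recovers at
        least 90% of the true positives."""
        from mrlink import SelectionConfig, select_instruments

        s = calibrated_scenario()
        exposure, tables, truth = simulate_mediator_battery(s, seed=77)
        assert len(tables) == 123
        assert sum(1 for b in truth.values() if b != 0) == 36
        kept, _ = select_instruments(exposure, SelectionConfig(), None)
        results = {}
        for tid, tbl in tables.items():
            h = harmonize(kept, tbl)
            results[tid] = ivw(h)
        res = screen_mediators(results, alpha=0.05)
        true_pos = {t for t, b in truth.items() if b != 0}
        recovered = true_pos & set(res["selected"])
        assert len(recovered) >= 0.9 * len(true_pos)

    def test_corrections(self):
        results = {f"m{i}": est(0.0 if i else 1.0, 0.1) for i in range(20)}
        none = screen_mediators(results, alpha=0.05)
        bonf = screen_mediators(results, alpha=0.05,
                                correction="bonferroni")
        assert set(bonf["selected"]) <= set(none["selected"])
        with pytest.raises(ValueError):
            screen_mediators(results, correction="holm")
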