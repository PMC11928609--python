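"""Instrument selection cascade, LD clumping and harmonization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mrlink import (
    EmptyResultError,
    LdTable,
    SelectionConfig,
    f_statistic,
    harmonize,
    is_palindromic,
    remove_presso_outliers,
    select_instruments,
)
from mrlink.sensitivity import presso
from mrlink.sumstats import CANONICAL_COLUMNS, SummaryStatsTable

from conftest import make_harmonized


def make_table(rows, trait_id="exp"):
    return SummaryStatsTable(
        trait_id, "quantitative",
        pd.DataFrame(rows, columns=CANONICAL_COLUMNS))


def snp(snp_id, pval=1e-8, beta=0.1, se=0.01, chrom="1", pos=1_000_000,
        ea="A", oa="G", eaf=0.3, n=1000):
    return (snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)


class TestFStatistic:
    def test_null_effect(self):
        assert f_statistic(0.0, 0.1) == 0.0

    def test_direct_arithmetic(self):
        assert f_statistic(0.1, 0.03) == pytest.approx(11.1111, abs=1e-3)

    def test_threshold_equivalence(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.1, 50)
        se = rng.uniform(0.01, 0.1, 50)
        f = f_statistic(beta, se)
        np.testing.assert_array_equal(f > 10,
                                      np.abs(beta / se) > np.sqrt(10))


@pytest.mark.parametrize("ea,oa,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("g", "c", True),
])
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


class TestSelectInstruments:
    def test_pvalue_filter_removes_all(self):
        t = make_table([snp(f"rs{i}", pval=1e-3) for i in range(3)])
        kept, prov = select_instruments(t, SelectionConfig(), None)
        assert kept.n_snp == 0
        assert all(r.reason == "pval" for r in prov)
        assert len(prov) == 3

    def test_clumping_keeps_smaller_p_of_linked_pair(self):
        t = make_table([snp("rs1", pval=1e-8, pos=1_000_000),
                        snp("rs2", pval=1e-6, pos=1_001_000)])
        ld = LdTable({("rs1", "rs2"): 1.0})
        kept, prov = select_instruments(t, SelectionConfig(), ld)
        assert list(kept.data["snp"]) == ["rs1"]
        assert [(r.snp_id, r.reason) for r in prov] == [("rs2", "ld_clump")]

    def test_clean_strong_snps_all_pass(self):
        rows = [snp(f"rs{i}", pval=1e-9, beta=0.1, se=0.01,
                    pos=1_000_000 + 10_000 * i) for i in range(50)]
        t = make_table(rows)
        kept, prov = select_instruments(t, SelectionConfig(), LdTable())
        assert kept.n_snp == 50
        assert prov == []

    def test_weak_instruments_dropped(self):
        # p below threshold but F = 9 < 10
        t = make_table([snp("rs1", pval=1e-9, beta=0.03, se=0.01),
                        snp("rs2", pval=1e-9, beta=0.3, se=0.01)])
        kept, prov = select_instruments(t, SelectionConfig(p_threshold=1.0),
                                        None)
        assert list(kept.data["snp"]) == ["rs2"]
        assert [(r.snp_id, r.reason) for r in prov] == \
            [("rs1", "weak_instrument")]

    def test_cis_window(self):
        t = make_table([snp("rs_in", pos=950_000),
                        snp("rs_out", pos=700_000),
                        snp("rs_chr", pos=950_000, chrom="2")])
        kept, prov = select_instruments(
            t, SelectionConfig(), None,
            gene_region=("1", 1_000_000, 1_100_000))
        assert list(kept.data["snp"]) == ["rs_in"]
        assert {r.snp_id for r in prov} == {"rs_out", "rs_chr"}
        assert all(r.reason == "cis_window" for r in prov)

    def test_maf_and_exclusion_and_palindrome(self):
        t = make_table([
            snp("rs_rare", eaf=0.005),
            snp("rs_conf"),
            snp("rs_pal", ea="A", oa="T"),
            snp("rs_ok"),
        ])
        cfg = SelectionConfig(exclusion_list=frozenset({"rs_conf"}))
        kept, prov = select_instruments(t, cfg, None)
        assert list(kept.data["snp"]) == ["rs_ok"]
        reasons = {r.snp_id: r.reason for r in prov}
        assert reasons == {"rs_rare": "maf", "rs_conf": "exclusion_list",
                           "rs_pal": "palindrome"}

    def test_missing_eaf_warns_unless_strict(self):
        t = make_table([snp("rs1", eaf=np.nan)])
        with pytest.warns(UserWarning, match="lack eaf"):
            kept, _ = select_instruments(t, SelectionConfig(), None)
        assert kept.n_snp == 1
        kept, prov = select_instruments(
            t, SelectionConfig(strict_maf=True), None)
        assert kept.n_snp == 0
        assert prov[0].reason == "maf"

    def test_provenance_partitions_input(self):
        rows = [snp(f"rs{i}", pval=10 ** -(3 + i),
                    pos=1_000_000 + 1000 * i) for i in range(10)]
        rows.append(snp("rs_pal", ea="C", oa="G"))
        t = make_table(rows)
        ld = LdTable({("rs7", "rs8"): 0.9})
        kept, prov = select_instruments(t, SelectionConfig(), ld)
        assert kept.n_snp + len(prov) == t.n_snp
        assert len({r.snp_id for r in prov}) == len(prov)

    def test_deterministic_rerun(self):
        rows = [snp(f"rs{i}", pval=1e-8, pos=1_000_000 + 500 * i)
                for i in range(20)]
        t = make_table(rows)
        ld = LdTable({(f"rs{i}", f"rs{i + 1}"): 0.5 for i in range(19)})
        a = select_instruments(t, SelectionConfig(), ld)
        b = select_instruments(t, SelectionConfig(), ld)
        pd.testing.assert_frame_equal(a[0].data, b[0].data)
        assert a[1] == b[1]

    def test_no_kept_pair_exceeds_r2(self):
        rng = np.random.default_rng(3)
        rows = [snp(f"rs{i}", pval=float(10 ** -rng.uniform(6, 12)),
                    pos=1_000_000 + 200 * i) for i in range(30)]
        t = make_table(rows)
        pairs = {}
        for i in range(30):
            for j in range(i + 1, 30):
                if rng.random() < 0.2:
                    pairs[(f"rs{i}", f"rs{j}")] = float(rng.uniform(0, 1))
        ld = LdTable(pairs)
        cfg = SelectionConfig()
        kept, _ = select_instruments(t, cfg, ld)
        ids = list(kept.data["snp"])
        pos = dict(zip(kept.data["snp"], kept.data["pos"]))
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if abs(pos[a] - pos[b]) <= cfg.ld_window_bp:
                    assert ld.r2(a, b) < cfg.ld_r2


class TestHarmonize:
    def test_same_alleles_identity(self):
        exp = make_table([snp("rs1", beta=0.1)])
        out = make_table([snp("rs1", beta=0.2)], trait_id="out")
        h = harmonize(exp, out)
        assert h.data.loc[0, "beta_out"] == 0.2
        assert h.data.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = make_table([snp("rs1", ea="A", oa="G", beta=0.1)])
        out = make_table([snp("rs1", ea="G", oa="A", beta=0.2, eaf=0.3)],
                         trait_id="out")
        h = harmonize(exp, out)
        assert h.data.loc[0, "beta_out"] == pytest.approx(-0.2)
        assert h.data.loc[0, "eaf_out"] == pytest.approx(0.7)

    def test_incompatible_alleles_dropped(self):
        exp = make_table([snp("rs1", ea="A", oa="G"), snp("rs2")])
        out = make_table([snp("rs1", ea="A", oa="C"), snp("rs2")],
                         trait_id="out")
        h = harmonize(exp, out)
        assert list(h.data["snp"]) == ["rs2"]
        assert [(r.snp_id, r.reason) for r in h.provenance] == \
            [("rs1", "allele_mismatch")]

    def test_missing_in_outcome_logged(self):
        exp = make_table([snp("rs1"), snp("rs2")])
        out = make_table([snp("rs1")], trait_id="out")
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert h.provenance[0].reason == "missing_in_outcome"

    def test_empty_intersection_raises(self):
        exp = make_table([snp("rs1")])
        out = make_table([snp("rs2")], trait_id="out")
        with pytest.raises(EmptyResultError):
            harmonize(exp, out)

    def test_involution_after_alignment(self):
        """Re-harmonizing tables whose alleles already agree is a no-op."""
        exp = make_table([snp("rs1", ea="A", oa="G", beta=0.1),
                          snp("rs2", ea="T", oa="C", beta=-0.2)])
        out = make_table([snp("rs1", ea="G", oa="A", beta=0.2),
                          snp("rs2", ea="T", oa="C", beta=0.4)],
                         trait_id="out")
        h1 = harmonize(exp, out)
        # write the aligned outcome back into a table and harmonize again
        aligned = out.data.copy()
        aligned.loc[0, ["effect_allele", "other_allele"]] = ["A", "G"]
        aligned.loc[0, "beta"] = h1.data.loc[0, "beta_out"]
        aligned.loc[0, "eaf"] = h1.data.loc[0, "eaf_out"]
        out2 = SummaryStatsTable("out", "quantitative", aligned)
        h2 = harmonize(exp, out2)
        pd.testing.assert_frame_equal(h1.data, h2.data)

    def test_exposure_count_partition(self):
        exp = make_table([snp("rs1"), snp("rs2", ea="A", oa="C"),
                          snp("rs3")])
        out = make_table([snp("rs1"), snp("rs2", ea="A", oa="G")],
                         trait_id="out")
        h = harmonize(exp, out)
        assert h.n_snp + len(h.provenance) == exp.n_snp


class TestPressoRemoval:
    def _outlier_set(self, seed=7, n=20):
        rng = np.random.default_rng(seed)
        bx = rng.normal(0.1, 0.02, n)
        se_x = np.full(n, 0.01)
        se_y = np.full(n, 0.05)
        by = 0.5 * bx + rng.normal(0, se_y)
        by[4] += 10 * se_y[4]
        return make_harmonized(bx, se_x, by, se_y)

    def test_no_outliers_is_identity(self):
        h = make_harmonized([0.1, 0.2, 0.15, 0.12],
                            [0.01] * 4,
                            [0.05, 0.1, 0.075, 0.06],
                            [0.05] * 4)
        pr = presso(h, n_sim=200, seed=1)
        assert not pr.outlier_indices
        h2 = remove_presso_outliers(h, pr)
        pd.testing.assert_frame_equal(h2.data, h.data)

    def test_flagged_row_removed_with_provenance(self):
        h = self._outlier_set()
        pr = presso(h, n_sim=1000, seed=2)
        assert 4 in pr.outlier_indices
        h2 = remove_presso_outliers(h, pr)
        assert h2.n_snp == h.n_snp - len(pr.outlier_indices)
        assert "rs5" not in set(h2.data["snp"])
        reasons = [r for r in h2.provenance if r.reason == "presso_outlier"]
        assert len(reasons) == len(pr.outlier_indices)
        # order of survivors preserved
        survivors = [s for s in h.data["snp"] if s != "rs5"]
        assert list(h2.data["snp"])[:len(survivors)] == survivors


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig(ld_r2=0.0)
    with pytest.raises(ValueError):
        SelectionConfig(maf_min=0.7)
    with pytest.raises(ValueError):
        SelectionConfig(p_threshold=-1)
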