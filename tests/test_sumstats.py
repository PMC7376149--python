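"""Summary-statistics I/O, harmonization and orientation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrnet.sumstats import (
    AssociationRecord,
    HarmonizedSet,
    SumstatsError,
    harmonize,
    load_fixture,
    orient_to_decrease,
    read_sumstats,
)

HEADER = "SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\tP\tN\n"


def _write(tmp_path, body, name="ss.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


def _rec(snp="rs1", beta=0.1, a1="A", a2="G", p=0.01, se=0.02, n=1000):
    return AssociationRecord(snp, "1", 100, a1, a2, beta, se, p, n)


class TestReadSumstats:
    def test_reads_instrument_rows_with_paper_typography(self, tmp_path):
        # U+2212 minus signs and mixed-case exponents as found in print
        body = (
            "rs11125529\t2\t54329370\tC\tA\t−0.056\t0.010\t4.48E−08\t37653\n"
            "rs755017\t20\t61892066\tA\tG\t-0.062\t0.011\t6.71e-09\t37113\n"
        )
        recs = read_sumstats(_write(tmp_path, body))
        assert [r.snp_id for r in recs] == ["rs11125529", "rs755017"]
        assert recs[0].beta == pytest.approx(-0.056)
        assert recs[0].p == pytest.approx(4.48e-8)

    def test_header_only_file_warns_and_returns_empty(self, tmp_path):
        with pytest.warns(UserWarning, match="no valid data rows"):
            assert read_sumstats(_write(tmp_path, "")) == []

    def test_zero_se_row_rejected_with_diagnostic(self, tmp_path):
        body = ("rs1\t1\t100\tA\tG\t0.1\t0.0\t0.01\t1000\n"
                "rs2\t1\t200\tA\tG\t0.1\t0.02\t0.01\t1000\n")
        with pytest.warns(UserWarning, match="row 0"):
            recs = read_sumstats(_write(tmp_path, body))
        assert [r.snp_id for r in recs] == ["rs2"]

    def test_non_numeric_beta_raises_naming_row_and_column(self, tmp_path):
        body = "rs1\t1\t100\tA\tG\tnot_a_number\t0.02\t0.01\t1000\n"
        with pytest.raises(SumstatsError, match="row 0.*BETA"):
            read_sumstats(_write(tmp_path, body))

    def test_duplicate_snp_id_is_an_error(self, tmp_path):
        body = ("rs1\t1\t100\tA\tG\t0.1\t0.02\t0.01\t1000\n"
                "rs1\t1\t100\tA\tG\t0.2\t0.02\t0.01\t1000\n")
        with pytest.raises(SumstatsError, match="duplicate"):
            read_sumstats(_write(tmp_path, body))

    def test_missing_mapped_column_is_an_error(self, tmp_path):
        path = _write(tmp_path, "rs1\t1\t100\tA\tG\t0.1\t0.02\t0.01\t1000\n")
        with pytest.raises(SumstatsError, match="EFFECT_SIZE"):
            read_sumstats(path, column_map={"beta": "EFFECT_SIZE"})

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sumstats(tmp_path / "nope.tsv")


class TestAssociationRecord:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se": 0.0},
            {"p": 0.0},
            {"p": 1.5},
            {"n": 0},
            {"a1": "A", "a2": "A"},
            {"a1": ""},
        ],
    )
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(SumstatsError):
            _rec(**kwargs)

    def test_allele_flip_is_an_involution(self):
        r = _rec(beta=-0.3)
        assert r.flip_alleles().flip_alleles() == r
        assert r.flip_alleles().beta == 0.3


class TestHarmonize:
    def test_matching_alleles_pair_directly(self):
        exp = [_rec("rs11125529", -0.056, "C", "A")]
        out = [_rec("rs11125529", -0.007, "C", "A", se=0.020)]
        hs = harmonize(exp, out)
        assert hs.records[0].beta_x == pytest.approx(-0.056)
        assert hs.records[0].beta_y == pytest.approx(-0.007)

    def test_swapped_alleles_flip_outcome_beta(self):
        exp = [_rec("rs1", 0.1, "C", "A")]
        out = [_rec("rs1", 0.05, "A", "C")]
        assert harmonize(exp, out).records[0].beta_y == pytest.approx(-0.05)

    def test_mismatched_allele_pair_dropped_with_warning(self):
        exp = [_rec("rs1", 0.1, "C", "A"), _rec("rs2", 0.1, "C", "A")]
        out = [_rec("rs1", 0.05, "T", "G"), _rec("rs2", 0.05, "C", "A")]
        with pytest.warns(UserWarning, match="allele mismatch"):
            hs = harmonize(exp, out)
        assert hs.snp_ids == ["rs2"]

    def test_palindromic_kept_with_warning_dropped_in_strict_mode(self):
        exp = [_rec("rs1", 0.1, "A", "T"), _rec("rs2", 0.1, "C", "A")]
        out = [_rec("rs1", 0.05, "A", "T"), _rec("rs2", 0.05, "C", "A")]
        with pytest.warns(UserWarning, match="palindromic"):
            assert len(harmonize(exp, out)) == 2
        with pytest.warns(UserWarning, match="palindromic"):
            assert harmonize(exp, out, strict_palindromic=True).snp_ids == ["rs2"]

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(SumstatsError, match="no SNPs shared"):
            harmonize([_rec("rs1")], [_rec("rs2")])

    def test_join_is_stable_under_outcome_reordering(self, ltl_records, als_records):
        a = harmonize(ltl_records, als_records)
        b = harmonize(ltl_records, list(reversed(als_records)))
        assert a.records == b.records


class TestOrientToDecrease:
    def test_fixture_orientation_flips_exposure_sign_only(self, ltl_als):
        d = orient_to_decrease(ltl_als)
        assert d.orientation == "decrease"
        assert d.records[0].beta_x == pytest.approx(0.056)
        assert d.records[0].beta_y == pytest.approx(-0.007)
        assert all(r.beta_x >= 0 for r in d.records)

    def test_idempotent(self, ltl_als_decrease):
        again = orient_to_decrease(ltl_als_decrease)
        assert again.records == ltl_als_decrease.records

    def test_increasing_allele_record_negates_outcome(self):
        hs = HarmonizedSet.from_arrays(["rs1"], [0.05], [0.01], [0.01], [0.02])
        d = orient_to_decrease(hs)
        assert d.records[0].beta_x == pytest.approx(0.05)
        assert d.records[0].beta_y == pytest.approx(-0.01)

    def test_zero_exposure_effect_is_an_error(self):
        hs = HarmonizedSet.from_arrays(["rs1"], [0.0], [0.01], [0.01], [0.02])
        with pytest.raises(ValueError, match="orientation undefined"):
            orient_to_decrease(hs)

    @given(
        bx=st.floats(-1, 1).filter(lambda v: abs(v) > 1e-6),
        by=st.floats(-1, 1, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_ratio_sign_is_negated_by_orientation(self, bx, by):
        """Per-SD-decrease ratio is minus the per-SD-increase ratio."""
        hs = HarmonizedSet.from_arrays(["rs1"], [bx], [0.01], [by], [0.02])
        d = orient_to_decrease(hs)
        r_inc = by / bx
        r_dec = d.records[0].beta_y / d.records[0].beta_x
        assert r_dec == pytest.approx(-r_inc, abs=1e-12)


class TestFixtures:
    def test_instrument_fixture_matches_published_values(self, ltl_als):
        assert len(ltl_als) == 7
        assert ltl_als.snp_ids[0] == "rs11125529"
        assert ltl_als.exposure_label == "LTL"
        by_id = {r.snp_id: r for r in ltl_als.records}
        r = by_id["rs2736100"]
        assert (r.beta_x, r.se_x, r.beta_y, r.se_y) == (-0.078, 0.009, 0.010, 0.014)
        assert np.all(np.array([rec.beta_x for rec in ltl_als.records]) < 0)

    def test_paths_fixture_ldl_row(self, paths_table):
        row = paths_table.query(
            "pop == 'EUR' and mediator == 'LDL' and outcome == 'ALS'"
        ).iloc[0]
        assert (row.a, row.se_a, row.b, row.se_b) == (-0.060, 0.031, -0.110, 0.031)
        assert (row.c, row.se_c) == (0.097, 0.089)

    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError):
            load_fixture("nonexistent")
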