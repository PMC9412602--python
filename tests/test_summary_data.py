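"""Reading, filtering and harmonising summary statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ironmr.summary_data import (
    GwasRecord,
    HarmonisedInstrument,
    LdMatrix,
    SummaryDataError,
    f_statistic,
    filter_weak,
    find_proxy,
    harmonise,
    is_palindromic,
    ld_prune,
    read_summary_table,
    select_instruments,
)

HEADER = "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\n"


def rec(snp="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01, pval=1e-9, **kw):
    return GwasRecord(snp_id=snp, effect_allele=ea, other_allele=oa, eaf=eaf,
                      beta=beta, se=se, pval=pval, **kw)


class TestReadSummaryTable:
    def test_reads_iron_rows(self, tmp_path):
        rows = [
            ("rs1800562", "6", 26093141, "A", "G", 0.067, 0.328, 0.016, 2.72e-97),
            ("rs1799945", "6", 26091179, "C", "T", 0.85, -0.189, 0.01, 1.10e-81),
            ("rs855791", "22", 37462936, "A", "G", 0.446, -0.181, 0.007, 1.32e-139),
            ("rs8177240", "3", 133000000, "T", "G", 0.669, -0.066, 0.007, 6.65e-20),
            ("rs7385804", "7", 100000000, "A", "C", 0.621, 0.064, 0.007, 1.36e-18),
        ]
        path = tmp_path / "iron.tsv"
        path.write_text(HEADER + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        records = read_summary_table(path)
        assert len(records) == 5
        first = records[0]
        assert first.snp_id == "rs1800562"
        assert first.beta == pytest.approx(0.328)
        assert first.se == pytest.approx(0.016)

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(HEADER)
        assert read_summary_table(path) == []

    def test_nonpositive_se_row_rejected_and_logged(self, tmp_path):
        path = tmp_path / "bad_se.tsv"
        path.write_text(HEADER + "rs1\t1\t100\tA\tG\t0.3\t0.1\t0\t1e-9\n")
        records, log = read_summary_table(path, return_log=True)
        assert records == []
        assert len(log) == 1 and log[0][1] == "invalid_record"

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "nocol.tsv"
        path.write_text(
            "snp_id\teffect_allele\tother_allele\teaf\tbeta\tpval\n"
            "rs1\tA\tG\t0.3\t0.1\t1e-9\n"
        )
        with pytest.raises(SummaryDataError, match="'se'"):
            read_summary_table(path)

    def test_unparsable_numeric_reports_line(self, tmp_path):
        path = tmp_path / "badnum.tsv"
        path.write_text(HEADER + "rs1\t1\t100\tA\tG\t0.3\tnot_a_number\t0.01\t1e-9\n")
        with pytest.raises(SummaryDataError, match="line 2"):
            read_summary_table(path)

    def test_dialect_remapping(self, tmp_path):
        path = tmp_path / "alt.tsv"
        path.write_text("rsid\tA1\tA2\tfreq\tb\tstderr\tp\nrs1\tA\tG\t0.3\t0.1\t0.01\t1e-9\n")
        records = read_summary_table(
            path,
            dialect={"snp_id": "rsid", "effect_allele": "A1", "other_allele": "A2",
                     "eaf": "freq", "beta": "b", "se": "stderr", "pval": "p"},
        )
        assert records[0].snp_id == "rs1" and records[0].beta == pytest.approx(0.1)


class TestSelectInstruments:
    def test_strict_inequality_at_threshold(self):
        at = rec(snp="rs_at", pval=5e-8)
        below = rec(snp="rs_below", pval=4.9e-8)
        kept = select_instruments([at, below], 5e-8)
        assert [r.snp_id for r in kept] == ["rs_below"]

    def test_unit_threshold_keeps_everything(self):
        records = [rec(snp=f"rs{i}", pval=p) for i, p in enumerate([0.9, 0.5, 1e-4])]
        assert select_instruments(records, 1.0) == records

    def test_all_fixture_exposure_rows_pass_gwas_threshold(self, fixture_records):
        exposures, _ = fixture_records
        for name, records in exposures.items():
            assert len(select_instruments(records, 5e-8)) == len(records)


class TestLdPrune:
    def test_uncorrelated_pair_both_kept(self):
        a = rec(snp="rs1800562", pval=1e-38)
        b = rec(snp="rs1799945", pval=1e-10)
        ld = LdMatrix({("rs1800562", "rs1799945"): 0.005})
        assert ld_prune([a, b], ld, 0.01) == [a, b]

    def test_perfect_ld_drops_weaker(self):
        strong = rec(snp="rs_strong", pval=1e-30)
        weak = rec(snp="rs_weak", pval=1e-10)
        ld = LdMatrix({("rs_strong", "rs_weak"): 1.0})
        kept = ld_prune([weak, strong], ld, 0.01)
        assert [r.snp_id for r in kept] == ["rs_strong"]

    def test_single_record_always_kept(self):
        only = rec()
        assert ld_prune([only], LdMatrix({}), 0.01) == [only]

    def test_missing_pair_treated_as_unlinked(self):
        a, b = rec(snp="rs_a"), rec(snp="rs_b", pval=1e-8)
        ld = LdMatrix({})
        assert len(ld_prune([a, b], ld, 0.01)) == 2
        assert ("rs_a", "rs_b") in ld.missing_pairs

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(SummaryDataError, match="asymmetric"):
            LdMatrix({("a", "b"): 0.1, ("b", "a"): 0.9})

    def test_kept_set_is_maximal(self, rng):
        # no dropped SNP is below-threshold with every kept SNP
        n = 12
        ids = [f"rs{i}" for i in range(n)]
        records = [rec(snp=s, pval=float(p)) for s, p in zip(ids, rng.uniform(1e-12, 1e-8, n))]
        r2 = {}
        for i in range(n):
            for j in range(i + 1, n):
                r2[(ids[i], ids[j])] = float(rng.uniform(0, 1))
        ld = LdMatrix(r2)
        kept = {r.snp_id for r in ld_prune(records, ld, 0.3)}
        for dropped in set(ids) - kept:
            assert any(ld.r2(dropped, k) >= 0.3 for k in kept)

    def test_commutes_with_p_filter(self, rng):
        n = 10
        ids = [f"rs{i}" for i in range(n)]
        records = [rec(snp=s, pval=float(p)) for s, p in zip(ids, rng.uniform(1e-12, 1e-6, n))]
        ld = LdMatrix(
            {(ids[i], ids[j]): float(rng.uniform(0, 1))
             for i in range(n) for j in range(i + 1, n)}
        )
        thr = 5e-8
        # significant SNPs precede the rest in the greedy order, so pruning
        # before or after the significance filter keeps the same set
        a = ld_prune(select_instruments(records, thr), ld, 0.3)
        b = [r for r in ld_prune(records, ld, 0.3) if r.pval < thr]
        assert a == b


class TestFindProxy:
    def test_unique_candidate_returned(self):
        cand = rec(snp="rs_proxy")
        ld = LdMatrix({("rs_target", "rs_proxy"): 0.95})
        assert find_proxy("rs_target", [cand], ld, 0.8) is cand

    def test_below_minimum_gives_none(self):
        cand = rec(snp="rs_proxy")
        ld = LdMatrix({("rs_target", "rs_proxy"): 0.7})
        assert find_proxy("rs_target", [cand], ld, 0.8) is None

    def test_tie_broken_by_pvalue_in_either_order(self):
        a = rec(snp="rs_a", pval=1e-10)
        b = rec(snp="rs_b", pval=1e-5)
        ld = LdMatrix({("rs_t", "rs_a"): 0.9, ("rs_t", "rs_b"): 0.9})
        assert find_proxy("rs_t", [a, b], ld, 0.8) is a
        assert find_proxy("rs_t", [b, a], ld, 0.8) is a

    def test_exact_pvalue_tie_broken_lexicographically(self):
        a = rec(snp="rs_a", pval=1e-5)
        b = rec(snp="rs_b", pval=1e-5)
        ld = LdMatrix({("rs_t", "rs_a"): 0.9, ("rs_t", "rs_b"): 0.9})
        assert find_proxy("rs_t", [b, a], ld, 0.8) is a


@pytest.mark.parametrize(
    "ea,oa,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("C", "T", False), ("AT", "A", False)],
)
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(rec(ea=ea, oa=oa)) is expected


class TestHarmonise:
    def test_already_aligned_copies_outcome(self):
        exp = rec(ea="A", oa="G", beta=0.2)
        out = rec(ea="A", oa="G", beta=-1.7e-4, se=2.7e-4, eaf=0.07)
        inst = harmonise(exp, out)
        assert inst.beta_y == pytest.approx(-1.7e-4)
        assert inst.eaf_y == pytest.approx(0.07)

    def test_swapped_alleles_negate_beta_and_flip_eaf(self):
        exp = rec(ea="A", oa="G", beta=0.2)
        out = rec(ea="G", oa="A", beta=-1.7e-4, se=2.7e-4, eaf=0.93)
        inst = harmonise(exp, out)
        assert inst.beta_y == pytest.approx(1.7e-4)
        assert inst.eaf_y == pytest.approx(0.07)

    def test_strand_complement_then_align(self):
        exp = rec(ea="A", oa="G", beta=0.2)
        out = rec(ea="T", oa="C", beta=3e-4, eaf=0.3)      # complement of A/G
        inst = harmonise(exp, out)
        assert inst.beta_y == pytest.approx(3e-4)
        out_swapped = rec(ea="C", oa="T", beta=3e-4, eaf=0.3)
        inst2 = harmonise(exp, out_swapped)
        assert inst2.beta_y == pytest.approx(-3e-4)

    def test_palindromic_dropped_when_requested(self):
        exp = rec(ea="A", oa="T")
        out = rec(ea="A", oa="T")
        log = []
        assert harmonise(exp, out, drop_palindromic=True, log=log) is None
        assert log[0][1] == "palindromic"
        assert harmonise(exp, out, drop_palindromic=False) is not None

    def test_incompatible_alleles_logged_none(self):
        exp = rec(ea="A", oa="G")
        out = rec(ea="A", oa="C")
        log = []
        assert harmonise(exp, out, log=log) is None
        assert log[0][1] == "incompatible_alleles"

    @settings(derandomize=True, max_examples=50)
    @given(
        beta_y=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
        swap=st.booleans(),
    )
    def test_involution_under_allele_swap(self, beta_y, eaf, swap):
        """Swapping outcome alleles and negating its beta leaves the
        harmonised instrument unchanged."""
        exp = rec(ea="A", oa="G", beta=0.2)
        out = rec(ea="A" if not swap else "G", oa="G" if not swap else "A",
                  beta=beta_y, eaf=eaf, pval=0.5)
        base = harmonise(exp, out)
        flipped = GwasRecord(
            snp_id=out.snp_id, effect_allele=out.other_allele,
            other_allele=out.effect_allele, eaf=1.0 - out.eaf, beta=-out.beta,
            se=out.se, pval=out.pval,
        )
        again = harmonise(exp, flipped)
        assert again.beta_y == pytest.approx(base.beta_y)
        assert again.eaf_y == pytest.approx(base.eaf_y)


class TestFStatistic:
    def test_ferritin_rs855791_oracle(self):
        # direct arithmetic: (0.055/0.007)^2
        r = rec(snp="rs855791", beta=-0.055, se=0.007)
        assert f_statistic(r) == pytest.approx((0.055 / 0.007) ** 2)
        assert f_statistic(r) == pytest.approx(61.7, rel=5e-3)

    def test_beta_equal_se_gives_unity(self):
        assert f_statistic(rec(beta=0.01, se=0.01)) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(beta=st.floats(0.001, 1.0), se=st.floats(0.001, 1.0), c=st.floats(0.01, 100))
    def test_scale_invariance(self, beta, se, c):
        a = f_statistic(rec(beta=beta, se=se))
        b = f_statistic(rec(beta=c * beta, se=c * se))
        assert b == pytest.approx(a, rel=1e-9)

    def test_r2_form_requires_sample_size(self):
        r = rec(beta=0.2, se=0.016, eaf=0.067)
        with pytest.raises(SummaryDataError, match="sample size"):
            f_statistic(r, method="r2")
        f = f_statistic(r, method="r2", n=48972)
        assert f > 10

    def test_all_fixture_instruments_strong(self, fixture_sets):
        fs = [i.f_stat for s in fixture_sets.values() for i in s]
        assert min(fs) >= 10


class TestFilterWeak:
    def test_boundary_instrument_removed(self):
        inst = HarmonisedInstrument(snp_id="rs_w", beta_x=0.1, se_x=0.032, beta_y=0.0,
                                    se_y=0.01, f_stat=9.99)
        out = filter_weak([inst], f_min=10)
        assert out.instruments == []
        assert out.selection_log[0][1] == "weak_instrument"

    def test_zero_threshold_is_identity(self, fixture_sets):
        for name, instruments in fixture_sets.items():
            assert filter_weak(instruments, f_min=0).instruments == instruments

    def test_fixture_ferritin_all_retained(self, fixture_sets):
        out = filter_weak(fixture_sets["ferritin"], f_min=10, exposure_name="ferritin")
        assert len(out.instruments) == 6
        assert out.selection_log == []


def test_record_validation_rejects_bad_fields():
    with pytest.raises(SummaryDataError):
        rec(se=-1.0)
    with pytest.raises(SummaryDataError):
        rec(eaf=1.5)
    with pytest.raises(SummaryDataError):
        rec(pval=0.0)
    with pytest.raises(SummaryDataError):
        rec(ea="A", oa="A")
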