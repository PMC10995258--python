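import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bdhla.association import (
    CarrierTable,
    CohortTable,
    SubjectRecord,
    associate_all,
    bonferroni,
    carrier_table,
    fisher_exact_two_sided,
    locus_test_counts,
    odds_ratio,
    pearson_chi2_p,
    phenotype_association,
    trunc3,
    wald_p,
    woolf_ci,
)
from bdhla.caller import GenotypeCall
from bdhla.nomenclature import parse_allele_name


def _subject(sid, group, genotypes, phenotypes=None):
    calls = {}
    for gene, pair in genotypes.items():
        a1, a2 = (parse_allele_name(p) for p in pair)
        calls[gene] = GenotypeCall(
            sample_id=sid,
            gene=gene,
            alleles=(a1,) if a1 == a2 else (a1, a2),
            zygosity="homozygous" if a1 == a2 else "heterozygous",
        )
    return SubjectRecord(
        subject_id=sid, group=group, genotypes=calls, phenotypes=phenotypes or {}
    )


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((7, 49, 8, 184), 3.285),   # A*26:01:01 carriers
            ((5, 51, 3, 189), 6.176),   # B*39:01:01 / B*51:01:02
            ((10, 10, 10, 10), 1.0),
        ],
    )
    def test_published_values(self, cells, expected):
        assert trunc3(odds_ratio(CarrierTable(*cells))) == pytest.approx(expected)

    def test_zero_cells_undefined(self):
        for cells in [(0, 56, 8, 184), (7, 49, 0, 192), (56, 0, 8, 184)]:
            assert odds_ratio(CarrierTable(*cells)) is None

    @given(
        st.tuples(*[st.integers(1, 50)] * 4).map(lambda t: CarrierTable(*t))
    )
    def test_row_swap_inverts(self, t):
        swapped = CarrierTable(a=t.c, b=t.d, c=t.a, d=t.b)
        assert odds_ratio(t) * odds_ratio(swapped) == pytest.approx(1.0)


class TestWoolfCI:
    @pytest.mark.parametrize(
        "cells,lo,hi",
        [
            ((7, 49, 8, 184), 1.135, 9.504),
            ((12, 44, 16, 176), 1.323, 6.798),   # DQB1*05:03:01
        ],
    )
    def test_published_values(self, cells, lo, hi):
        got = woolf_ci(CarrierTable(*cells))
        assert trunc3(got[0]) == pytest.approx(lo)
        assert trunc3(got[1]) == pytest.approx(hi)

    def test_symmetric_table_symmetric_on_log_scale(self):
        lo, hi = woolf_ci(CarrierTable(10, 10, 10, 10))
        assert lo * hi == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(1, 40)] * 4).map(lambda t: CarrierTable(*t)))
    def test_contains_or_and_shrinks_with_counts(self, t):
        orr = odds_ratio(t)
        lo, hi = woolf_ci(t)
        assert lo <= orr <= hi
        big = CarrierTable(t.a * 4, t.b * 4, t.c * 4, t.d * 4)
        blo, bhi = woolf_ci(big)
        assert (bhi / blo) < (hi / lo)  # interval shrinks as cells scale up

    def test_zero_cell_undefined(self):
        assert woolf_ci(CarrierTable(0, 56, 8, 184)) is None


class TestWaldP:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((7, 49, 8, 184), 0.028),
            ((5, 51, 3, 189), 0.015),
        ],
    )
    def test_published_values(self, cells, expected):
        assert round(wald_p(CarrierTable(*cells)), 3) == pytest.approx(expected)

    def test_null_table_gives_p_one(self):
        assert wald_p(CarrierTable(10, 10, 10, 10)) == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(1, 40)] * 4).map(lambda t: CarrierTable(*t)))
    def test_consistent_with_ci(self, t):
        """p < 0.05 iff the 95% CI excludes 1 (same z statistic)."""
        p = wald_p(t)
        lo, hi = woolf_ci(t)
        excludes_one = lo > 1.0 or hi < 1.0
        if abs(p - 0.05) > 1e-9:
            assert (p < 0.05) == excludes_one


class TestFisher:
    def test_derived_examples(self, fisher_oracle):
        assert fisher_exact_two_sided(CarrierTable(5, 51, 3, 189)) == pytest.approx(
            0.0160, abs=5e-5
        )
        assert fisher_exact_two_sided(CarrierTable(7, 49, 8, 184)) == pytest.approx(
            0.0486, abs=5e-5
        )
        assert fisher_oracle(7, 49, 8, 184) == pytest.approx(
            fisher_exact_two_sided(CarrierTable(7, 49, 8, 184)), abs=1e-12
        )

    def test_zero_margin_gives_one(self):
        assert fisher_exact_two_sided(CarrierTable(0, 10, 0, 20)) == 1.0

    @given(cells=st.tuples(*[st.integers(0, 15)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        from conftest import fisher_two_sided_enumeration

        if sum(cells) == 0:
            return
        t = CarrierTable(*cells)
        assert fisher_exact_two_sided(t) == pytest.approx(
            fisher_two_sided_enumeration(*cells), abs=1e-12
        )


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.027, 49, 1.323), (0.028, 34, 0.952), (0.008, 16, 0.128)],
    )
    def test_published_pc_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_uncapped_and_validated(self):
        assert bonferroni(0.5, 10) == 5.0
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


@pytest.fixture
def small_cohort():
    subjects = [
        _subject("c1", "case", {"A": ("A*26:01:01", "A*11:01:01")}, {"ocular": True}),
        _subject("c2", "case", {"A": ("A*26:01:01", "A*26:01:01")}, {"ocular": True}),
        _subject("c3", "case", {"A": ("A*24:02:01", "A*11:01:01")}, {"ocular": False}),
        _subject("k1", "control", {"A": ("A*26:01:01", "A*24:02:01")}),
        _subject("k2", "control", {"A": ("A*11:01:01", "A*11:01:01")}),
        _subject("k3", "control", {"A": ("A*24:02:01", "A*24:02:01")}),
        _subject("k4", "control", {"A": ("A*11:01:01", "A*24:02:01")}),
    ]
    return CohortTable(subjects=subjects)


class TestCohortOperations:
    def test_carrier_table_counts_homozygote_once(self, small_cohort):
        t = carrier_table(small_cohort, parse_allele_name("A*26:01:01"), 3)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 3)

    def test_carrier_table_resolution_collapses(self, small_cohort):
        # at 1 field, A*26 carriers are the same subjects
        t = carrier_table(small_cohort, parse_allele_name("A*26:01:01"), 1)
        assert (t.a, t.c) == (2, 1)

    def test_absent_gene_raises(self, small_cohort):
        with pytest.raises(KeyError):
            carrier_table(small_cohort, parse_allele_name("B*51:01:01"), 3)

    def test_uncarried_allele_empty_cells(self, small_cohort):
        t = carrier_table(small_cohort, parse_allele_name("A*33:03:01"), 3)
        assert (t.a, t.c) == (0, 0)

    def test_locus_test_counts(self, small_cohort):
        assert locus_test_counts(small_cohort, 3) == {"A": 3}
        extra = CohortTable(
            subjects=small_cohort.subjects
            + [_subject("k5", "control", {"A": ("A*33:03:01", "A*11:01:01")})]
        )
        assert locus_test_counts(extra, 3) == {"A": 4}

    def test_associate_all_rows_and_order(self, small_cohort):
        results = associate_all(small_cohort, 3)
        assert len(results) == 3
        assert [str(r.allele) for r in results] == sorted(
            str(r.allele) for r in results
        )
        assert all(r.m == 3 for r in results)

    def test_associate_all_empty_cohort(self):
        assert associate_all(CohortTable(subjects=[]), 3) == []

    def test_phenotype_association(self, small_cohort):
        res = phenotype_association(
            small_cohort, "ocular", parse_allele_name("A*26:01:01"),
            comparator="case_subset_vs_control",
        )
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (2, 0, 1, 3)
        with pytest.raises(ValueError, match="no cases positive"):
            phenotype_association(
                small_cohort, "pathergy", parse_allele_name("A*26:01:01")
            )

    def test_phenotype_all_positive_case_vs_case_errors(self, small_cohort):
        cohort = CohortTable(
            subjects=[
                s if s.group == "control"
                else _subject(s.subject_id, "case",
                              {"A": tuple(str(a) for a in s.genotypes["A"].allele_pair())},
                              {"ocular": True})
                for s in small_cohort.subjects
            ]
        )
        with pytest.raises(ValueError, match="empty reference"):
            phenotype_association(
                cohort, "ocular", parse_allele_name("A*26:01:01"),
                comparator="case_vs_case",
            )


def test_sex_distribution_chi_square():
    """Cases 23M/33F vs controls 111M/81F: Pearson chi-square without
    continuity correction gives the published 0.027."""
    assert round(pearson_chi2_p([[23, 33], [111, 81]]), 3) == 0.027
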