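"""Spectrum collapsing and chi-squared comparisons, checked against
hand-written expected-count oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cftrfreq.catalog import CohortAF, CohortEntry, PatientSpectrum
from cftrfreq.compare import (
    ContingencyTable,
    build_table,
    chi_square_test,
    collapse_spectrum,
    compare_cohort_afs,
    compare_total_burden,
    total_burden,
)
from cftrfreq.exceptions import (
    DegenerateTableError,
    MissingDataError,
    ValidationError,
)

VARIANTS_12 = [
    "F508del", "CFTRdele2,3(21kb)", "L138ins", "W1282X", "1677delTA",
    "3849+10kbC>T", "E92K", "2143delT", "G542X", "2184insA", "N1303K", "R334W",
]


def pearson_oracle(counts, yates=False):
    """Brute-force Pearson statistic from first principles."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    dev = np.abs(counts - expected)
    if yates:
        dev = np.clip(dev - 0.5, 0.0, None)
    return float((dev**2 / expected).sum())


def yates_2x2_closed_form(a, b, c, d):
    """N(|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


small_tables = st.integers(2, 3).flatmap(
    lambda r: st.integers(2, 3).flatmap(
        lambda c: st.lists(
            st.lists(st.integers(0, 16), min_size=c, max_size=c),
            min_size=r,
            max_size=r,
        )
    )
).map(np.array).filter(
    lambda t: (t.sum(axis=1) > 0).all() and (t.sum(axis=0) > 0).all() and t.sum() <= 50
)


class TestCollapse:
    def test_pools_remainder_conserving_alleles(self):
        s = PatientSpectrum("r", 65, dict(zip("abcde", [100, 20, 5, 3, 2])))
        out = collapse_spectrum(s, ["a", "b"])
        assert out.counts == {"a": 100, "b": 20, "other": 10}
        assert out.total_alleles == s.total_alleles

    def test_yugra_two_group_collapse(self, spectra_by_region):
        out = collapse_spectrum(spectra_by_region["Yugra region"], ["F508del"])
        assert out.counts == {"F508del": 43, "other": 65}

    def test_keep_everything_leaves_empty_other(self):
        s = PatientSpectrum("r", 5, {"a": 4, "b": 6})
        assert collapse_spectrum(s, ["a", "b"]).counts["other"] == 0

    def test_other_is_reserved(self):
        s = PatientSpectrum("r", 5, {"a": 10})
        with pytest.raises(ValidationError, match="reserved"):
            collapse_spectrum(s, ["other"])

    @given(
        counts=st.lists(st.integers(0, 100), min_size=2, max_size=6),
        n_keep=st.integers(1, 3),
    )
    def test_total_alleles_invariant(self, counts, n_keep):
        s = PatientSpectrum("r", max(1, sum(counts) // 2), {f"v{i}": c for i, c in enumerate(counts)})
        keep = [f"v{i}" for i in range(n_keep)]
        assert collapse_spectrum(s, keep).total_alleles == s.total_alleles


class TestBuildTable:
    def test_district_rows_and_central_counts(self, district_spectra):
        districts = district_spectra[1:]  # drop the national aggregate
        table = build_table(districts, ["F508del", "CFTRdele2,3(21kb)"])
        assert table.counts.shape == (8, 3)
        central = table.counts[table.row_labels.index("Central Federal District")]
        assert central.tolist() == [839, 126, 645]

    def test_two_region_table(self, spectra_by_region):
        table = build_table(
            [spectra_by_region["St.Petersburg"], spectra_by_region["Yugra region"]],
            ["F508del", "CFTRdele2,3(21kb)"],
        )
        assert table.counts.tolist() == [[2846, 178, 1799], [43, 5, 60]]

    def test_duplicate_region_rejected(self):
        s = PatientSpectrum("r", 5, {"a": 4, "b": 6})
        with pytest.raises(ValidationError, match="duplicate"):
            build_table([s, s], ["a"])


class TestChiSquare:
    def test_district_heterogeneity_statistic(self, district_spectra):
        table = build_table(district_spectra[1:], ["F508del", "CFTRdele2,3(21kb)"])
        res = chi_square_test(table, yates="auto")
        assert res.df == 14
        assert not res.yates_applied
        assert res.statistic == pytest.approx(pearson_oracle(table.counts), abs=1e-10)
        assert res.statistic == pytest.approx(197.55, rel=0.01)
        assert res.p_value < 2.2e-16

    def test_2x2_auto_applies_yates(self, spectra_by_region):
        table = build_table(
            [spectra_by_region["St.Petersburg"], spectra_by_region["Yugra region"]],
            ["F508del"],
        )
        res = chi_square_test(table, yates="auto")
        assert res.yates_applied and res.df == 1
        assert res.statistic == pytest.approx(
            yates_2x2_closed_form(2846, 1977, 43, 65), abs=1e-10
        )
        off = chi_square_test(table, yates="off")
        assert off.statistic > res.statistic  # the correction only shrinks it

    def test_identical_proportions_give_zero(self):
        table = ContingencyTable(["a", "b"], ["x", "y"], np.array([[10, 30], [20, 60]]))
        assert chi_square_test(table, yates="off").statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_column_margin_is_degenerate(self):
        table = ContingencyTable(["a", "b"], ["x", "y"], np.array([[0, 5], [0, 7]]))
        with pytest.raises(DegenerateTableError):
            chi_square_test(table)

    def test_yates_on_non_2x2_rejected(self):
        table = ContingencyTable(["a", "b"], ["x", "y", "z"], np.array([[1, 2, 3], [4, 5, 6]]))
        with pytest.raises(ValidationError, match="2x2"):
            chi_square_test(table, yates="on")

    def test_min_expected_reported_and_warned(self, caplog):
        table = ContingencyTable(["a", "b"], ["x", "y"], np.array([[1, 9], [2, 8]]))
        with caplog.at_level("WARNING", logger="cftrfreq.compare"):
            res = chi_square_test(table, yates="off")
        assert res.min_expected == pytest.approx(1.5)
        assert any("expected" in r.message for r in caplog.records)

    @given(table=small_tables)
    def test_oracle_equivalence_small_tables(self, table):
        ct = ContingencyTable(
            [f"r{i}" for i in range(table.shape[0])],
            [f"c{j}" for j in range(table.shape[1])],
            table,
        )
        res = chi_square_test(ct, yates="off")
        assert res.statistic == pytest.approx(pearson_oracle(table), abs=1e-10)
        assert res.df == (table.shape[0] - 1) * (table.shape[1] - 1)
        if table.shape == (2, 2):
            corrected = chi_square_test(ct, yates="on")
            assert corrected.statistic == pytest.approx(
                pearson_oracle(table, yates=True), abs=1e-10
            )

    @given(table=small_tables)
    def test_permutation_invariance(self, table):
        ct = lambda t: ContingencyTable(
            [f"r{i}" for i in range(t.shape[0])],
            [f"c{j}" for j in range(t.shape[1])],
            t,
        )
        base = chi_square_test(ct(table), yates="off").statistic
        flipped_rows = chi_square_test(ct(table[::-1]), yates="off").statistic
        flipped_cols = chi_square_test(ct(table[:, ::-1]), yates="off").statistic
        assert base == pytest.approx(flipped_rows, abs=1e-12)
        assert base == pytest.approx(flipped_cols, abs=1e-12)

    def test_p_decreases_as_statistic_grows_at_fixed_df(self):
        weak = ContingencyTable(["a", "b"], ["x", "y"], np.array([[12, 10], [10, 12]]))
        strong = ContingencyTable(["a", "b"], ["x", "y"], np.array([[20, 2], [2, 20]]))
        rw, rs = (chi_square_test(t, yates="off") for t in (weak, strong))
        assert rs.statistic > rw.statistic
        assert rs.p_value < rw.p_value


class TestCohortComparisons:
    def test_total_burden_reference_columns(self, cohorts):
        assert total_burden(cohorts["RUSeq"], VARIANTS_12) == (pytest.approx(0.0117), 2)
        assert total_burden(cohorts["InfertileMen"], VARIANTS_12) == (pytest.approx(0.0240), 0)
        assert total_burden(cohorts["Petrova"], VARIANTS_12) == (pytest.approx(0.0072), 7)

    def test_all_missing_cohort(self):
        cohort = CohortAF("empty", 10, {v: CohortEntry(af=None) for v in VARIANTS_12})
        assert total_burden(cohort, VARIANTS_12) == (0.0, 12)

    def test_f508del_enrichment_in_infertile_men(self, cohorts):
        # counts reconstructed as round(af * AN): 183/12066 vs 27/3342
        res = compare_cohort_afs(cohorts["InfertileMen"], cohorts["RUSeq"], "F508del", yates="off")
        oracle = pearson_oracle([[183, 12066 - 183], [27, 3342 - 27]])
        assert res.statistic == pytest.approx(oracle, abs=1e-10)
        assert res.statistic == pytest.approx(9.8, abs=0.05)
        assert res.df == 1

    def test_identical_cohorts_give_zero(self, cohorts):
        res = compare_cohort_afs(cohorts["RUSeq"], cohorts["RUSeq"], "F508del", yates="off")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_missing_variant_never_treated_as_zero(self, cohorts):
        with pytest.raises(MissingDataError, match="MISSING"):
            compare_cohort_afs(cohorts["RUSeq"], cohorts["InfertileMen"], "CFTRdele2,3(21kb)")

    def test_absent_in_both_is_degenerate_not_zero(self):
        a = CohortAF("a", 50, {"v": CohortEntry(af=0.0)})
        b = CohortAF("b", 60, {"v": CohortEntry(af=0.0)})
        with pytest.raises(DegenerateTableError):
            compare_cohort_afs(a, b, "v", yates="off")

    def test_three_cohort_burden_comparison_runs(self, cohorts):
        # the published three-way comparison is not reconstructable exactly
        # from rounded AFs; the generic k x 2 test must still be well-formed
        res = compare_total_burden(
            [cohorts["InfertileMen"], cohorts["NonCBAVD"], cohorts["RUSeq"]],
            VARIANTS_12,
            yates="off",
        )
        assert res.df == 2
        assert res.statistic > 0
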