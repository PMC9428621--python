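"""ROR, Woolf interval, Pearson chi-square and signal screening.

The oracle for the three statistics is an independent direct-formula
implementation (plus scipy.stats.chi2_contingency for the p-value), kept
here in the test suite and written against the textbook definitions, not
against the package code.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pvsignal import (
    ClassMap,
    SignalStatus,
    TwoByTwoTable,
    ZeroCellError,
    classify_signal,
    pearson_chi2_p,
    ror,
    screen_tables,
    signal_table_to_frame,
    woolf_ci,
)
from pvsignal.disproportionality import SignalRow, round_half_up, round_sig
from pvsignal.reference import (
    full_screen_counts,
    reference_class_map,
    N_CASES,
    N_REPORTS,
)
from pvsignal.simulate import tabulate_virtual


# --- independent oracle -----------------------------------------------------

def oracle_ror(a, b, c, d):
    return (a * d) / (b * c)


def oracle_woolf(a, b, c, d, level=0.95):
    z = stats.norm.ppf((1 + level) / 2)
    lor = math.log(a * d / (b * c))
    s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(lor - z * s), math.exp(lor + z * s)


def oracle_p(a, b, c, d):
    res = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return res.pvalue


def table(a, b, c, d):
    return TwoByTwoTable(a, b, c, d, class_id="X", term_code="T")


def test_statistics_agree_with_direct_formula_oracle():
    """1,000 random tables with cells in [1, 1e6]: 1e-9 relative agreement."""
    rng = np.random.default_rng(20240917)
    cells = rng.integers(1, 10**6, size=(1000, 4))
    for a, b, c, d in cells:
        t = table(int(a), int(b), int(c), int(d))
        assert ror(t) == pytest.approx(oracle_ror(a, b, c, d), rel=1e-9)
        lo, hi = woolf_ci(t)
        olo, ohi = oracle_woolf(a, b, c, d)
        assert lo == pytest.approx(olo, rel=1e-9)
        assert hi == pytest.approx(ohi, rel=1e-9)
        assert pearson_chi2_p(t) == pytest.approx(oracle_p(a, b, c, d), rel=1e-9, abs=1e-300)


class TestPointEstimates:
    @pytest.mark.parametrize(
        "cells, expected_2dp",
        [
            ((8, 116283, 62, 29642384), 32.89),  # HPV row of the published screen
            ((3, 26614, 67, 29732053), 50.02),   # yellow fever row
            ((4, 2881218, 66, 26877449), 0.57),  # COVID-19 row
            ((1, 1, 1, 1), 1.0),
        ],
    )
    def test_published_rors_reproduce(self, cells, expected_2dp):
        assert round_half_up(ror(table(*cells)), 2) == expected_2dp

    @pytest.mark.parametrize(
        "cells, lo, hi",
        [
            ((8, 116283, 62, 29642384), 15.8, 68.7),
            ((8, 70006, 62, 29688661), 26.2, 114.3),
        ],
    )
    def test_published_intervals_reproduce(self, cells, lo, hi):
        clo, chi_ = woolf_ci(table(*cells))
        assert round_sig(clo, 3) == lo
        # compare at the printed precision of each bound
        ndig = len(str(hi).split(".")[1])
        assert round_half_up(chi_, ndig) == hi

    def test_published_p_values(self):
        assert pearson_chi2_p(table(4, 2881218, 66, 26877449)) == pytest.approx(
            0.262, abs=5e-4
        )
        assert pearson_chi2_p(table(8, 116283, 62, 29642384)) < 0.001
        assert pearson_chi2_p(table(1, 1, 1, 1)) == 1.0

    def test_level_out_of_range_rejected(self):
        from pvsignal import ParameterError

        with pytest.raises(ParameterError):
            woolf_ci(table(1, 1, 1, 1), level=1.5)


class TestZeroCells:
    def test_zero_cell_refused_by_default(self):
        with pytest.raises(ZeroCellError, match="b"):
            ror(table(1, 0, 1, 1))
        with pytest.raises(ZeroCellError):
            woolf_ci(table(1, 1, 0, 1))
        with pytest.raises(ZeroCellError):
            pearson_chi2_p(table(0, 0, 1, 1))

    def test_haldane_anscombe_flag(self):
        t = table(2, 0, 5, 10)
        assert ror(t, zero_correction=True) == pytest.approx(
            (2.5 * 10.5) / (0.5 * 5.5)
        )
        lo, hi = woolf_ci(t, zero_correction=True)
        assert 0 < lo < hi


small_cells = st.integers(1, 10**6)


@given(a=small_cells, b=small_cells, c=small_cells, d=small_cells)
@settings(max_examples=100, deadline=None)
def test_interval_log_symmetry_and_ordering(a, b, c, d):
    """low*high == ror^2 (log symmetry) and low <= ror <= high."""
    t = table(a, b, c, d)
    r = ror(t)
    lo, hi = woolf_ci(t)
    assert lo * hi == pytest.approx(r * r, rel=1e-9)
    assert lo <= r <= hi


@given(a=small_cells, b=small_cells, c=small_cells, d=small_cells)
@settings(max_examples=100, deadline=None)
def test_transpose_and_reciprocity_symmetries(a, b, c, d):
    t = table(a, b, c, d)
    # b<->c exchange leaves ror unchanged; p invariant under transpose
    assert ror(table(a, c, b, d)) == pytest.approx(ror(t), rel=1e-12)
    assert pearson_chi2_p(table(a, c, b, d)) == pytest.approx(
        pearson_chi2_p(t), rel=1e-9, abs=1e-300
    )
    # swapping exposure labels inverts the ror and mirrors the interval
    swapped = table(c, d, a, b)
    assert ror(swapped) == pytest.approx(1 / ror(t), rel=1e-9)
    lo, hi = woolf_ci(t)
    slo, shi = woolf_ci(swapped)
    assert slo == pytest.approx(1 / hi, rel=1e-9)
    assert shi == pytest.approx(1 / lo, rel=1e-9)


@given(a=st.integers(3, 500), b=small_cells, c=st.integers(1, 500), d=small_cells)
@settings(max_examples=100, deadline=None)
def test_signal_iff_wald_test_significant(a, b, c, d):
    """CI excludes 1 exactly when the two-sided Wald z-test on ln ROR
    rejects at the same level (Pearson p may differ; not asserted)."""
    t = table(a, b, c, d)
    lo, hi = woolf_ci(t)
    z = abs(math.log(ror(t))) / math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    wald_p = 2 * stats.norm.sf(z)
    assert (lo > 1 or hi < 1) == (wald_p < 0.05)


class TestScreening:
    @pytest.fixture
    def screen(self):
        tables = tabulate_virtual(full_screen_counts(), N_CASES, N_REPORTS)
        return screen_tables(tables, reference_class_map())

    def test_minimum_count_filter(self, screen):
        included = {r.class_id for r in screen.included_rows}
        assert len(included) == 8
        for r in screen.rows:
            assert r.included == (r.table.a >= 3)
            if not r.included:
                assert r.ror is None and r.p_value is None

    def test_filter_monotonicity_at_min_one(self):
        tables = tabulate_virtual(full_screen_counts(), N_CASES, N_REPORTS)
        st1 = screen_tables(tables, reference_class_map(), min_exposed_cases=1)
        assert len(st1.included_rows) == 13

    def test_rows_sorted_by_descending_ror_included_first(self, screen):
        rors = [r.ror for r in screen.rows if r.included]
        assert rors == sorted(rors, reverse=True)
        flags = [r.included for r in screen.rows]
        assert flags == sorted(flags, reverse=True)

    def test_signal_implies_included_and_covid_not_flagged(self, screen):
        by_id = {r.class_id: r for r in screen.rows}
        assert by_id["HPV"].signal and by_id["DTP_POLIO"].signal
        assert not by_id["COVID19"].signal
        assert len(screen.signals) == 7
        for r in screen.rows:
            if r.signal:
                assert r.included

    def test_classification(self, screen):
        by_id = {r.class_id: r for r in screen.rows}
        assert classify_signal(by_id["HPV"]) is SignalStatus.signal
        assert classify_signal(by_id["COVID19"]) is SignalStatus.no_signal
        assert classify_signal(by_id["RABIES"]) is SignalStatus.not_evaluable

    def test_display_rounding(self, screen):
        df = signal_table_to_frame(screen, rounded=True).set_index("class_id")
        assert df.loc["HPV", "ror"] == 32.89
        assert df.loc["HPV", "ci_low"] == 15.8
        assert df.loc["HPV", "ci_high"] == 68.7
        assert df.loc["HPV", "p_value"] == "<0.001"
        assert df.loc["COVID19", "p_value"] == "0.262"

    def test_writers(self, screen, tmp_path):
        import json

        from pvsignal import write_signal_table

        write_signal_table(screen, tmp_path / "s.csv", "csv")
        write_signal_table(screen, tmp_path / "s.json", "json")
        doc = json.loads((tmp_path / "s.json").read_text())
        assert doc["n_cases"] == N_CASES
        assert len(doc["rows"]) == 13
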