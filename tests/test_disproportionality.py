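import math

import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from conftest import make_report
from pvsignal.cleaning import CaseSeries, DrugSynonymMap, deduplicate
from pvsignal.disproportionality import (
    ContingencyTable,
    DegenerateTableError,
    DisproportionalityResult,
    SignalCriteria,
    build_contingency,
    classify_signal,
    compute_ror,
    implied_ror_from_ci,
    run_analysis,
)

CRIZOTINIB = DrugSynonymMap.build("CRIZOTINIB", ["XALKORI"])
PLEURAL = ["Pleural effusion"]

cells = st.integers(min_value=1, max_value=2000)


def hand_series():
    """8 reports: 2 drug+event, 1 drug only, 2 event only, 3 neither."""
    reports = [
        make_report("P1", drugs=[("CRIZOTINIB", "PS")], reactions=["Pleural effusion"]),
        make_report("P2", drugs=[("XALKORI", "PS")], reactions=["Pleural effusion", "Nausea"]),
        make_report("P3", drugs=[("CRIZOTINIB", "PS")], reactions=["Nausea"]),
        make_report("P4", drugs=[("ASPIRIN", "PS")], reactions=["Pleural effusion"]),
        make_report("P5", drugs=[("IBUPROFEN", "PS")], reactions=["pleural effusion"]),
        make_report("P6", drugs=[("ASPIRIN", "PS")], reactions=["Headache"]),
        make_report("P7", drugs=[("METFORMIN", "PS")], reactions=["Nausea"]),
        make_report("P8", drugs=[("XALKORI", "SS")], reactions=["Pleural effusion"]),
    ]
    return deduplicate(reports)


class TestBuildContingency:
    def test_hand_enumerated_counts(self):
        # P8 matches the drug only via a non-PS role: background under restriction
        table = build_contingency(hand_series(), CRIZOTINIB, PLEURAL)
        assert (table.a, table.b, table.c, table.d) == (2, 1, 3, 2)

    def test_relaxing_ps_restriction_moves_one_report_into_a(self):
        restricted = build_contingency(hand_series(), CRIZOTINIB, PLEURAL, True)
        relaxed = build_contingency(hand_series(), CRIZOTINIB, PLEURAL, False)
        assert relaxed.a == restricted.a + 1
        assert relaxed.c == restricted.c - 1

    def test_no_drug_matches_partitions_into_background(self):
        series = hand_series()
        table = build_contingency(series, DrugSynonymMap.build("GEFITINIB"), PLEURAL)
        assert table.a == table.b == 0
        assert table.c + table.d == len(series)

    def test_every_report_lands_in_exactly_one_cell(self):
        table = build_contingency(hand_series(), CRIZOTINIB, PLEURAL)
        assert table.total == len(hand_series())

    def test_empty_series_yields_all_zero_table(self):
        table = build_contingency(CaseSeries([]), CRIZOTINIB, PLEURAL)
        assert (table.a, table.b, table.c, table.d) == (0, 0, 0, 0)


class TestComputeRor:
    def test_symmetric_table_is_null(self):
        res = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert res.ror == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high
        assert not res.is_signal

    def test_frozen_example_against_direct_formula(self):
        # (20, 80, 100, 9800): ROR (a*d)/(b*c) = 24.5 exactly
        res = compute_ror(ContingencyTable(20, 80, 100, 9800))
        assert res.ror == pytest.approx(24.5)
        assert res.se_log == pytest.approx(
            math.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 9800)
        )
        assert res.ci_low == pytest.approx(14.448136, abs=1e-5)
        assert res.ci_high == pytest.approx(41.545152, abs=1e-5)
        assert res.n_reports == 20 and not res.corrected

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_matches_independent_odds_ratio_implementation(self, a, b, c, d):
        res = compute_ror(ContingencyTable(a, b, c, d))
        oracle = Table2x2([[a, b], [c, d]])
        assert res.ror == pytest.approx(oracle.oddsratio, rel=1e-12)
        lo, hi = oracle.oddsratio_confint(0.05)
        assert res.ci_low == pytest.approx(lo, rel=1e-4)
        assert res.ci_high == pytest.approx(hi, rel=1e-4)

    def test_zero_cell_gets_haldane_anscombe_correction(self):
        res = compute_ror(ContingencyTable(0, 10, 10, 100))
        assert res.corrected
        assert res.ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))
        assert res.n_reports == 0  # reported count stays the uncorrected cell

    def test_all_zero_table_raises_instead_of_nan(self):
        with pytest.raises(DegenerateTableError):
            compute_ror(ContingencyTable(0, 0, 0, 0))

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_antisymmetry_under_exposure_swap(self, a, b, c, d):
        res = compute_ror(ContingencyTable(a, b, c, d))
        swapped = compute_ror(ContingencyTable(b, a, d, c))
        assert swapped.ror == pytest.approx(1 / res.ror, rel=1e-12)
        assert swapped.ci_low == pytest.approx(1 / res.ci_high, rel=1e-9)
        assert swapped.ci_high == pytest.approx(1 / res.ci_low, rel=1e-9)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_log_symmetry_and_result_invariants(self, a, b, c, d):
        res = compute_ror(ContingencyTable(a, b, c, d))
        assert math.sqrt(res.ci_low * res.ci_high) == pytest.approx(res.ror, rel=1e-9)
        assert res.ci_low <= res.ror <= res.ci_high
        assert res.n_reports == a

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestImpliedRor:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [(6.60, 9.12, 7.76), (7.10, 11.41, 9.00), (1.0, 1.0, 1.0)],
    )
    def test_geometric_mean_recovers_point_estimate(self, lo, hi, expected):
        assert round(implied_ror_from_ci(lo, hi), 2) == expected

    def test_nonpositive_or_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            implied_ror_from_ci(0.0, 2.0)
        with pytest.raises(ValueError):
            implied_ror_from_ci(3.0, 2.0)


def result(ror, ci_low, n):
    return DisproportionalityResult(
        ror=ror, se_log=0.1, ci_low=ci_low, ci_high=ror * 2, n_reports=n,
        corrected=False, is_signal=False,
    )


class TestClassifySignal:
    @pytest.mark.parametrize(
        "ror, ci_low, n, expected",
        [
            (4.76, 3.80, 76, True),
            (1.0, 0.8, 1000, False),
            (2.5, 0.95, 50, False),  # CI criterion fails alone
            (2.5, 1.5, 9, False),  # report-count criterion fails alone
            (2.00, 1.5, 50, False),  # "exceeding 2.00" is strict
            (2.01, 1.00, 50, False),  # "above 1.00" is strict
            (2.01, 1.01, 10, True),  # "at least ten" is inclusive
        ],
    )
    def test_tri_criteria_rule(self, ror, ci_low, n, expected):
        assert classify_signal(result(ror, ci_low, n)) is expected

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            SignalCriteria(min_ror=0.0)


class TestRunAnalysis:
    DRUGS = [CRIZOTINIB, DrugSynonymMap.build("CERITINIB", ["ZYKADIA"])]
    EVENTS = {"Pleural effusion": PLEURAL, "Pericardial effusion": ["Pericardial effusion"]}

    def test_one_row_per_drug_event_pair_in_given_order(self):
        frame = run_analysis(hand_series(), self.DRUGS, self.EVENTS)
        assert len(frame) == 4
        assert list(frame.drug) == ["CRIZOTINIB", "CRIZOTINIB", "CERITINIB", "CERITINIB"]
        assert list(frame.event)[:2] == ["Pleural effusion", "Pericardial effusion"]

    def test_empty_drug_list_yields_empty_table(self):
        frame = run_analysis(hand_series(), [], self.EVENTS)
        assert frame.empty

    def test_rows_agree_with_standalone_computation(self):
        frame = run_analysis(hand_series(), self.DRUGS, self.EVENTS)
        table = build_contingency(hand_series(), CRIZOTINIB, PLEURAL)
        res = compute_ror(table)
        row = frame.iloc[0]
        assert row.ror == pytest.approx(res.ror)
        assert row.n_reports == res.n_reports

    def test_degenerate_series_reports_per_row_errors_without_aborting(self):
        frame = run_analysis(CaseSeries([]), self.DRUGS, self.EVENTS)
        assert len(frame) == 4
        assert (frame.error != "").all()
        assert (~frame.is_signal).all()
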