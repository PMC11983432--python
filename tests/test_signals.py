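"""Disproportionality statistics: frozen values, identities, degenerate tables."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrsignal import (
    BcpnnPrior,
    ContingencyTable,
    DrugRole,
    ReportSet,
    bcpnn_ic,
    build_contingency,
    compute_signal_statistics,
    contingency_tables,
    detect_signals,
    ebgm,
    make_report,
    prr,
    ror,
)
from adrsignal.signals import UnknownEventError

T = ContingencyTable(20, 80, 100, 900)

cells = st.integers(min_value=1, max_value=200)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


class TestRor:
    def test_symmetric_table_is_unity(self):
        assert ror(ContingencyTable(10, 10, 10, 10)).estimate == 1.0

    def test_frozen_point_estimate(self):
        assert ror(T).estimate == pytest.approx((20 * 900) / (80 * 100))

    def test_frozen_ci_low_closed_form(self):
        # independently evaluated closed form, not the implementation's path
        expected = math.exp(
            math.log(2.25) - 1.96 * math.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 900)
        )
        assert ror(T).ci_low == pytest.approx(expected, rel=1e-12)

    def test_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        t22 = sm.Table2x2([[T.a, T.b], [T.c, T.d]])
        res = ror(T)
        assert res.estimate == pytest.approx(t22.oddsratio, rel=1e-12)
        low, high = t22.oddsratio_confint(0.05)
        # statsmodels uses the normal quantile 1.959964 rather than 1.96
        assert res.ci_low == pytest.approx(low, rel=1e-4)
        assert res.ci_high == pytest.approx(high, rel=1e-4)

    def test_zero_a_gives_zero_estimate(self):
        res = ror(ContingencyTable(0, 10, 10, 10))
        assert res.estimate == 0.0
        assert 0 < res.ci_low < res.ci_high < math.inf  # CI from +0.5-corrected cells
        bare = ror(ContingencyTable(0, 10, 10, 10), continuity=False)
        assert (bare.estimate, bare.ci_low, bare.ci_high) == (0.0, 0.0, math.inf)

    def test_zero_cell_ci_uses_continuity_correction(self):
        t = ContingencyTable(5, 0, 10, 100)
        res = ror(t)
        assert math.isinf(res.estimate)  # point estimate on raw counts
        assert 0 < res.ci_low < res.ci_high < math.inf  # CI from +0.5 cells

    def test_correction_disabled_degenerate(self):
        res = ror(ContingencyTable(0, 10, 10, 10), continuity=False)
        assert (res.ci_low, res.ci_high) == (0.0, math.inf)


class TestPrr:
    def test_frozen_point_estimate(self):
        assert prr(T).estimate == pytest.approx((20 / 100) / (100 / 1000))

    def test_homogeneous_table_is_unity(self):
        # a/(a+b) == c/(c+d) by construction
        assert prr(ContingencyTable(5, 45, 20, 180)).estimate == pytest.approx(1.0)

    def test_zero_c_reports_infinite(self):
        assert math.isinf(prr(ContingencyTable(5, 5, 0, 10)).estimate)

    @settings(max_examples=100, derandomize=True)
    @given(t=tables)
    def test_positive_halfwidth(self, t):
        res = prr(t)
        assert res.ci_low < res.estimate < res.ci_high


class TestBcpnn:
    def test_exact_independence_ic_zero(self):
        assert bcpnn_ic(ContingencyTable(100, 900, 9900, 89100)).ic == 0.0

    def test_frozen_ic(self):
        assert bcpnn_ic(T).ic == pytest.approx(math.log2(11 / 6), rel=1e-12)

    def test_a_zero_keeps_shrunk_estimates_finite(self):
        res = bcpnn_ic(ContingencyTable(0, 10, 10, 100))
        assert res.ic == -math.inf
        assert math.isfinite(res.e_ic) and math.isfinite(res.ic025)

    def test_e_ic_approaches_ic_for_large_tables(self):
        k = 1000
        small = ContingencyTable(2, 8, 10, 90)
        big = ContingencyTable(2 * k, 8 * k, 10 * k, 90 * k)
        assert bcpnn_ic(big).ic == pytest.approx(bcpnn_ic(small).ic, rel=1e-12)
        assert bcpnn_ic(big).e_ic == pytest.approx(bcpnn_ic(small).ic, abs=5e-3)

    def test_prior_requires_positive_hyperparameters(self):
        with pytest.raises(ValueError):
            BcpnnPrior(alpha1=0.0)

    @settings(max_examples=100, derandomize=True)
    @given(t=tables)
    def test_ic025_below_e_ic(self, t):
        res = bcpnn_ic(t)
        assert res.ic025 < res.e_ic


class TestEbgm:
    def test_frozen_observed_expected(self):
        assert ebgm(T).estimate == pytest.approx(11 / 6, rel=1e-12)

    def test_exact_independence_is_unity(self):
        assert ebgm(ContingencyTable(100, 900, 9900, 89100)).estimate == 1.0

    @settings(max_examples=200, derandomize=True)
    @given(t=tables)
    def test_two_to_the_ic_equals_ebgm(self, t):
        """Both formulas reduce to the observed/expected ratio."""
        assert 2.0 ** bcpnn_ic(t).ic == pytest.approx(ebgm(t).estimate, rel=1e-12)

    def test_ebgm05_is_ci_lower_bound(self):
        res = ebgm(T)
        assert res.ebgm05 == res.ci_low
        assert res.ci_low < res.estimate < res.ci_high


@settings(max_examples=100, derandomize=True)
@given(
    a=st.integers(min_value=1, max_value=100),
    bump=st.integers(min_value=1, max_value=50),
    b=cells,
    c=cells,
    d=cells,
)
def test_ratio_estimates_increase_in_a(a, bump, b, c, d):
    """Holding b, c, d fixed, more co-reports means larger ROR and PRR."""
    lo = ContingencyTable(a, b, c, d)
    hi = ContingencyTable(a + bump, b, c, d)
    assert ror(hi).estimate > ror(lo).estimate
    assert prr(hi).estimate > prr(lo).estimate


@settings(max_examples=100, derandomize=True)
@given(
    a=st.integers(min_value=1, max_value=100),
    bump=st.integers(min_value=1, max_value=50),
    extra_b=st.integers(min_value=0, max_value=100),
    extra_c=st.integers(min_value=0, max_value=100),
    d=cells,
)
def test_observed_expected_increases_in_a_when_margins_dominate(
    a, bump, extra_b, extra_c, d
):
    """IC and EBGM are observed/expected ratios: raising a also raises both
    margins, so monotonicity in a holds once b and c stay at least as large
    as a (the regime of any real signal-screening table, where a drug's
    co-reports are a minority of its reports and of the event's reports)."""
    b = a + bump + extra_b
    c = a + bump + extra_c
    lo = ContingencyTable(a, b, c, d)
    hi = ContingencyTable(a + bump, b, c, d)
    assert bcpnn_ic(hi).ic > bcpnn_ic(lo).ic
    assert ebgm(hi).estimate > ebgm(lo).estimate


class TestBuildContingency:
    def test_pt_selector(self, small_universe, toy_map):
        t = build_contingency(small_universe, "drugA", "Rash", toy_map)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_soc_selector_matching_one_pt(self, small_universe, toy_map):
        t = build_contingency(small_universe, "drugA", "Skin disorders", toy_map)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_soc_selector_covering_all_pts(self, small_universe):
        from adrsignal import MeddraMap

        broad = MeddraMap(
            pt_to_soc={"Rash": "Everything", "Nausea": "Everything"},
            soc_list=("Everything",),
        )
        t = build_contingency(small_universe, "drugA", "Everything", broad)
        assert (t.a, t.b, t.c, t.d) == (2, 0, 2, 0)

    def test_unknown_selector_raises(self, small_universe, toy_map):
        with pytest.raises(UnknownEventError):
            build_contingency(small_universe, "drugA", "No such event", toy_map)

    def test_cells_partition_universe(self, mixed_reports, toy_map):
        for event in ("Rash", "Nausea", "Dizziness"):
            t = build_contingency(mixed_reports, "drugA", event, toy_map)
            assert t.n == len(mixed_reports)


class TestDetectSignals:
    def test_absent_drug_empty(self, small_universe, toy_map):
        assert detect_signals(small_universe, "ghost", toy_map) == []

    def test_tables_match_build_contingency(self, mixed_reports, toy_map):
        tables = contingency_tables(mixed_reports, "drugA", toy_map)
        for event, t in tables.items():
            assert t == build_contingency(mixed_reports, "drugA", event, toy_map)

    def test_single_drug_universe_degenerate_without_crash(self, toy_map):
        rs = ReportSet(
            reports=[
                make_report("s1", [("only", DrugRole.PRIMARY_SUSPECT)], ["Rash"]),
                make_report("s2", [("only", DrugRole.PRIMARY_SUSPECT)], ["Nausea"]),
            ]
        )
        results = dict(detect_signals(rs, "only", toy_map))
        for stats in results.values():
            assert stats.degenerate
            assert not stats.is_signal("any")

    def test_min_a_floor_suppresses_flags(self):
        t = ContingencyTable(2, 8, 10, 980)
        flagged = compute_signal_statistics(t)
        floored = compute_signal_statistics(t, min_a=3)
        assert flagged.flag_ror
        assert not floored.is_signal("any")

    def test_soc_level_aggregation(self, mixed_reports, toy_map):
        tables = contingency_tables(mixed_reports, "drugA", toy_map, level="soc")
        # drugA reports: r1 (Rash+Nausea -> Skin, GI), r4 (Diarrhoea -> GI)
        assert tables["Gastrointestinal disorders"].a == 2
        assert tables["Skin disorders"].a == 1
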