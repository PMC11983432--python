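"""Descriptive profiling: percentages, denominators, partitions, ordering."""

import pytest

from adrsignal import (
    DrugRole,
    ReportSet,
    Seriousness,
    demographic_table,
    make_report,
    percent,
    serious_ae_rates,
    soc_profile,
    top_pt_table,
)
from adrsignal.profiles import StratifiedCounts


def _reports(*specs):
    out = []
    for i, spec in enumerate(specs):
        out.append(make_report(f"p{i}", [("drugA", DrugRole.PRIMARY_SUSPECT)], **spec))
    return ReportSet(reports=out)


class TestPercent:
    @pytest.mark.parametrize(
        "count,denom,expected",
        [
            (10_751, 11_452, 93.88),  # large-count half-up
            (999, 2_269, 44.03),
            (1, 8, 12.5),
            (1, 800, 0.13),  # 0.125 rounds up, not banker's
            (0, 7, 0.0),
        ],
    )
    def test_half_up_two_decimals(self, count, denom, expected):
        assert percent(count, denom) == expected

    def test_zero_denominator_is_missing(self):
        assert percent(3, 0) is None


class TestDemographics:
    def test_sex_distribution(self):
        rs = _reports(
            {"reactions": ["Rash"], "sex": "male"},
            {"reactions": ["Rash"], "sex": "male"},
            {"reactions": ["Rash"], "sex": "female"},
            {"reactions": ["Rash"]},
        )
        table = demographic_table(rs, "sex")
        assert table.as_dict() == {"Male": 2, "Female": 1, "Unknown": 1}
        assert dict(zip(table.stratum_labels, table.percentages)) == {
            "Male": 50.0,
            "Female": 25.0,
            "Unknown": 25.0,
        }

    def test_year_axis_bins_before_2017(self):
        rs = _reports(
            {"reactions": ["Rash"], "year": 2012},
            {"reactions": ["Rash"], "year": 2016},
            {"reactions": ["Rash"], "year": 2020},
            {"reactions": ["Rash"]},
        )
        table = demographic_table(rs, "year")
        assert table.as_dict() == {"Before 2017": 2, "2020": 1, "Unknown": 1}

    def test_empty_set_flagged(self):
        table = demographic_table(ReportSet(), "sex")
        assert table.denominator == 0
        assert all(p is None for p in table.percentages)

    def test_unknown_axis_rejected(self, mixed_reports):
        with pytest.raises(ValueError):
            demographic_table(mixed_reports, "favourite_colour")

    def test_exclusive_strata_cannot_exceed_denominator(self):
        with pytest.raises(ValueError):
            StratifiedCounts(("a", "b"), (3, 3), denominator=4)


class TestSocProfile:
    def test_degenerate_single_soc(self, toy_map):
        rs = _reports({"reactions": ["Rash", "Pruritus"]}, {"reactions": ["Rash"]})
        prof = soc_profile(rs, toy_map)
        assert prof.total_reactions == 3
        assert prof.rate("Skin disorders") == 100.0

    def test_partition_with_unmapped_bucket(self, toy_map):
        rs = _reports({"reactions": ["Rash", "Mystery PT", "Nausea"]})
        prof = soc_profile(rs, toy_map)
        assert prof.total_reactions == 3
        assert sum(prof.per_soc.values()) + prof.n_unmapped == prof.total_reactions
        assert prof.n_unmapped == 1

    def test_reaction_level_denominator(self, toy_map):
        # one report, three reactions: denominator is 3, not 1
        rs = _reports({"reactions": ["Rash", "Nausea", "Dizziness"]})
        prof = soc_profile(rs, toy_map)
        assert prof.rate("Skin disorders") == percent(1, 3)


class TestTopPt:
    def test_rates_and_ordering(self):
        rs = _reports(
            {"reactions": ["Rash", "Nausea"]},
            {"reactions": ["Rash"]},
            {"reactions": ["Rash"]},
        )
        table = top_pt_table(rs, 2)
        assert table.rows[0] == ("Rash", 3, 75.0)
        assert table.rows[1] == ("Nausea", 1, 25.0)

    def test_tie_broken_lexicographically(self):
        rs = _reports({"reactions": ["Zoster", "Ague"]})
        table = top_pt_table(rs, 2)
        assert [r[0] for r in table.rows] == ["Ague", "Zoster"]

    def test_n_exceeding_distinct_pts_returns_all(self):
        rs = _reports({"reactions": ["Rash"]})
        assert top_pt_table(rs, 10).n == 1

    def test_report_level_denominator_option(self):
        rs = _reports({"reactions": ["Rash", "Nausea"]}, {"reactions": ["Rash"]})
        reaction_level = top_pt_table(rs, 1)
        report_level = top_pt_table(rs, 1, denominator="reports")
        assert reaction_level.rows[0][2] == percent(2, 3)
        assert report_level.rows[0][2] == percent(2, 2)

    def test_denominators_coincide_for_single_reaction_reports(self):
        rs = _reports({"reactions": ["Rash"]}, {"reactions": ["Nausea"]})
        assert top_pt_table(rs, 2).rows == top_pt_table(rs, 2, denominator="reports").rows


class TestSeriousRates:
    def test_multi_outcome_report_counts_toward_each(self):
        rs = _reports(
            {"reactions": ["Rash", "Nausea"],
             "seriousness": frozenset([Seriousness.DEATH, Seriousness.HOSPITALIZATION])},
            {"reactions": ["Rash"]},
        )
        table = serious_ae_rates(rs)
        counts = table.as_dict()
        assert counts["death"] == 1
        assert counts["hospitalization"] == 1
        assert counts["any_serious"] == 1
        assert table.denominator == 3  # reaction-level N

    def test_no_serious_outcomes_all_zero(self):
        rs = _reports({"reactions": ["Rash"]})
        assert set(serious_ae_rates(rs).counts) == {0}

    def test_report_level_denominator_option(self):
        rs = _reports({"reactions": ["Rash", "Nausea", "Dizziness"]})
        assert serious_ae_rates(rs, denominator="reports").denominator == 1
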