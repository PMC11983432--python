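"""Primary-suspect screening: selection, dedup, validity, idempotence."""

import pytest

from adrsignal import DrugRole, ReportSet, make_report, screen_primary_suspect


def test_selects_primary_suspect_reports(mixed_reports):
    out = screen_primary_suspect(mixed_reports, "drugA")
    assert [r.report_id for r in out.reports] == ["r1", "r4"]
    by_name = {f.name: f.n_removed for f in out.filters_applied}
    assert by_name["primary_suspect"] == 3
    assert by_name["deduplicate"] == 0
    assert by_name["drop_invalid"] == 0


def test_secondary_suspect_not_eligible(mixed_reports):
    # r2 names drugA only as secondary suspect
    assert "r2" not in screen_primary_suspect(mixed_reports, "drugA").report_ids


def test_duplicate_report_id_removed_keeping_first():
    rs = ReportSet(
        reports=[
            make_report("dup", [("d", DrugRole.PRIMARY_SUSPECT)], ["Rash"]),
            make_report("dup", [("d", DrugRole.PRIMARY_SUSPECT)], ["Nausea"]),
        ]
    )
    out = screen_primary_suspect(rs, "d")
    assert len(out) == 1
    assert out.reports[0].reactions == ("Rash",)
    assert {f.name: f.n_removed for f in out.filters_applied}["deduplicate"] == 1


def test_absent_drug_gives_empty_set(mixed_reports):
    out = screen_primary_suspect(mixed_reports, "nonexistent")
    assert len(out) == 0
    assert out.has_unique_ids


def test_empty_drug_name_rejected(mixed_reports):
    with pytest.raises(ValueError):
        screen_primary_suspect(mixed_reports, "  ")


def test_idempotent_and_never_grows(mixed_reports):
    once = screen_primary_suspect(mixed_reports, "drugA")
    twice = screen_primary_suspect(once, "drugA")
    assert twice.reports == once.reports
    assert len(once) <= len(mixed_reports)
    # surviving records are the original objects, fields untouched
    assert all(r in mixed_reports.reports for r in once.reports)
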