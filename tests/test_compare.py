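"""Shared/unique/partial signal partition across drugs."""

import pytest

from adrsignal import SignalSet, comparison_report, intersect_signals


def _set(drug, *pts, soc="SOC1"):
    return SignalSet.from_pairs(drug, [(pt, soc) for pt in pts])


def test_two_set_algebra():
    cr = intersect_signals([_set("d1", "x", "y"), _set("d2", "y", "z")])
    assert cr.shared == {"SOC1": ["y"]}
    assert cr.unique_per_drug["d1"] == {"SOC1": ["x"]}
    assert cr.unique_per_drug["d2"] == {"SOC1": ["z"]}
    assert cr.partial == {}


def test_pairwise_but_not_universal_is_neither_shared_nor_unique():
    cr = intersect_signals(
        [_set("d1", "w", "p"), _set("d2", "w", "p"), _set("d3", "w")]
    )
    assert cr.shared == {"SOC1": ["w"]}
    assert all(not per for per in cr.unique_per_drug.values())
    assert cr.partial == {"p": ("d1", "d2")}


def test_single_set_rejected():
    with pytest.raises(ValueError):
        intersect_signals([_set("d1", "x")])


def test_conflicting_soc_assignment_rejected():
    with pytest.raises(ValueError):
        intersect_signals([_set("d1", "x", soc="A"), _set("d2", "x", soc="B")])


def test_permutation_invariance():
    sets = [_set("d1", "x", "y"), _set("d2", "y", "z"), _set("d3", "y", "x")]
    fwd = intersect_signals(sets)
    rev = intersect_signals(sets[::-1])
    assert fwd.shared == rev.shared
    assert fwd.unique_per_drug == rev.unique_per_drug
    assert set(fwd.partial) == set(rev.partial)


def test_conservation_per_drug():
    sets = [
        SignalSet.from_pairs("d1", [("a", "S"), ("b", "S"), ("c", "T")]),
        SignalSet.from_pairs("d2", [("a", "S"), ("b", "S"), ("d", "T")]),
        SignalSet.from_pairs("d3", [("a", "S"), ("e", "T")]),
    ]
    cr = intersect_signals(sets)
    for s in sets:
        n_unique = sum(len(v) for v in cr.unique_per_drug[s.drug].values())
        n_partial = sum(1 for pt, who in cr.partial.items() if s.drug in who)
        assert len(s.pts) == cr.n_shared + n_unique + n_partial


def test_soc_ranking_by_shared_count_then_name():
    sets = [
        SignalSet.from_pairs("d1", [("a", "S"), ("b", "S"), ("c", "A"), ("d", "B"), ("e", "B")]),
        SignalSet.from_pairs("d2", [("a", "S"), ("b", "S"), ("c", "A"), ("d", "B"), ("e", "B")]),
    ]
    cr = intersect_signals(sets)
    assert cr.soc_ranking == ["B", "S", "A"]  # 2, 2 tie broken lexicographically; then 1


def test_report_rendering():
    cr = intersect_signals([_set("d1", "x", "y"), _set("d2", "y", "z")])
    report = comparison_report(cr)
    assert list(report.shared_table["signal_n"]) == [1]
    assert report.unique_table.shape[0] == 1
    assert "d1" in report.unique_table.columns


def test_empty_shared_set_rendering():
    cr = intersect_signals([_set("d1", "x"), _set("d2", "z")])
    report = comparison_report(cr)
    assert report.shared_table.empty
    assert "no PT is signalled for every drug" in report.text
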