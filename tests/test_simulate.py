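"""Synthetic report generator: determinism, validation, marginal fidelity."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from adrsignal import (
    GeneratorConfig,
    default_config,
    generate,
    null_universe_config,
    planted_universe_config,
)
from adrsignal.models import Sex
from adrsignal.simulate import _expected_pair_count


def test_identical_seed_identical_output():
    cfg = default_config(n_reports=500, seed=11)
    rs1, gt1 = generate(cfg)
    rs2, gt2 = generate(cfg)
    assert rs1.reports == rs2.reports
    assert gt1 == gt2


def test_different_seed_differs():
    a, _ = generate(default_config(n_reports=500, seed=1))
    b, _ = generate(default_config(n_reports=500, seed=2))
    assert a.reports != b.reports


def test_single_drug_single_pt_degenerate():
    cfg = GeneratorConfig(
        n_reports=50,
        drugs=(("onlydrug", 1.0),),
        pt_catalog=(("OnlyPT", "SomeSOC", 1.0),),
    )
    rs, _ = generate(cfg)
    assert all(r.drugs[0].name == "onlydrug" for r in rs.reports)
    assert all(r.reactions == ("OnlyPT",) for r in rs.reports)


def test_reactions_unique_within_report():
    rs, _ = generate(default_config(n_reports=2_000, seed=3))
    for r in rs.reports:
        assert len(r.reactions) == len(set(r.reactions))


@pytest.mark.parametrize(
    "bad",
    [
        {"planted": (("ghostdrug", "Rash", 5.0),)},
        {"planted": (("apalutamide", "Ghost PT", 5.0),)},
        {"planted": (("apalutamide", "Rash", 0.5),)},
        {"mean_reactions": 0.4},
        {"n_reports": 0},
    ],
)
def test_invalid_configs_rejected(bad):
    cfg = default_config(n_reports=100)
    with pytest.raises(ValueError):
        dataclasses.replace(cfg, **bad)


def test_sex_margin_chi_square_not_rejected():
    """Generated sex margins converge to the configured probabilities."""
    cfg = default_config(n_reports=50_000, seed=5)
    rs, _ = generate(cfg)
    observed = {s: 0 for s in Sex}
    for r in rs.reports:
        observed[r.sex] += 1
    probs = dict(cfg.sex_probs)
    f_obs = [observed[s] for s in Sex]
    f_exp = [probs[s] * len(rs) for s in Sex]
    _, p = stats.chisquare(f_obs, f_exp)
    assert p > 0.01


def test_planted_pair_realized_count_tracks_expectation():
    """At rr=5 the realized planted count sits within binomial error of the
    analytic expectation, and the empirical enrichment over the unplanted
    baseline recovers the planted multiplier for a rare PT."""
    base = planted_universe_config(rr=5.0, n_reports=50_000, seed=9)
    # rare planted PT so within-report competition barely distorts the RR
    catalog = tuple(
        (pt, soc, 0.1 if pt == "Rash" else w) for pt, soc, w in base.pt_catalog
    )
    cfg = dataclasses.replace(base, pt_catalog=catalog)
    rs, gt = generate(cfg)
    pair = ("darolutamide", "Rash")
    expected = gt.expected_counts[pair]
    realized = gt.realized_counts[pair]
    assert realized == pytest.approx(expected, abs=4 * np.sqrt(expected))
    baseline = _expected_pair_count(
        dataclasses.replace(cfg, planted=()), "darolutamide", "Rash", 1.0
    )
    assert realized / baseline == pytest.approx(5.0, rel=0.15)


def test_null_config_has_no_plants():
    cfg = null_universe_config(n_reports=100)
    assert cfg.planted == ()
    assert len({w for _, _, w in cfg.pt_catalog}) == 1


def test_meddra_map_covers_catalog():
    cfg = default_config(n_reports=10)
    mmap = cfg.meddra_map()
    assert all(pt in mmap for pt, _, _ in cfg.pt_catalog)
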