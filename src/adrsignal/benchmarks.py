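"""Simulation benchmarks: null calibration and planted-signal recovery.

These drive the generator and the detection stack end to end:

* the null study measures per-pair criterion flag rates on independent
  (no-association) universes — under independence the ROR criterion
  (CI lower bound > 1) is a one-sided ~2.5% test, so its flag rate should
  stay below 5%;
* the recovery study plants one association of known strength and measures
  how often each criterion (and all four jointly) flags it across
  replicate universes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import (
    RECOVERY_PAIR,
    generate,
    null_universe_config,
    planted_universe_config,
)
from .signals import detect_signals

#: Keep derived child seeds inside the 31-bit range.
_SEED_MOD = 2**31


def _child_seed(base: int, i: int) -> int:
    return (base * 1_000_003 + i) % _SEED_MOD


@dataclass(frozen=True, slots=True)
class NullCalibration:
    n_universes: int
    n_pairs: int  # drugs x PTs x universes
    flag_rates: dict[str, float]  # per-criterion fraction of pairs flagged


def null_flag_rate(
    n_universes: int = 200, n_reports: int = 5_000, base_seed: int = 0
) -> NullCalibration:
    """Per-pair criterion flag rates over replicate independence universes.

    Every (drug, PT) pair in every universe counts once in the denominator;
    pairs never observed together simply contribute an unflagged pair.
    """
    flags = {"ror": 0, "prr": 0, "bcpnn": 0, "ebgm": 0, "any": 0}
    n_pairs = 0
    for i in range(n_universes):
        cfg = null_universe_config(n_reports=n_reports, seed=_child_seed(base_seed, i))
        rs, _ = generate(cfg)
        mmap = cfg.meddra_map()
        n_pairs += len(cfg.drugs) * len(cfg.pt_catalog)
        for drug, _share in cfg.drugs:
            for _ev, s in detect_signals(rs, drug, mmap):
                flags["ror"] += s.flag_ror
                flags["prr"] += s.flag_prr
                flags["bcpnn"] += s.flag_bcpnn
                flags["ebgm"] += s.flag_ebgm
                flags["any"] += s.is_signal("any")
    return NullCalibration(
        n_universes=n_universes,
        n_pairs=n_pairs,
        flag_rates={k: v / n_pairs for k, v in flags.items()},
    )


@dataclass(frozen=True, slots=True)
class RecoveryResult:
    rr: float
    n_replicates: int
    mean_a: float  # mean co-report count of the planted pair
    rates: dict[str, float]  # per-criterion and joint ("all") detection rates


def planted_recovery(
    rr: float,
    n_replicates: int = 100,
    n_reports: int = 20_000,
    base_seed: int = 0,
) -> RecoveryResult:
    """Fraction of replicate universes in which each criterion flags the
    planted pair."""
    drug, pt = RECOVERY_PAIR
    hits = {"ror": 0, "prr": 0, "bcpnn": 0, "ebgm": 0, "all": 0}
    total_a = 0
    for i in range(n_replicates):
        cfg = planted_universe_config(
            rr=rr, n_reports=n_reports, seed=_child_seed(base_seed, i)
        )
        rs, _ = generate(cfg)
        stats = dict(detect_signals(rs, drug, cfg.meddra_map())).get(pt)
        if stats is None:
            continue  # planted pair never co-reported: counts as a miss
        total_a += stats.n_reports
        hits["ror"] += stats.flag_ror
        hits["prr"] += stats.flag_prr
        hits["bcpnn"] += stats.flag_bcpnn
        hits["ebgm"] += stats.flag_ebgm
        hits["all"] += stats.is_signal("all")
    return RecoveryResult(
        rr=rr,
        n_replicates=n_replicates,
        mean_a=total_a / n_replicates,
        rates={k: v / n_replicates for k, v in hits.items()},
    )
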