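"""Cross-drug signal comparison: shared and drug-exclusive signals by SOC.

Given one signal set per drug (PT-level signals with their SOCs), the
comparison splits the union of signalled PTs three ways:

* shared — signalled for every input drug (grouped by SOC with per-SOC
  counts, SOCs ranked by count);
* unique — signalled for exactly one drug;
* partial — signalled for at least two drugs but not all (reported
  separately; it belongs to neither of the two headline tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd


@dataclass(frozen=True, slots=True)
class SignalSet:
    """The PT-level signals detected for one drug, with their SOCs."""

    drug: str
    events: frozenset[tuple[str, str]]  # (PT, SOC) pairs

    def __post_init__(self) -> None:
        pts = [pt for pt, _ in self.events]
        if len(pts) != len(set(pts)):
            raise ValueError(f"signal set for {self.drug!r}: a PT appears under two SOCs")

    @property
    def pts(self) -> frozenset[str]:
        return frozenset(pt for pt, _ in self.events)

    @classmethod
    def from_pairs(cls, drug: str, pairs) -> "SignalSet":
        return cls(drug=drug, events=frozenset((str(p), str(s)) for p, s in pairs))


@dataclass(slots=True)
class ComparisonResult:
    """Shared/unique/partial partition of signals across drugs."""

    drugs: tuple[str, ...]
    shared: dict[str, list[str]]  # SOC -> sorted shared PTs
    unique_per_drug: dict[str, dict[str, list[str]]]  # drug -> SOC -> PTs
    partial: dict[str, tuple[str, ...]]  # PT -> drugs signalling it (>=2, <all)
    soc_ranking: list[str] = field(default_factory=list)

    @property
    def n_shared(self) -> int:
        return sum(len(v) for v in self.shared.values())

    def shared_count(self, soc: str) -> int:
        return len(self.shared.get(soc, []))


def intersect_signals(sets: Sequence[SignalSet]) -> ComparisonResult:
    """Partition PT-level signals into shared / unique / partially shared.

    Requires at least two signal sets with a consistent PT->SOC assignment.
    The result is independent of input order (drug columns keep the given
    order, but membership does not depend on it).
    """
    if len(sets) < 2:
        raise ValueError("signal comparison requires at least two signal sets")
    drugs = tuple(s.drug for s in sets)
    if len(set(drugs)) != len(drugs):
        raise ValueError("duplicate drug names in signal sets")

    soc_of: dict[str, str] = {}
    for s in sets:
        for pt, soc in s.events:
            if soc_of.setdefault(pt, soc) != soc:
                raise ValueError(f"PT {pt!r} assigned to two different SOCs across sets")

    membership: dict[str, list[str]] = {}
    for s in sets:
        for pt in s.pts:
            membership.setdefault(pt, []).append(s.drug)

    shared: dict[str, list[str]] = {}
    unique: dict[str, dict[str, list[str]]] = {d: {} for d in drugs}
    partial: dict[str, tuple[str, ...]] = {}
    for pt, who in membership.items():
        soc = soc_of[pt]
        if len(who) == len(drugs):
            shared.setdefault(soc, []).append(pt)
        elif len(who) == 1:
            unique[who[0]].setdefault(soc, []).append(pt)
        else:
            partial[pt] = tuple(d for d in drugs if d in who)

    for v in shared.values():
        v.sort()
    for per_soc in unique.values():
        for v in per_soc.values():
            v.sort()

    ranking = sorted(shared, key=lambda soc: (-len(shared[soc]), soc))
    return ComparisonResult(
        drugs=drugs,
        shared=shared,
        unique_per_drug=unique,
        partial=partial,
        soc_ranking=ranking,
    )


@dataclass(slots=True)
class ComparisonReport:
    """Rendered comparison tables (shared-by-SOC and unique-by-drug)."""

    shared_table: pd.DataFrame
    unique_table: pd.DataFrame
    text: str


def comparison_report(cr: ComparisonResult) -> ComparisonReport:
    """Render the shared and drug-exclusive signal tables.

    The shared table has one row per SOC (ranked by shared-signal count)
    with the PT list and its count; the unique table has one row per SOC
    with one column per drug.  An empty shared set yields an empty table
    with an explanatory note in the text rendering.
    """
    shared_rows = [
        {
            "system_organ_class": soc,
            "adrs": ", ".join(cr.shared[soc]),
            "signal_n": len(cr.shared[soc]),
        }
        for soc in cr.soc_ranking
    ]
    shared_df = pd.DataFrame(shared_rows, columns=["system_organ_class", "adrs", "signal_n"])

    all_socs = sorted({soc for per in cr.unique_per_drug.values() for soc in per})
    unique_rows = []
    for soc in all_socs:
        row = {"system_organ_class": soc}
        for d in cr.drugs:
            row[d] = ", ".join(cr.unique_per_drug[d].get(soc, []))
        unique_rows.append(row)
    unique_df = pd.DataFrame(unique_rows, columns=["system_organ_class", *cr.drugs])

    lines = [f"Signals shared by all {len(cr.drugs)} drugs: {cr.n_shared} PT(s)"]
    if shared_df.empty:
        lines.append("(no PT is signalled for every drug)")
    else:
        lines.append(shared_df.to_string(index=False))
    lines.append("")
    lines.append("Drug-exclusive signals:")
    lines.append(unique_df.to_string(index=False) if not unique_df.empty else "(none)")
    if cr.partial:
        lines.append("")
        lines.append(f"Partially shared PTs (in >=2 but not all drugs): {len(cr.partial)}")
    return ComparisonReport(shared_table=shared_df, unique_table=unique_df, text="\n".join(lines))
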