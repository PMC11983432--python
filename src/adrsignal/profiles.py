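"""Descriptive ADR profiling: demographics, SOC rates, top-PT tables, serious AEs.

Two denominator conventions coexist in VigiAccess-style summaries and are
kept as distinct code paths here:

* report-level: the number of reports (demographic tables);
* reaction-level: the total number of PT occurrences, where a report with k
  reactions contributes k (SOC incidence tables, and by default the top-PT
  and serious-AE rates).

Percentages are rounded half-up to two decimals, matching how the published
summary tables print them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional

import pandas as pd

from .models import (
    AGE_GROUP_LABELS,
    AgeGroup,
    Continent,
    MeddraMap,
    ReportSet,
    Seriousness,
    Sex,
)

logger = logging.getLogger(__name__)

UNMAPPED = "Unmapped"

Denominator = Literal["reactions", "reports"]


def percent(count: int, denominator: int) -> Optional[float]:
    """count/denominator as a percentage, rounded half-up to 2 decimals.

    Exact decimal arithmetic so that e.g. 10751/11452 -> 93.88 regardless of
    binary floating-point representation.  None when the denominator is 0.
    """
    if denominator == 0:
        return None
    frac = Decimal(count * 100) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class StratifiedCounts:
    """Counts over an ordered set of strata with a shared denominator.

    ``exclusive`` marks strata that partition the denominator (demographic
    axes); serious-outcome counts are non-exclusive because one report may
    carry several outcomes.
    """

    stratum_labels: tuple[str, ...]
    counts: tuple[int, ...]
    denominator: int
    exclusive: bool = True

    def __post_init__(self) -> None:
        if len(self.stratum_labels) != len(self.counts):
            raise ValueError("labels and counts length mismatch")
        if any(c < 0 for c in self.counts) or self.denominator < 0:
            raise ValueError("counts must be non-negative")
        if self.exclusive and self.denominator and sum(self.counts) > self.denominator:
            raise ValueError("exclusive strata counts exceed denominator")

    @property
    def percentages(self) -> tuple[Optional[float], ...]:
        return tuple(percent(c, self.denominator) for c in self.counts)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.stratum_labels, self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum_labels,
                "count": self.counts,
                "denominator": self.denominator,
                "percent": self.percentages,
            }
        )


@dataclass(slots=True)
class SocProfile:
    """Reaction counts and rates per system organ class for one drug.

    ``total_reactions`` is the reaction-level N; per-SOC counts plus the
    unmapped bucket partition it exactly.
    """

    drug: str
    total_reactions: int
    per_soc: dict[str, int]
    n_unmapped: int = 0

    def rate(self, soc: str) -> Optional[float]:
        return percent(self.per_soc.get(soc, 0), self.total_reactions)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"soc": soc, "count": c, "denominator": self.total_reactions, "percent": percent(c, self.total_reactions)}
            for soc, c in self.per_soc.items()
        ]
        if self.n_unmapped:
            rows.append(
                {
                    "soc": UNMAPPED,
                    "count": self.n_unmapped,
                    "denominator": self.total_reactions,
                    "percent": percent(self.n_unmapped, self.total_reactions),
                }
            )
        return pd.DataFrame(rows)


@dataclass(slots=True)
class PtRateTable:
    """Top-N preferred terms by rate, ties broken lexicographically."""

    drug: str
    rows: list[tuple[str, int, Optional[float]]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["pt", "count", "report_rate_percent"])


YEAR_CUTOFF = 2017
BEFORE_LABEL = f"Before {YEAR_CUTOFF}"


def demographic_table(rs: ReportSet, axis: str) -> StratifiedCounts:
    """Report-level distribution over one demographic axis.

    One stratum per enum label including ``unknown``.  The year axis bins
    everything before 2017 into a single "Before 2017" stratum, then one
    stratum per observed later year.  An empty ReportSet yields all-zero
    counts with denominator 0 (percentages reported as missing).
    """
    n = len(rs.reports)
    if axis == "sex":
        labels = [s for s in Sex]
        counts = {s: 0 for s in labels}
        for r in rs.reports:
            counts[r.sex] += 1
        return StratifiedCounts(
            tuple(s.value.capitalize() for s in labels),
            tuple(counts[s] for s in labels),
            n,
        )
    if axis == "age_group":
        labels = [a for a in AgeGroup]
        counts = {a: 0 for a in labels}
        for r in rs.reports:
            counts[r.age_group] += 1
        return StratifiedCounts(
            tuple(AGE_GROUP_LABELS[a] for a in labels),
            tuple(counts[a] for a in labels),
            n,
        )
    if axis == "continent":
        labels = [c for c in Continent]
        counts = {c: 0 for c in labels}
        for r in rs.reports:
            counts[r.continent] += 1
        return StratifiedCounts(
            tuple(c.value if c is not Continent.UNKNOWN else "Unknown" for c in labels),
            tuple(counts[c] for c in labels),
            n,
        )
    if axis == "year":
        before = 0
        unknown = 0
        per_year: dict[int, int] = {}
        for r in rs.reports:
            if r.year is None:
                unknown += 1
            elif r.year < YEAR_CUTOFF:
                before += 1
            else:
                per_year[r.year] = per_year.get(r.year, 0) + 1
        labels = [BEFORE_LABEL, *(str(y) for y in sorted(per_year)), "Unknown"]
        counts = [before, *(per_year[y] for y in sorted(per_year)), unknown]
        return StratifiedCounts(tuple(labels), tuple(counts), n)
    raise ValueError(f"unknown axis {axis!r}")


def soc_profile(rs: ReportSet, map: MeddraMap, drug: str = "") -> SocProfile:
    """Reaction-level SOC incidence profile.

    Each PT occurrence is attributed to its SOC; unresolvable PTs are
    excluded from ``per_soc``, tallied in the unmapped bucket, and logged.
    """
    per_soc = {soc: 0 for soc in map.soc_list}
    n_unmapped = 0
    total = 0
    unmapped_pts: set[str] = set()
    for r in rs.reports:
        for pt in r.reactions:
            total += 1
            soc = map.soc_of(pt)
            if soc is None:
                n_unmapped += 1
                unmapped_pts.add(pt)
            else:
                per_soc[soc] += 1
    if unmapped_pts:
        logger.warning(
            "%d reaction occurrence(s) over %d PT(s) not resolvable through the PT->SOC map",
            n_unmapped,
            len(unmapped_pts),
        )
    return SocProfile(drug=drug, total_reactions=total, per_soc=per_soc, n_unmapped=n_unmapped)


def top_pt_table(
    rs: ReportSet,
    n: int,
    drug: str = "",
    denominator: Denominator = "reactions",
) -> PtRateTable:
    """Top-``n`` preferred terms by occurrence rate.

    The default denominator is the reaction-level N; ``denominator="reports"``
    switches to the report count.  Sorted by rate descending, ties broken
    lexicographically by PT; if fewer than ``n`` distinct PTs exist, all are
    returned without padding.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: dict[str, int] = {}
    for r in rs.reports:
        for pt in r.reactions:
            counts[pt] = counts.get(pt, 0) + 1
    denom = rs.total_reactions if denominator == "reactions" else len(rs.reports)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return PtRateTable(
        drug=drug,
        rows=[(pt, c, percent(c, denom)) for pt, c in ordered],
    )


def serious_ae_rates(rs: ReportSet, denominator: Denominator = "reactions") -> StratifiedCounts:
    """Counts of reports with each serious outcome (death, hospitalization,
    disability).

    A report may count toward several outcomes.  The default denominator is
    the reaction-level N, matching how published VigiAccess summaries pair
    the reaction total with the serious-AE rate; ``denominator="reports"``
    gives the report-level alternative.
    """
    outcomes = [Seriousness.DEATH, Seriousness.HOSPITALIZATION, Seriousness.DISABILITY]
    counts = {o: 0 for o in outcomes}
    n_any = 0
    for r in rs.reports:
        hit = False
        for o in outcomes:
            if o in r.seriousness:
                counts[o] += 1
                hit = True
        n_any += hit
    denom = rs.total_reactions if denominator == "reactions" else len(rs.reports)
    return StratifiedCounts(
        stratum_labels=tuple([o.value for o in outcomes] + ["any_serious"]),
        counts=tuple([counts[o] for o in outcomes] + [n_any]),
        denominator=denom,
        exclusive=False,
    )
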