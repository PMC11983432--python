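"""Core data model for individual case safety reports (ICSRs).

A spontaneous report links one or more suspect/concomitant drugs to one or
more adverse reactions coded as MedDRA preferred terms (PTs), together with
reporter demographics and seriousness outcomes.  The model mirrors what a
public pharmacovigilance portal such as WHO-VigiAccess exposes at the
aggregate level: PT-coded reactions, the PT->SOC (system organ class)
hierarchy, and report-level strata for sex, age group, continent and year.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence


class DrugRole(str, enum.Enum):
    """Role a drug plays in a report, as classified by the reporter."""

    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class AgeGroup(str, enum.Enum):
    """Age bands used by VigiAccess-style demographic summaries."""

    LT18 = "lt18"
    A18_44 = "a18_44"
    A45_64 = "a45_64"
    A65_74 = "a65_74"
    GE75 = "ge75"
    UNKNOWN = "unknown"


class Continent(str, enum.Enum):
    AFRICA = "Africa"
    AMERICAS = "Americas"
    ASIA = "Asia"
    EUROPE = "Europe"
    OCEANIA = "Oceania"
    UNKNOWN = "unknown"


class Seriousness(str, enum.Enum):
    """Treatment-interrupting outcomes tracked per report."""

    DEATH = "death"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    NONE_REPORTED = "none_reported"


#: Canonical seriousness value for reports with no serious outcome.
NO_SERIOUS_OUTCOME = frozenset([Seriousness.NONE_REPORTED])


#: Display labels used when rendering demographic tables.
AGE_GROUP_LABELS = {
    AgeGroup.LT18: "<18",
    AgeGroup.A18_44: "18-44",
    AgeGroup.A45_64: "45-64",
    AgeGroup.A65_74: "65-74",
    AgeGroup.GE75: ">=75",
    AgeGroup.UNKNOWN: "Unknown",
}


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug named on a report, with its reported role."""

    name: str
    role: DrugRole


@dataclass(slots=True)
class CaseReport:
    """One individual case safety report.

    ``reactions`` is a non-empty sequence of MedDRA preferred terms; a drug
    name may appear at most once.  Demographic fields are always one of the
    declared enum values (missing data maps to the ``unknown`` member, never
    to free text); ``year`` is a calendar year or ``None`` when unknown.
    """

    report_id: str
    drugs: tuple[DrugEntry, ...]
    reactions: tuple[str, ...]
    sex: Sex = Sex.UNKNOWN
    age_group: AgeGroup = AgeGroup.UNKNOWN
    continent: Continent = Continent.UNKNOWN
    year: Optional[int] = None
    seriousness: frozenset[Seriousness] = NO_SERIOUS_OUTCOME

    def validate(self) -> None:
        """Raise ``ValueError`` on a structurally invalid report."""
        if not self.reactions:
            raise ValueError(f"report {self.report_id!r}: empty reaction list")
        names = [d.name for d in self.drugs]
        if len(names) != len(set(names)):
            raise ValueError(
                f"report {self.report_id!r}: a drug name appears with more than one role"
            )

    def has_primary_suspect(self, drug: str) -> bool:
        return any(
            d.role is DrugRole.PRIMARY_SUSPECT and d.name == drug for d in self.drugs
        )

    @property
    def is_valid(self) -> bool:
        """Structural validity: at least one reaction and one drug entry."""
        return bool(self.reactions) and bool(self.drugs)


@dataclass(frozen=True, slots=True)
class MeddraMap:
    """A PT -> SOC dictionary defining a two-level MedDRA-style hierarchy.

    Every preferred term maps to exactly one system organ class;
    ``soc_list`` fixes the display order of the SOC universe.
    """

    pt_to_soc: Mapping[str, str]
    soc_list: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.soc_list)
        stray = {s for s in self.pt_to_soc.values() if s not in known}
        if stray:
            raise ValueError(f"PT->SOC map references SOCs outside soc_list: {sorted(stray)}")

    def soc_of(self, pt: str) -> Optional[str]:
        return self.pt_to_soc.get(pt)

    def pts_in_soc(self, soc: str) -> frozenset[str]:
        return frozenset(p for p, s in self.pt_to_soc.items() if s == soc)

    def __contains__(self, pt: str) -> bool:
        return pt in self.pt_to_soc


@dataclass(frozen=True, slots=True)
class FilterRecord:
    """Provenance entry for one screening step applied to a ReportSet."""

    name: str
    detail: str
    n_removed: int


@dataclass(slots=True)
class ReportSet:
    """A collection of case reports with provenance of applied filters."""

    reports: list[CaseReport] = field(default_factory=list)
    filters_applied: list[FilterRecord] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[CaseReport]:
        return iter(self.reports)

    @property
    def report_ids(self) -> list[str]:
        return [r.report_id for r in self.reports]

    @property
    def has_unique_ids(self) -> bool:
        ids = self.report_ids
        return len(ids) == len(set(ids))

    @property
    def total_reactions(self) -> int:
        """Reaction-level N: a report with k reactions contributes k."""
        return sum(len(r.reactions) for r in self.reports)

    def with_filter(
        self, reports: Iterable[CaseReport], record: FilterRecord
    ) -> "ReportSet":
        """A new ReportSet holding ``reports`` and the extended filter trail."""
        return ReportSet(
            reports=list(reports),
            filters_applied=[*self.filters_applied, record],
            source=self.source,
        )


def make_report(
    report_id: str,
    drugs: Sequence[tuple[str, DrugRole | str]] | Sequence[DrugEntry],
    reactions: Sequence[str],
    **kwargs,
) -> CaseReport:
    """Convenience constructor accepting (name, role) pairs for drugs."""
    entries = tuple(
        d if isinstance(d, DrugEntry) else DrugEntry(d[0], DrugRole(d[1])) for d in drugs
    )
    if not kwargs.get("seriousness"):
        kwargs["seriousness"] = NO_SERIOUS_OUTCOME
    report = CaseReport(
        report_id=report_id, drugs=entries, reactions=tuple(reactions), **kwargs
    )
    report.validate()
    return report
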