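"""Reading and writing case-report collections and PT->SOC maps.

File formats
------------
Reports CSV (UTF-8, comma-separated, quoted fields), one row per report::

    report_id,drug,role,reactions,sex,age_group,continent,year,seriousness

``drug`` and ``role`` are aligned pipe-delimited lists (one entry per drug
on the report); ``reactions`` and ``seriousness`` are pipe-delimited lists.
The JSON format is an array of objects with the same keys, with ``drugs``
as a list of ``{"name": ..., "role": ...}`` objects and ``reactions`` /
``seriousness`` as lists.

PT->SOC map: two-column CSV ``pt,soc``.

Field normalization
-------------------
Free-text demographic fields are normalized before enum lookup: strip
leading/trailing whitespace, collapse internal runs of whitespace, casefold,
and replace en-dashes with hyphens.  The frozen synonym tables below then
map the normalized token to an enum member; anything unrecognized maps to
the ``unknown`` member (demographics) or raises (drug roles, which have no
unknown member).
"""

from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path
from typing import Optional, Union

from .models import (
    AgeGroup,
    CaseReport,
    Continent,
    DrugEntry,
    DrugRole,
    FilterRecord,
    MeddraMap,
    ReportSet,
    Seriousness,
    Sex,
)

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "report_id",
    "drug",
    "role",
    "reactions",
    "sex",
    "age_group",
    "continent",
    "year",
    "seriousness",
]

LIST_SEP = "|"

_WS = re.compile(r"\s+")


def normalize_token(value: str) -> str:
    """Canonical form used for synonym lookup: trimmed, casefolded, en-dash -> hyphen."""
    return _WS.sub(" ", value.replace("–", "-").strip()).casefold()


SEX_SYNONYMS = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "": Sex.UNKNOWN,
    "u": Sex.UNKNOWN,
    "unknown": Sex.UNKNOWN,
}

AGE_SYNONYMS = {
    "<18": AgeGroup.LT18,
    "lt18": AgeGroup.LT18,
    "under 18": AgeGroup.LT18,
    "0-17": AgeGroup.LT18,
    "18-44": AgeGroup.A18_44,
    "a18_44": AgeGroup.A18_44,
    "45-64": AgeGroup.A45_64,
    "a45_64": AgeGroup.A45_64,
    "65-74": AgeGroup.A65_74,
    "a65_74": AgeGroup.A65_74,
    ">=75": AgeGroup.GE75,
    "≥75": AgeGroup.GE75,
    "75+": AgeGroup.GE75,
    "ge75": AgeGroup.GE75,
    "": AgeGroup.UNKNOWN,
    "unknown": AgeGroup.UNKNOWN,
}

CONTINENT_SYNONYMS = {
    "africa": Continent.AFRICA,
    "americas": Continent.AMERICAS,
    "america": Continent.AMERICAS,
    "asia": Continent.ASIA,
    "europe": Continent.EUROPE,
    "oceania": Continent.OCEANIA,
    "": Continent.UNKNOWN,
    "unknown": Continent.UNKNOWN,
}

ROLE_SYNONYMS = {
    "primary_suspect": DrugRole.PRIMARY_SUSPECT,
    "primary suspect": DrugRole.PRIMARY_SUSPECT,
    "primary": DrugRole.PRIMARY_SUSPECT,
    "ps": DrugRole.PRIMARY_SUSPECT,
    "secondary_suspect": DrugRole.SECONDARY_SUSPECT,
    "secondary suspect": DrugRole.SECONDARY_SUSPECT,
    "secondary": DrugRole.SECONDARY_SUSPECT,
    "ss": DrugRole.SECONDARY_SUSPECT,
    "concomitant": DrugRole.CONCOMITANT,
    "companion": DrugRole.CONCOMITANT,
    "interacting": DrugRole.INTERACTING,
}

SERIOUSNESS_SYNONYMS = {
    "death": Seriousness.DEATH,
    "died": Seriousness.DEATH,
    "fatal": Seriousness.DEATH,
    "hospitalization": Seriousness.HOSPITALIZATION,
    "hospitalisation": Seriousness.HOSPITALIZATION,
    "hospitalized": Seriousness.HOSPITALIZATION,
    "disability": Seriousness.DISABILITY,
    "disabling": Seriousness.DISABILITY,
    "none": Seriousness.NONE_REPORTED,
    "none_reported": Seriousness.NONE_REPORTED,
    "": Seriousness.NONE_REPORTED,
}


class MalformedRecordError(ValueError):
    """A record could not be parsed; carries row number and field name."""

    def __init__(self, row: Union[int, str], fieldname: str, message: str):
        self.row = row
        self.fieldname = fieldname
        super().__init__(f"record {row}, field {fieldname!r}: {message}")


def parse_sex(value: str) -> Sex:
    return SEX_SYNONYMS.get(normalize_token(value), Sex.UNKNOWN)


def parse_age_group(value: str) -> AgeGroup:
    return AGE_SYNONYMS.get(normalize_token(value), AgeGroup.UNKNOWN)


def parse_continent(value: str) -> Continent:
    return CONTINENT_SYNONYMS.get(normalize_token(value), Continent.UNKNOWN)


def parse_role(value: str, row: Union[int, str] = "?") -> DrugRole:
    token = normalize_token(value)
    if token not in ROLE_SYNONYMS:
        raise MalformedRecordError(row, "role", f"unrecognized drug role {value!r}")
    return ROLE_SYNONYMS[token]


def parse_year(value: str, row: Union[int, str] = "?") -> Optional[int]:
    token = normalize_token(value)
    if token in ("", "unknown"):
        return None
    try:
        return int(token)
    except ValueError as exc:
        raise MalformedRecordError(row, "year", f"not a year: {value!r}") from exc


def parse_seriousness(values: list[str], row: Union[int, str] = "?") -> frozenset[Seriousness]:
    out = set()
    for v in values:
        token = normalize_token(v)
        if token not in SERIOUSNESS_SYNONYMS:
            raise MalformedRecordError(row, "seriousness", f"unrecognized outcome {v!r}")
        out.add(SERIOUSNESS_SYNONYMS[token])
    if not out:
        out.add(Seriousness.NONE_REPORTED)
    if len(out) > 1:
        out.discard(Seriousness.NONE_REPORTED)
    return frozenset(out)


def _split(value: str) -> list[str]:
    value = value.strip()
    if not value:
        return []
    return [part.strip() for part in value.split(LIST_SEP)]


def _record_from_row(row_num: Union[int, str], row: dict) -> Optional[CaseReport]:
    """Build one CaseReport from a parsed CSV/JSON row; None if rejected."""
    missing = [c for c in CSV_COLUMNS if c not in row and c not in ("drug", "role")]
    if "drugs" not in row:
        missing += [c for c in ("drug", "role") if c not in row]
    if missing:
        raise MalformedRecordError(row_num, missing[0], "missing column")

    report_id = str(row["report_id"]).strip()
    if not report_id:
        raise MalformedRecordError(row_num, "report_id", "empty identifier")

    if "drugs" in row:  # JSON shape
        raw_drugs = [(d["name"], d["role"]) for d in row["drugs"]]
    else:
        names = _split(str(row["drug"]))
        roles = _split(str(row["role"]))
        if len(names) != len(roles):
            raise MalformedRecordError(
                row_num, "role", f"{len(names)} drug(s) but {len(roles)} role(s)"
            )
        raw_drugs = list(zip(names, roles))
    drugs = tuple(
        DrugEntry(name=_WS.sub(" ", str(n).strip()), role=parse_role(str(r), row_num))
        for n, r in raw_drugs
    )
    seen: set[str] = set()
    for d in drugs:
        if d.name in seen:
            raise MalformedRecordError(row_num, "drug", f"duplicate drug name {d.name!r}")
        seen.add(d.name)

    raw_reactions = (
        [str(x) for x in row["reactions"]]
        if isinstance(row["reactions"], list)
        else _split(str(row["reactions"]))
    )
    reactions = tuple(_WS.sub(" ", r.strip()) for r in raw_reactions if r.strip())
    if not reactions:
        return None  # rejected: invalid report

    raw_serious = (
        [str(x) for x in row["seriousness"]]
        if isinstance(row.get("seriousness"), list)
        else _split(str(row.get("seriousness", "")))
    )
    raw_year = row.get("year")
    return CaseReport(
        report_id=report_id,
        drugs=drugs,
        reactions=reactions,
        sex=parse_sex(str(row.get("sex", ""))),
        age_group=parse_age_group(str(row.get("age_group", ""))),
        continent=parse_continent(str(row.get("continent", ""))),
        year=None if raw_year is None else parse_year(str(raw_year), row_num),
        seriousness=parse_seriousness(raw_serious, row_num),
    )


def infer_format(path: Union[str, Path]) -> str:
    return "json" if str(path).lower().endswith(".json") else "csv"


def read_reports(path: Union[str, Path], format: Optional[str] = None) -> ReportSet:
    """Read a report collection from CSV or JSON.

    Unknown or missing demographic fields map to the ``unknown`` enum member
    and are never dropped.  Records with an empty reaction list are rejected;
    the rejection count is logged and recorded in ``filters_applied``.
    """
    path = Path(path)
    fmt = format or infer_format(path)
    reports: list[CaseReport] = []
    n_rejected = 0

    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):  # row 1 is the header
                rec = _record_from_row(i, row)
                if rec is None:
                    n_rejected += 1
                else:
                    reports.append(rec)
    elif fmt == "json":
        with path.open(encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise MalformedRecordError(0, "", "JSON root must be an array of report objects")
        for i, row in enumerate(data, start=1):
            rec = _record_from_row(i, row)
            if rec is None:
                n_rejected += 1
            else:
                reports.append(rec)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if n_rejected:
        logger.warning("rejected %d record(s) with empty reaction lists from %s", n_rejected, path)
    rs = ReportSet(reports=reports, source=str(path))
    rs.filters_applied.append(
        FilterRecord("reject_invalid_on_read", "records with no reactions", n_rejected)
    )
    return rs


def _report_to_row(r: CaseReport) -> dict:
    return {
        "report_id": r.report_id,
        "drug": LIST_SEP.join(d.name for d in r.drugs),
        "role": LIST_SEP.join(d.role.value for d in r.drugs),
        "reactions": LIST_SEP.join(r.reactions),
        "sex": r.sex.value,
        "age_group": r.age_group.value,
        "continent": r.continent.value,
        "year": "" if r.year is None else str(r.year),
        "seriousness": LIST_SEP.join(sorted(s.value for s in r.seriousness)),
    }


def write_reports(rs: ReportSet, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write a ReportSet so that ``read_reports`` round-trips it field-for-field."""
    path = Path(path)
    fmt = format or infer_format(path)
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS, quoting=csv.QUOTE_MINIMAL)
            writer.writeheader()
            for r in rs.reports:
                writer.writerow(_report_to_row(r))
    elif fmt == "json":
        payload = []
        for r in rs.reports:
            payload.append(
                {
                    "report_id": r.report_id,
                    "drugs": [{"name": d.name, "role": d.role.value} for d in r.drugs],
                    "reactions": list(r.reactions),
                    "sex": r.sex.value,
                    "age_group": r.age_group.value,
                    "continent": r.continent.value,
                    "year": r.year,
                    "seriousness": sorted(s.value for s in r.seriousness),
                }
            )
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_meddra_map(path: Union[str, Path]) -> MeddraMap:
    """Read a two-column ``pt,soc`` CSV into a MeddraMap.

    SOC order follows first appearance in the file.
    """
    pt_to_soc: dict[str, str] = {}
    soc_order: list[str] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames[:2]] != ["pt", "soc"]:
            raise MalformedRecordError(1, "pt", "expected header 'pt,soc'")
        for i, row in enumerate(reader, start=2):
            pt = _WS.sub(" ", row["pt"].strip())
            soc = _WS.sub(" ", row["soc"].strip())
            if not pt or not soc:
                raise MalformedRecordError(i, "pt" if not pt else "soc", "empty value")
            if pt in pt_to_soc and pt_to_soc[pt] != soc:
                raise MalformedRecordError(i, "pt", f"PT {pt!r} maps to two SOCs")
            if soc not in soc_order:
                soc_order.append(soc)
            pt_to_soc[pt] = soc
    return MeddraMap(pt_to_soc=pt_to_soc, soc_list=tuple(soc_order))


def write_meddra_map(m: MeddraMap, path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pt", "soc"])
        for soc in m.soc_list:
            for pt in sorted(m.pts_in_soc(soc)):
                writer.writerow([pt, soc])
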