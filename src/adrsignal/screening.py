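"""Report screening: primary-suspect selection, deduplication, validity.

VigiAccess-style analyses restrict to reports naming the target drug as the
primary suspect, then drop duplicate and structurally invalid reports.  The
three steps are applied in that order and each is recorded, with its removal
count, in the result's filter trail.
"""

from __future__ import annotations

from .models import FilterRecord, ReportSet


def screen_primary_suspect(rs: ReportSet, drug: str) -> ReportSet:
    """Restrict ``rs`` to reports naming ``drug`` as primary suspect.

    Duplicates (identical ``report_id``) are removed keeping the first
    occurrence; invalid reports (no reactions or no drug entries) are
    removed.  A report listing several primary-suspect drugs is eligible
    whenever the target is among them (no exclusivity requirement).
    Idempotent: screening an already-screened set removes nothing further.
    """
    if not drug or not drug.strip():
        raise ValueError("drug name must be non-empty")
    drug = drug.strip()

    selected = [r for r in rs.reports if r.has_primary_suspect(drug)]
    n_not_primary = len(rs.reports) - len(selected)

    seen: set[str] = set()
    deduped = []
    for r in selected:
        if r.report_id in seen:
            continue
        seen.add(r.report_id)
        deduped.append(r)
    n_dup = len(selected) - len(deduped)

    valid = [r for r in deduped if r.is_valid]
    n_invalid = len(deduped) - len(valid)

    out = rs.with_filter(
        valid,
        FilterRecord("primary_suspect", f"drug={drug}", n_not_primary),
    )
    out.filters_applied.append(FilterRecord("deduplicate", "identical report_id", n_dup))
    out.filters_applied.append(
        FilterRecord("drop_invalid", "no reactions or no drug entries", n_invalid)
    )
    return out
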