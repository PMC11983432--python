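"""Disproportionality signal detection on 2x2 contingency tables.

For a (drug, event) pair in a spontaneous-report universe the 2x2 table is

====  ==========================  ==========================
cell  meaning
====  ==========================  ==========================
a     target drug and target event
b     target drug, other events
c     other drugs, target event
d     other drugs, other events
====  ==========================  ==========================

with N = a+b+c+d, counted at report level (a report mentions the event if
any of its reactions matches).  Four classical algorithms are implemented:

* ROR, the reporting odds ratio ad/bc with log-normal 95% CI
  exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d));
* PRR, the proportional reporting ratio [a/(a+b)]/[c/(c+d)] with the same
  form of CI;
* BCPNN information component IC = log2(a*N/((a+b)(a+c))), its prior-shrunk
  expectation E(IC) under the Bate et al. (1998) Beta/Dirichlet prior, and
  the lower credibility bound IC025 = E(IC) - 1.96*sqrt(V(IC)) with the
  delta-method variance from the same construction;
* EBGM, here the observed/expected ratio a*N/((a+b)(a+c)) with a log-normal
  interval; EBGM05 is the interval's lower bound used one-sidedly.  This is
  the unshrunk O/E ratio, not DuMouchel's Gamma-Poisson mixture posterior;
  the name is kept because it is the label these screening criteria use.

Signal criteria: ROR CI lower bound > 1; PRR >= 2 with CI lower bound > 1;
IC025 > 0; EBGM05 > 2.

Zero cells: point estimates use raw counts whenever defined; when any cell
is zero the Haldane-Anscombe +0.5 continuity correction is applied to all
four cells for the ROR/PRR/EBGM interval computation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional

import pandas as pd

from .models import DrugRole, MeddraMap, ReportSet

Z95 = 1.96
LN2 = math.log(2.0)


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Report counts a, b, c, d for one (drug, event) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected(self, delta: float = 0.5) -> tuple[float, float, float, float]:
        return (self.a + delta, self.b + delta, self.c + delta, self.d + delta)


class RorResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float


class PrrResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float


class IcResult(NamedTuple):
    ic: float
    e_ic: float
    ic025: float


class EbgmResult(NamedTuple):
    estimate: float
    ebgm05: float
    ci_low: float
    ci_high: float


def _lognormal_ci(center: float, cells: tuple[float, float, float, float]) -> tuple[float, float]:
    """exp(ln center +/- 1.96*sqrt(sum 1/cell)); degenerate when center is 0/inf."""
    if center <= 0.0 or math.isinf(center):
        return (0.0, math.inf)
    hw = Z95 * math.sqrt(sum(1.0 / x for x in cells))
    ln = math.log(center)
    return (math.exp(ln - hw), math.exp(ln + hw))


def _ci_cells(t: ContingencyTable) -> tuple[float, float, float, float]:
    if t.has_zero_cell:
        return t.corrected()
    return (float(t.a), float(t.b), float(t.c), float(t.d))


def ror(t: ContingencyTable, continuity: bool = True) -> RorResult:
    """Reporting odds ratio ad/bc with log-normal 95% CI.

    With ``continuity`` (default) the CI is computed on +0.5-corrected cells
    whenever any cell is zero; the point estimate always uses raw counts
    when defined (a=0 -> 0, bc=0 with ad>0 -> inf).
    """
    if t.a == 0:
        est = 0.0
    elif t.b * t.c == 0:
        est = math.inf
    else:
        est = (t.a * t.d) / (t.b * t.c)
    if t.has_zero_cell and not continuity:
        return RorResult(est, 0.0, math.inf)
    cells = _ci_cells(t) if continuity else (float(t.a), float(t.b), float(t.c), float(t.d))
    center = est if not t.has_zero_cell else (cells[0] * cells[3]) / (cells[1] * cells[2])
    low, high = _lognormal_ci(center, cells)
    return RorResult(est, low, high)


def prr(t: ContingencyTable, continuity: bool = True) -> PrrResult:
    """Proportional reporting ratio [a/(a+b)]/[c/(c+d)] with log-normal 95% CI.

    Degenerate margins (a+b = 0 or c+d = 0) yield NaN with a (0, inf)
    interval; c = 0 with a > 0 yields an infinite estimate.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        return PrrResult(math.nan, 0.0, math.inf)
    if t.a == 0:
        est = 0.0
    elif t.c == 0:
        est = math.inf
    else:
        est = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    if t.has_zero_cell and not continuity:
        return PrrResult(est, 0.0, math.inf)
    cells = _ci_cells(t)
    if t.has_zero_cell:
        ca, cb, cc, cd = cells
        center = (ca / (ca + cb)) / (cc / (cc + cd))
    else:
        center = est
    low, high = _lognormal_ci(center, cells)
    return PrrResult(est, low, high)


@dataclass(frozen=True, slots=True)
class BcpnnPrior:
    """Hyperparameters of the BCPNN prior (Bate et al., 1998).

    Marginal drug and event rates carry Beta(alpha1, alpha - alpha1) /
    Beta(beta1, beta - beta1) priors; the joint cell carries pseudo-count
    gamma11 with normalizer gamma chosen per table so that the information
    component shrinks toward independence: E(IC) -> 0 as N grows for a table
    at exact independence.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")

    def gamma(self, t: ContingencyTable) -> float:
        """Joint normalizer tying the joint prior to the margins."""
        n = t.n
        return (
            self.gamma11
            * (n + self.alpha)
            * (n + self.beta)
            / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1))
        )


DEFAULT_PRIOR = BcpnnPrior()


def bcpnn_ic(t: ContingencyTable, prior: BcpnnPrior = DEFAULT_PRIOR) -> IcResult:
    """Observed IC, prior-shrunk E(IC) and lower credibility bound IC025.

    IC = log2(a*N/((a+b)(a+c))) is -inf when a = 0; E(IC) and IC025 remain
    finite through the prior pseudo-counts.
    """
    if t.a + t.b == 0 or t.a + t.c == 0:
        raise ValueError("BCPNN requires non-degenerate drug and event margins")
    n = t.n
    if t.a == 0:
        ic = -math.inf
    else:
        ic = math.log2(t.a * n / ((t.a + t.b) * (t.a + t.c)))

    g = prior.gamma(t)
    e_ic = math.log2(
        (t.a + prior.gamma11)
        * (n + prior.alpha)
        * (n + prior.beta)
        / ((n + g) * (t.a + t.b + prior.alpha1) * (t.a + t.c + prior.beta1))
    )
    # Delta-method variance of the posterior IC (Bate et al., 1998).
    v_ic = (
        (n - t.a + g - prior.gamma11) / ((t.a + prior.gamma11) * (1 + n + g))
        + (n - (t.a + t.b) + prior.alpha - prior.alpha1)
        / ((t.a + t.b + prior.alpha1) * (1 + n + prior.alpha))
        + (n - (t.a + t.c) + prior.beta - prior.beta1)
        / ((t.a + t.c + prior.beta1) * (1 + n + prior.beta))
    ) / (LN2 * LN2)
    ic025 = e_ic - Z95 * math.sqrt(v_ic)
    return IcResult(ic, e_ic, ic025)


def ebgm(t: ContingencyTable, continuity: bool = True) -> EbgmResult:
    """Observed/expected ratio a*N/((a+b)(a+c)) with log-normal interval.

    EBGM05 is the interval's lower bound read one-sidedly.  a = 0 yields a
    zero estimate with a degenerate interval.
    """
    if t.a + t.b == 0 or t.a + t.c == 0:
        return EbgmResult(math.nan, 0.0, 0.0, math.inf)
    est = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    if t.has_zero_cell and not continuity:
        return EbgmResult(est, 0.0, 0.0, math.inf)
    cells = _ci_cells(t)
    if t.has_zero_cell:
        ca, cb, cc, cd = cells
        center = ca * (ca + cb + cc + cd) / ((ca + cb) * (ca + cc))
    else:
        center = est
    low, high = _lognormal_ci(center, cells)
    return EbgmResult(est, low, low, high)


@dataclass(slots=True)
class SignalStatistics:
    """All four disproportionality statistics and criterion flags for one pair."""

    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    prr_ci_low: float
    prr_ci_high: float
    ic: float
    e_ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ebgm_ci_low: float
    ebgm_ci_high: float
    n_reports: int
    table: Optional[ContingencyTable] = None
    degenerate: bool = False
    flag_ror: bool = False
    flag_prr: bool = False
    flag_bcpnn: bool = False
    flag_ebgm: bool = False

    def is_signal(self, rule: Literal["any", "all"] = "any") -> bool:
        flags = (self.flag_ror, self.flag_prr, self.flag_bcpnn, self.flag_ebgm)
        return all(flags) if rule == "all" else any(flags)


def compute_signal_statistics(
    t: ContingencyTable,
    prior: BcpnnPrior = DEFAULT_PRIOR,
    continuity: bool = True,
    min_a: int = 0,
) -> SignalStatistics:
    """Evaluate all four algorithms and their criteria on one table.

    ``min_a`` optionally suppresses flags for pairs with fewer than that
    many co-reports (off by default).  A degenerate table — any zero row or
    column margin, e.g. c = d = 0 in a single-drug universe — produces
    NaN/sentinel statistics with all flags off rather than an exception.
    """
    degenerate = (
        t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0
    )
    r = ror(t, continuity)
    p = prr(t, continuity)
    if degenerate:
        ic_res = IcResult(math.nan, math.nan, math.nan)
    else:
        ic_res = bcpnn_ic(t, prior)
    e = ebgm(t, continuity)

    stats = SignalStatistics(
        ror=r.estimate,
        ror_ci_low=r.ci_low,
        ror_ci_high=r.ci_high,
        prr=p.estimate,
        prr_ci_low=p.ci_low,
        prr_ci_high=p.ci_high,
        ic=ic_res.ic,
        e_ic=ic_res.e_ic,
        ic025=ic_res.ic025,
        ebgm=e.estimate,
        ebgm05=e.ebgm05,
        ebgm_ci_low=e.ci_low,
        ebgm_ci_high=e.ci_high,
        n_reports=t.a,
        table=t,
        degenerate=degenerate,
    )
    if not degenerate and t.a >= min_a:
        stats.flag_ror = stats.ror_ci_low > 1.0
        stats.flag_prr = (not math.isnan(stats.prr)) and stats.prr >= 2.0 and stats.prr_ci_low > 1.0
        stats.flag_bcpnn = stats.ic025 > 0.0
        stats.flag_ebgm = stats.ebgm05 > 2.0
    return stats


class UnknownEventError(KeyError):
    """The event selector matches no known PT or SOC."""


def _universe_pass(rs_all: ReportSet, drug: str):
    """One pass over the universe: per-report drug membership and reaction sets."""
    for r in rs_all.reports:
        yield r.has_primary_suspect(drug), frozenset(r.reactions)


def build_contingency(
    rs_all: ReportSet,
    drug: str,
    event: str,
    map: MeddraMap,
) -> ContingencyTable:
    """2x2 table for (drug, event) against the full multi-drug universe.

    ``event`` is a PT or a SOC name; a SOC selector matches any PT mapping
    to it.  ``rs_all`` must be the unscreened universe: the b/c/d cells are
    completed from every other report in it.
    """
    if event in map.soc_list:
        targets = map.pts_in_soc(event)
    elif event in map or any(event in r.reactions for r in rs_all.reports):
        targets = frozenset([event])
    else:
        raise UnknownEventError(f"event {event!r} matches no known PT or SOC")

    a = b = c = d = 0
    for is_drug, reactions in _universe_pass(rs_all, drug):
        has_event = not targets.isdisjoint(reactions)
        if is_drug and has_event:
            a += 1
        elif is_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def contingency_tables(
    rs_all: ReportSet,
    drug: str,
    map: MeddraMap,
    level: Literal["pt", "soc"] = "pt",
) -> dict[str, ContingencyTable]:
    """All (drug, event) tables for events observed with the drug, in one pass.

    At SOC level each report's reactions are lifted through the PT->SOC map
    (unmapped PTs are ignored at this level).
    """
    n_total = len(rs_all.reports)
    n_drug = 0
    event_total: dict[str, int] = {}
    event_drug: dict[str, int] = {}
    for r in rs_all.reports:
        is_drug = r.has_primary_suspect(drug)
        n_drug += is_drug
        if level == "pt":
            events = set(r.reactions)
        else:
            events = {map.soc_of(pt) for pt in r.reactions}
            events.discard(None)
        for ev in events:
            event_total[ev] = event_total.get(ev, 0) + 1
            if is_drug:
                event_drug[ev] = event_drug.get(ev, 0) + 1
    tables = {}
    for ev, a in sorted(event_drug.items()):
        b = n_drug - a
        c = event_total[ev] - a
        d = n_total - a - b - c
        tables[ev] = ContingencyTable(a, b, c, d)
    return tables


def detect_signals(
    rs_all: ReportSet,
    drug: str,
    map: MeddraMap,
    level: Literal["pt", "soc"] = "pt",
    prior: BcpnnPrior = DEFAULT_PRIOR,
    continuity: bool = True,
    min_a: int = 0,
) -> list[tuple[str, SignalStatistics]]:
    """Signal statistics for every event observed with ``drug``.

    Returns (event, SignalStatistics) pairs sorted by event name; empty
    when the drug is absent from the universe.
    """
    tables = contingency_tables(rs_all, drug, map, level)
    return [
        (ev, compute_signal_statistics(t, prior=prior, continuity=continuity, min_a=min_a))
        for ev, t in tables.items()
    ]


def signal_frame(
    results: list[tuple[str, SignalStatistics]],
    map: MeddraMap,
    drug: str = "",
    level: Literal["pt", "soc"] = "pt",
) -> pd.DataFrame:
    """Tabular rendering of detection results (one row per event)."""
    rows = []
    for ev, s in results:
        rows.append(
            {
                "drug": drug,
                "event": ev,
                "soc": ev if level == "soc" else (map.soc_of(ev) or ""),
                "a": s.n_reports,
                "b": s.table.b if s.table else None,
                "c": s.table.c if s.table else None,
                "d": s.table.d if s.table else None,
                "ror": s.ror,
                "ror_l": s.ror_ci_low,
                "ror_u": s.ror_ci_high,
                "prr": s.prr,
                "prr_l": s.prr_ci_low,
                "prr_u": s.prr_ci_high,
                "ic": s.ic,
                "ic025": s.ic025,
                "ebgm": s.ebgm,
                "ebgm05": s.ebgm05,
                "flag_ror": s.flag_ror,
                "flag_prr": s.flag_prr,
                "flag_bcpnn": s.flag_bcpnn,
                "flag_ebgm": s.flag_ebgm,
                "signal_any": s.is_signal("any"),
                "signal_all": s.is_signal("all"),
            }
        )
    return pd.DataFrame(rows)
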