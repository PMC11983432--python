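"""Synthetic spontaneous-report databases with known ground truth.

The generator emulates the structure of a VigiAccess-style database: a
multi-drug universe with market-share report volumes, multi-reaction
reports drawn from a weighted PT catalog, report-level demographics with
margins matching the published apalutamide column, independent seriousness
outcomes, and planted drug-event associations of known strength.

Sampling model (per report, all reports independent):

* suspect drug ~ categorical(market shares); each report names a single
  primary-suspect drug;
* number of reactions k ~ geometric(1/mean_reactions) truncated at the
  catalog size (so k >= 1);
* the k reactions are drawn without replacement from the catalog with
  weight background * rr_multiplier for planted (drug, PT) pairs and
  background otherwise, via the Gumbel top-k (successive-sampling) trick;
* sex/age/continent/year ~ the configured categorical margins,
  independent of drug and reactions;
* each seriousness outcome is an independent Bernoulli.

Identical seed and config give byte-identical serialized output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import datasets
from .models import (
    AgeGroup,
    CaseReport,
    Continent,
    DrugEntry,
    DrugRole,
    MeddraMap,
    ReportSet,
    Seriousness,
    Sex,
)


@dataclass(frozen=True, slots=True)
class GeneratorConfig:
    """Full specification of one synthetic report universe."""

    n_reports: int
    drugs: tuple[tuple[str, float], ...]
    pt_catalog: tuple[tuple[str, str, float], ...]  # (PT, SOC, background weight)
    planted: tuple[tuple[str, str, float], ...] = ()  # (drug, PT, rr >= 1)
    mean_reactions: float = 1.83
    sex_probs: tuple[tuple[Sex, float], ...] = (
        (Sex.FEMALE, 0.0031), (Sex.MALE, 0.9388), (Sex.UNKNOWN, 0.0581),
    )
    age_probs: tuple[tuple[AgeGroup, float], ...] = (
        (AgeGroup.LT18, 0.0003), (AgeGroup.A18_44, 0.0009), (AgeGroup.A45_64, 0.0630),
        (AgeGroup.A65_74, 0.1936), (AgeGroup.GE75, 0.3165), (AgeGroup.UNKNOWN, 0.4257),
    )
    continent_probs: tuple[tuple[Continent, float], ...] = (
        (Continent.AFRICA, 0.0123), (Continent.AMERICAS, 0.5180), (Continent.ASIA, 0.1431),
        (Continent.EUROPE, 0.3252), (Continent.OCEANIA, 0.0014),
    )
    year_probs: tuple[tuple[int, float], ...] = (
        (2016, 0.0003), (2017, 0.0003), (2018, 0.0065), (2019, 0.0737), (2020, 0.0953),
        (2021, 0.1150), (2022, 0.1913), (2023, 0.2083), (2024, 0.3093),
    )
    seriousness_probs: tuple[tuple[Seriousness, float], ...] = (
        (Seriousness.DEATH, 0.04), (Seriousness.HOSPITALIZATION, 0.03),
        (Seriousness.DISABILITY, 0.005),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        if not self.drugs or any(w <= 0 for _, w in self.drugs):
            raise ValueError("drug market-share weights must be positive")
        if not self.pt_catalog or any(w <= 0 for _, _, w in self.pt_catalog):
            raise ValueError("PT background weights must be positive")
        if self.mean_reactions < 1.0:
            raise ValueError("mean_reactions must be >= 1")
        drug_names = {d for d, _ in self.drugs}
        pt_names = {p for p, _, _ in self.pt_catalog}
        if len(drug_names) != len(self.drugs) or len(pt_names) != len(self.pt_catalog):
            raise ValueError("duplicate drug or PT in config")
        for drug, pt, rr in self.planted:
            if drug not in drug_names:
                raise ValueError(f"planted pair references unknown drug {drug!r}")
            if pt not in pt_names:
                raise ValueError(f"planted pair references unknown PT {pt!r}")
            if rr < 1.0:
                raise ValueError("rr_multiplier must be >= 1")
        for probs in (self.sex_probs, self.age_probs, self.continent_probs,
                      self.year_probs):
            total = sum(p for _, p in probs)
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
                raise ValueError("categorical probabilities must sum to 1")
        if any(not 0.0 <= p <= 1.0 for _, p in self.seriousness_probs):
            raise ValueError("seriousness probabilities must lie in [0, 1]")

    def meddra_map(self) -> MeddraMap:
        """The PT->SOC map implied by the catalog."""
        pt_to_soc = {pt: soc for pt, soc, _ in self.pt_catalog}
        soc_list = []
        for _, soc, _ in self.pt_catalog:
            if soc not in soc_list:
                soc_list.append(soc)
        return MeddraMap(pt_to_soc=pt_to_soc, soc_list=tuple(soc_list))


@dataclass(frozen=True, slots=True)
class GroundTruth:
    """Planted associations with analytic expected and realized co-report counts."""

    planted: tuple[tuple[str, str, float], ...]
    expected_counts: dict[tuple[str, str], float] = field(default_factory=dict)
    realized_counts: dict[tuple[str, str], int] = field(default_factory=dict)


def default_config(n_reports: int = 5_000, seed: int = 0, **overrides) -> GeneratorConfig:
    """Default universe mirroring the published three-drug database.

    Market shares follow the published report volumes; the PT catalog is
    the apalutamide top-20 PT list with background weights proportional to
    the printed report rates; demographic margins follow the apalutamide
    column of the published demographics (illustrative, not inferential).
    """
    total = sum(datasets.REPORT_COUNTS.values())
    drugs = tuple((d, datasets.REPORT_COUNTS[d] / total) for d in datasets.DRUGS)
    mmap = datasets.reference_meddra_map()
    catalog = tuple(
        (pt, mmap.soc_of(pt) or "Unknown SOC", float(rate))
        for pt, rate in datasets.TOP20["apalutamide"]
    )
    return GeneratorConfig(
        n_reports=n_reports, drugs=drugs, pt_catalog=catalog, seed=seed, **overrides
    )


def null_universe_config(n_reports: int = 5_000, seed: int = 0) -> GeneratorConfig:
    """Independence benchmark: three drugs, 20 equal-weight PTs, no plants."""
    cfg = default_config(n_reports=n_reports, seed=seed)
    flat = tuple((pt, soc, 1.0) for pt, soc, _ in cfg.pt_catalog)
    return replace(cfg, pt_catalog=flat, planted=())


#: Benchmark plant: PT and drug used by the recovery study.
RECOVERY_PAIR = ("darolutamide", "Rash")


def planted_universe_config(
    rr: float, n_reports: int = 20_000, seed: int = 0
) -> GeneratorConfig:
    """Recovery benchmark: one planted association on a low-share drug.

    Market shares (0.15, 0.05, 0.80) put the plant on a 5%-share drug so
    the planted pair's observed/expected ratio is not diluted by the drug's
    own contribution to the event background; 20 equal-background PTs and
    1.5 mean reactions per report keep the per-pair counts large enough
    (expected a ~ 300 at rr = 5) for all four interval criteria to be
    informative.
    """
    cfg = default_config(n_reports=n_reports, seed=seed)
    flat = tuple((pt, soc, 1.0) for pt, soc, _ in cfg.pt_catalog)
    drug, pt = RECOVERY_PAIR
    return replace(
        cfg,
        drugs=(("apalutamide", 0.15), ("darolutamide", 0.05), ("enzalutamide", 0.80)),
        pt_catalog=flat,
        planted=((drug, pt, rr),),
        mean_reactions=1.5,
    )


def _expected_pair_count(cfg: GeneratorConfig, drug: str, pt: str, rr: float) -> float:
    """Analytic approximation of E[a] for a planted pair.

    Treats the truncated geometric draw count as its untruncated mean and
    the without-replacement draws as independent: E[a] ~ n * share *
    (1 - (1 - w/W)^mean_reactions) with w the planted weight and W the
    drug's total catalog weight.
    """
    share = dict(cfg.drugs)[drug] / sum(w for _, w in cfg.drugs)
    weights = {p: w for p, _, w in cfg.pt_catalog}
    w = weights[pt] * rr
    total_w = sum(weights.values()) - weights[pt] + w
    p_event = 1.0 - (1.0 - w / total_w) ** cfg.mean_reactions
    return cfg.n_reports * share * p_event


def generate(
    cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[ReportSet, GroundTruth]:
    """Draw one synthetic report universe.

    A fresh generator seeded from ``cfg.seed`` is used unless ``rng`` is
    supplied, so identical configs yield identical universes.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_reports
    drug_names = [d for d, _ in cfg.drugs]
    shares = np.array([w for _, w in cfg.drugs], dtype=float)
    shares /= shares.sum()
    pt_names = [p for p, _, _ in cfg.pt_catalog]
    n_pts = len(pt_names)

    # Per-drug reaction weights, with planted multipliers applied.
    weights = np.tile(np.array([w for _, _, w in cfg.pt_catalog], dtype=float), (len(drug_names), 1))
    pt_index = {p: j for j, p in enumerate(pt_names)}
    drug_index = {d: i for i, d in enumerate(drug_names)}
    for drug, pt, rr in cfg.planted:
        weights[drug_index[drug], pt_index[pt]] *= rr

    drug_idx = rng.choice(len(drug_names), size=n, p=shares)
    k = np.minimum(rng.geometric(1.0 / cfg.mean_reactions, size=n), n_pts)

    # Gumbel top-k: taking the k largest log(w)+Gumbel keys per row is
    # equivalent to sequential weighted sampling without replacement.
    keys = np.log(weights[drug_idx]) + rng.gumbel(size=(n, n_pts))
    order = np.argsort(-keys, axis=1)

    sex_vals = [s for s, _ in cfg.sex_probs]
    sex_draw = rng.choice(len(sex_vals), size=n, p=np.array([p for _, p in cfg.sex_probs]))
    age_vals = [a for a, _ in cfg.age_probs]
    age_draw = rng.choice(len(age_vals), size=n, p=np.array([p for _, p in cfg.age_probs]))
    cont_vals = [c for c, _ in cfg.continent_probs]
    cont_draw = rng.choice(len(cont_vals), size=n, p=np.array([p for _, p in cfg.continent_probs]))
    year_vals = [y for y, _ in cfg.year_probs]
    year_draw = rng.choice(len(year_vals), size=n, p=np.array([p for _, p in cfg.year_probs]))
    serious_vals = [s for s, _ in cfg.seriousness_probs]
    serious_draw = rng.random(size=(n, len(serious_vals))) < np.array(
        [p for _, p in cfg.seriousness_probs]
    )

    none_set = frozenset([Seriousness.NONE_REPORTED])
    reports = []
    for i in range(n):
        hits = serious_draw[i]
        seriousness = (
            frozenset(s for s, h in zip(serious_vals, hits) if h) if hits.any() else none_set
        )
        reports.append(
            CaseReport(
                report_id=f"R{i:07d}",
                drugs=(DrugEntry(drug_names[drug_idx[i]], DrugRole.PRIMARY_SUSPECT),),
                reactions=tuple(pt_names[j] for j in order[i, : k[i]]),
                sex=sex_vals[sex_draw[i]],
                age_group=age_vals[age_draw[i]],
                continent=cont_vals[cont_draw[i]],
                year=int(year_vals[year_draw[i]]),
                seriousness=seriousness,
            )
        )

    realized: dict[tuple[str, str], int] = {}
    expected: dict[tuple[str, str], float] = {}
    for drug, pt, rr in cfg.planted:
        di, pj = drug_index[drug], pt_index[pt]
        realized[(drug, pt)] = int(
            sum(
                1
                for i in range(n)
                if drug_idx[i] == di and pj in order[i, : k[i]]
            )
        )
        expected[(drug, pt)] = _expected_pair_count(cfg, drug, pt, rr)

    rs = ReportSet(reports=reports, source=f"synthetic(seed={cfg.seed}, n={n})")
    truth = GroundTruth(planted=cfg.planted, expected_counts=expected, realized_counts=realized)
    return rs, truth
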