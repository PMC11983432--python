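# Methods

This note documents the statistical model, the conventions the package
freezes, the synthetic-data generator, and the design choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Report model and screening

An individual case safety report (ICSR) links one or more drugs — each with
a reporter-assigned role (primary suspect, secondary suspect, concomitant,
interacting) — to one or more adverse reactions coded as MedDRA preferred
terms (PTs), plus demographics (sex, age band, continent, report year) and
seriousness outcomes (death, hospitalization, disability). PTs roll up to
system organ classes (SOCs) through a one-to-many PT→SOC map; the bundled
map is a toy two-level hierarchy covering the 26 analyzed SOCs and the ~300
PTs that appear in the published signal tables, standing in for licensed
MedDRA.

Screening to a target drug applies three steps in order, each recorded with
its removal count: keep reports naming the target as primary suspect
(without exclusivity — a report listing several primary suspects is
eligible whenever the target is among them); drop duplicate `report_id`s
keeping the first occurrence (public portals deduplicate upstream, so
exact-id match is the only duplicate definition implemented; fuzzy case
linkage is out of scope); drop structurally invalid reports (no reactions
or no drug entries — the minimal structural definition, since no richer
definition of "invalid" is available for the source data). Screening is
idempotent and never alters surviving records.

Free-text fields are normalized before enum lookup (trim, collapse internal
whitespace, casefold, en-dash → hyphen) against frozen synonym tables
(`adrsignal.io`); anything unrecognized maps to the `unknown` member rather
than being dropped, so denominators are conserved.

## Denominator conventions and rounding

Two denominators coexist and are distinct code paths:

* **report-level** — number of reports; used for demographic tables;
* **reaction-level** — total PT occurrences (a report with k reactions
  contributes k); used for SOC incidence, and by default for top-PT rates
  and serious-AE rates.

The published summaries pair the reaction-level N with both the SOC rates
and the serious-AE rates, and the top-PT "report rate" is only plausible
against the reaction-level N (e.g. a 9.93% rash rate ≈ 2,082/20,965), so
reaction-level is the default; `denominator="reports"` switches both the
top-PT and serious-AE paths to the report-level alternative. On a
collection where every report has exactly one reaction the two coincide
(tested). Serious-outcome counts are non-exclusive: a report with death and
hospitalization counts toward both.

Percentages are computed in exact decimal arithmetic and rounded **half-up
to two decimals**, which reproduces every printed demographic cell and all
but four SOC cells of the published tables (the four are internally
inconsistent in the source by +0.01 and are pinned as errata in
`adrsignal.datasets.PERCENT_ERRATA`). The year axis bins everything before
2017 into a single "Before 2017" stratum, mirroring the published layout.

## Disproportionality statistics

All four algorithms operate on the report-level 2×2 table for a (drug,
event) pair against the full multi-drug universe supplied by the caller —
the package does not attempt to model the full VigiBase background beyond
that universe. An event selector is a PT or a SOC (matching any PT under
it).

* **ROR** = ad/bc with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = [a/(a+b)]/[c/(c+d)] with the same CI form.
* **BCPNN**: observed IC = log₂(aN/((a+b)(a+c))); the shrunk expectation
  E(IC) = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))] with the Bate
  et al. (1998) defaults α₁=β₁=γ₁₁=1, α=β=2 and the per-table joint
  normalizer γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)); IC025 = E(IC) −
  1.96·√V(IC) with the same paper's delta-method variance. Under this
  construction E(IC) at exact independence is not identically zero but
  O(1/N) (≈ −0.0015 at N = 10⁵); the observed IC is exactly zero there.
* **EBGM**: here the *unshrunk* observed/expected ratio aN/((a+b)(a+c))
  with a log-normal interval, EBGM05 being the interval's lower bound read
  one-sidedly. This deliberately diverges from DuMouchel's terminology:
  the full Gamma–Poisson mixture posterior is not implemented, because the
  screening convention being reproduced defines EBGM by the O/E formula.
  Note the algebraic identity EBGM = 2^IC for every table (both formulas
  reduce to O/E); it is asserted to machine precision in the tests.

Signal criteria: ROR CI lower bound > 1 (the "95%CI>1" convention read as
the lower bound, the universal reading); PRR ≥ 2 with CI lower bound > 1;
IC025 > 0; EBGM05 > 2. A pair is a *signal* if at least one criterion
fires ("any", the default) or all four ("all", used where low false-positive
rates matter, e.g. the planted-recovery benchmark). No minimum co-report
floor is imposed by default; `min_a` exposes one.

Numerical edge cases: a=0 gives point estimates 0 (ROR/PRR/EBGM) and IC =
−∞ while E(IC)/IC025 stay finite through the prior; c=0 gives an infinite
PRR sentinel; any zero cell triggers the Haldane–Anscombe +0.5 correction
on all four cells *for interval computation only* (standard practice; the
source conventions are silent), with a toggle to disable it; a table with
any zero row or column margin (e.g. a single-drug universe, where c=d=0)
is marked degenerate — statistics are reported as NaN/sentinels and all
flags are off, with no exception raised.

A caution on monotonicity: ROR and PRR are strictly increasing in a with
b, c, d fixed, but the O/E ratio behind IC/EBGM is not in general, because
a also inflates both margins; it is strictly increasing whenever b, c ≥ a,
which covers every realistic screening table (a drug's co-reports are a
minority of its reports and of the event's reports). The property tests
assert exactly these statements.

## Cross-drug comparison

Given per-drug PT-level signal sets, the union of signalled PTs is split
into *shared* (signalled for every drug; grouped by SOC, SOCs ranked by
shared count with lexicographic tie-break), *drug-exclusive* (signalled for
exactly one drug — the reading of the published "different ADRs" table,
which leaves cells blank rather than listing partial overlaps), and
*partially shared* (≥2 but not all drugs; reported separately because it
belongs in neither headline table). Conservation (each drug's signal count
= shared + its exclusive + its partial) and permutation invariance are
tested. PT matching is exact after field normalization; no synonym
resolution is attempted.

## Synthetic-report generator

The generator emulates the structure of the public database: per report,
a single primary-suspect drug drawn by market share; a reaction count from
a geometric distribution (mean 1.83 by default, the overall
reactions-per-report ratio of the bundled counts) truncated at the catalog
size; reactions drawn without replacement (PT lists never repeat, matching
portal PT counting) from a weighted catalog where planted (drug, PT) pairs
have their background weight multiplied by rr; demographics and seriousness
independent of drug and reactions. Without-replacement weighted sampling is
vectorized with the Gumbel top-k trick. Default market shares follow the
published report volumes; the default catalog is the apalutamide top-20 PT
list weighted by printed rates; default demographic margins are transcribed
from the apalutamide column (illustrative, not inferential). Identical seed
and config give identical universes.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: reporting delays and year trends, the Weber
effect, drug–demographic and reaction–reaction dependence, duplicate and
partially-filled reports, country-level geography, and masking by
co-reported drugs. A hook exists for age-dependent reaction weights (off by
default; no joint distribution is published to calibrate it).

The analytic expectation attached to each planted pair treats the truncated
draw count as its mean and the draws as independent — adequate for the
catalog sizes used here (relative error well under the binomial noise at
the tested sizes) — and is checked against realized counts in the tests.
Because a planted drug's own reports inflate the event background, the
observed/expected ratio of a planted pair is systematically below the
planted rr; the planted ROR tracks rr much more closely. This dilution is
why the recovery benchmark plants on a low-share drug.

## Benchmark designs

* **Null calibration**: 200 universes of 5,000 reports, 3 drugs at the
  published market shares, 20 equal-weight PTs, no plants. Per-pair flag
  rates are measured over all 3×20 pairs per universe. The ROR criterion is
  a one-sided ~2.5% test under independence, so its rate is required to
  stay ≤ 5%.
* **Planted recovery**: 100 universes of 20,000 reports, shares
  (0.15, 0.05, 0.80) with one pair planted at rr = 5 on the 0.05-share
  drug, 20 equal-background PTs, mean 1.5 reactions/report. These sizes
  were chosen analytically before measurement so that the weakest
  criterion, EBGM05 > 2, has true EBGM ≈ 3.5 with expected a ≈ 300 —
  comfortably detectable — while expected a stays far above the a ≥ 20
  premise. All four criteria are required to fire jointly in ≥ 95% of
  replicates, and joint sensitivity must be non-decreasing in rr over
  {1, 2, 5, 10}.

Problem sizes throughout (replicate counts, universe sizes, the 625-table
oracle grid) are the package's own benchmark choices, balancing
Monte-Carlo error against a test suite that completes in a few minutes on
one CPU.

## Known limitations

* EBGM here is the unshrunk O/E ratio (see above); small-count pairs are
  therefore noisier than under a true empirical-Bayes shrinker.
* IC025 uses a delta-method normal approximation, not posterior sampling.
* The bundled PT→SOC map is a reconstruction from published tables, not
  licensed MedDRA; PT coverage outside those tables maps to an explicit
  unmapped bucket.
* Dataset-level headline numbers that depend on unpublished record-level
  data (total shared-signal count across the three real drugs, serious-AE
  outcome splits, per-pair signal values) cannot be recomputed from the
  published aggregates; the published shared/unique signal *lists* are
  instead checked for internal consistency, with two pinned source errata
  (four percent cells, one shared-count row) documented in
  `adrsignal.datasets`.
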