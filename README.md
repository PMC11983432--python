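# adrsignal

Pharmacovigilance signal detection and adverse-drug-reaction (ADR) profiling
for spontaneous-report databases, built around the public WHO-VigiAccess view
of individual case safety reports (ICSRs). The package screens report
collections to primary-suspect reports for a target drug, produces the
standard descriptive outputs (demographic distributions, system-organ-class
incidence, top-N preferred-term tables, serious-AE rates), runs
four-algorithm disproportionality analysis, and compares signal profiles
across drugs. It ships a synthetic-report generator with planted
associations so every stage is testable without access to record-level data,
plus the published VigiAccess summary counts for three androgen antagonists
(apalutamide, darolutamide, enzalutamide) as regression fixtures.

Intended users: pharmacoepidemiologists and drug-safety analysts who want a
reproducible, scriptable version of the VigiAccess-style screening /
profiling / disproportionality workflow.

## The statistics

For a drug–event pair, reports are cross-classified into the 2×2 table
(a = drug & event, b = drug & other events, c = other drugs & event,
d = neither; N = a+b+c+d). Four classical disproportionality measures are
computed, each with its conventional signal criterion:

| Measure | Formula | Signal criterion |
|---|---|---|
| ROR | ad/bc, 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | CI lower bound > 1 |
| PRR | [a/(a+b)] / [c/(c+d)], same CI form | PRR ≥ 2 and CI lower bound > 1 |
| BCPNN IC | IC = log₂(aN/((a+b)(a+c))), shrunk E(IC) and IC025 under the Bate et al. (1998) prior | IC025 > 0 |
| EBGM | observed/expected aN/((a+b)(a+c)) with log-normal interval | EBGM05 > 2 |

Zero cells get a Haldane–Anscombe +0.5 correction for interval computation
only; point estimates stay on raw counts. See `docs/methods.md` for the
prior, the variance approximation, denominator conventions, and the
deliberate divergence of this EBGM from DuMouchel's Gamma–Poisson shrinker.

## Worked example

Simulate a 20,000-report universe with one planted association
(darolutamide–Rash, relative risk 5) and detect it:

```python
import adrsignal as ads

cfg = ads.planted_universe_config(rr=5.0, n_reports=20_000, seed=42)
reports, truth = ads.generate(cfg)
stats = dict(ads.detect_signals(reports, "darolutamide", cfg.meddra_map()))["Rash"]
print(f"ROR  {stats.ror:6.2f}  (95% CI {stats.ror_ci_low:.2f}-{stats.ror_ci_high:.2f})  flag={stats.flag_ror}")
# ... analogous lines for PRR / IC / EBGM
```

Output:

```
universe: 20000 reports; 30086 reactions
planted: (('darolutamide', 'Rash', 5.0),) expected a ~ 295.6 realized a = 292
ROR    4.96  (95% CI 4.28-5.74)  flag=True
PRR    3.84  (95% CI 3.32-4.44)  flag=True
IC     1.74  (IC025 1.53)                flag=True
EBGM   3.35  (EBGM05 2.89)               flag=True
signal (all four): True
```

The planted pair is co-reported 292 times (analytic expectation ≈ 296); all
four criteria flag it. The observed ROR (≈5) tracks the planted relative
risk, while the observed/expected ratio (EBGM ≈ 3.3) is lower because the
planted drug's own reports inflate the event background — see
`docs/methods.md`.

The bundled published counts work the same way; the apalutamide sex
distribution reproduces the printed percentages exactly:

```python
from adrsignal.datasets import demographic_fixture
print(demographic_fixture("apalutamide", "sex").to_frame().to_string(index=False))
```

```
stratum  count  denominator  percent
 Female     35        11452     0.31
   Male  10751        11452    93.88
Unknown    666        11452     5.82
```

## Command line

The `adrsignal` console script exposes the pipeline stages:

```
adrsignal simulate --n-reports 5000 --seed 1 --out reports.csv --truth truth.json
adrsignal screen --in reports.csv --drug enzalutamide --out screened.csv
adrsignal profile demographics --in reports.csv --drug enzalutamide --axis sex
adrsignal signals detect --drug enzalutamide --universe reports.csv --out signals.csv
adrsignal compare --signals a.csv --signals b.csv --signals c.csv --out-dir cmp/
adrsignal run-all --config pipeline.yaml
```

`run-all` executes simulate/ingest → screen → profile → detect → compare
from one YAML config and writes a results directory with a manifest
(config hash, seed, version).

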