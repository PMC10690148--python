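# edisim

In-silico comparison of vaccine dosing regimens for protein subunit
immunogens: how splitting one dose over time — a 7-shot escalating course,
a two-shot "extended prime" (20% at day 0, 80% at day 7), or a slow-release
second dose — changes T-cell priming and the germinal-center (GC) antibody
response, relative to a single bolus injection.

The package is aimed at computational immunologists and vaccine-delivery
researchers who want a transparent, desk-scale model of why extended-prime
schedules outperform bolus injection, and a sandbox for exploring dosing
patterns that would be expensive to test in animals.

Two models share one representation of a dosing schedule:

* **Priming model** (`edisim.priming`) — a deterministic ODE model of
  adjuvant-driven innate activation, dendritic-cell (DC) recruitment,
  activation/antigen-loading of DCs (requiring adjuvant *and* antigen
  simultaneously), saturating T-cell proliferation and Tfh
  differentiation.  Two parameters — the DC recruitment rate and the
  baseline T-cell count — are fit to day-14 Tfh counts across regimens by
  log-scale least squares.
* **GC model** (`edisim.gc`) — a stochastic lymph-node model in which
  intact ("native") antigen degrades with a 6.2-hour half-life into a
  partially degraded ("non-native") immunodominant form; antibody produced
  by GC-derived plasma cells captures soluble antigen of its matching
  specificity onto follicular dendritic cells (FDCs) as immune complexes,
  where it is protected from degradation and fuels competitive, agent-based
  B-cell selection in a set of capacity-limited GCs.

The central quantity of the GC model is the affinity-weighted antibody
titer, `titer = Σ concentration · 10^(affinity − a_ref)` on a −log10 Kd
scale, which drives cooperative immune-complex deposition on FDCs — so the
*timing* of antigen arrival relative to the antibody response determines how
much intact antigen reaches the follicles.

A synthetic-cohort generator (`edisim.synthetic`) emulates per-animal
readouts with mean-preserving lognormal noise so the fitting pipeline is
testable end to end, and `edisim.experiments` orchestrates the canned
analyses with full metadata for reproducibility.

## Worked example

Simulate the optimized two-shot extended prime (20% day 0 / 80% day 7) with
both models:

```bash
$ edisim priming --regimen 2ed --t-end 21 --out demo_priming
peak Tfh: 4760.9 cells; wrote demo_priming/trajectory.csv

$ edisim gc --regimen 2ed --t-end 21 --reps 5 --seed 1 --out demo_gc
day 21: GC B cells 2855, native IC fraction 36.0%; wrote demo_gc/mean.csv
```

The priming run reports a peak Tfh count of ~4,800 cells — about 6.6-fold
above the bolus value with the same parameters (`--regimen bolus` gives
~720), reproducing the strong Tfh amplification of extended-prime dosing.
The GC run reports that at day 21 roughly 36% of the antigen held on FDCs
as immune complexes is still intact: the day-7 second dose arrives when
antibody titers are modest, so most of it degrades before capture.  Asking
for a 10-day slow release of the second dose instead:

```bash
$ edisim gc --regimen 2ed --release-days 10 --t-end 21 --reps 5 --seed 1 --out demo_ext
```

raises the intact share to ~86%, because most of the antigen now arrives
after high-affinity antibody has developed.  Regimen shorthands accepted
everywhere: `bolus`, `7ed`, `2ed`, `2ed-ext:<days>`, `ned:<n>`,
`2dose:<frac>:<interval>`; YAML/JSON regimen files also work.

The library interface mirrors the CLI:

```python
from edisim import GCParams, make_two_dose, native_ic_fraction, simulate_gc

out = simulate_gc(GCParams(), make_two_dose(0.2, 7.0), t_end=21.0,
                  n_replicates=10, seed=1)
print(native_ic_fraction(out, 21.0))   # ~0.37
```

Named experiments (priming panels, GC panels, release-duration sweep,
adjuvant-mismatch check, fit demo) run via
`edisim experiment --name release_sweep --out results/` and write CSV
tables plus manifest/metadata JSON.

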