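# Methods

`edisim` simulates the immunological consequences of splitting a protein
subunit vaccine dose over time.  It contains two independent models that act
on the same dosing-schedule objects: a deterministic kinetic model of T
follicular helper (Tfh) cell priming, and a hybrid
deterministic–stochastic model of the germinal center (GC) response with
antigen degradation and antibody-mediated antigen capture on follicular
dendritic cells (FDCs).  This note records the model equations, the meaning
and provenance of the default parameters, the design choices made where the
design was genuinely open, and what the test suite does and does not
establish.

## Dosing regimens

A regimen is a list of dose events; each event delivers a fraction of the
total antigen and/or adjuvant dose at a start day, either instantaneously
(impulse) or at a constant rate over a window.  Constructors cover the
regimens of interest:

* **bolus** — everything at day 0;
* **n-dose escalating** — impulses with amounts proportional to `e^k` for
  injection index `k = 0..n-1`, normalized to the total.  This rule is
  adopted because for 7 doses it gives a final-injection share of
  `e^6 / Σ e^k = 63.3%`, matching the canonical escalating protocol in
  which the last of 7 injections on day 12 carries 63% of the dose;
  per-doubling escalation (1, 2, 4, …) would give 50.4% and is not used.
  The dose-number series keeps the 12-day span fixed and rescales the
  interval (`12/(n-1)`), matching the published comparison in which the
  escalation pattern and total window were held constant;
* **two-dose extended prime (2-ED)** — fraction `f` at day 0 and `1-f` at a
  chosen interval; `f = 0.2`, interval 7 d is the optimized regimen;
* **extended release** — any event can be converted to a zero-order release
  of the same amount over a chosen duration (a depot-release second dose);
  when the event carries both components, only the antigen is extended and
  the adjuvant remains an impulse, since depot formulations anchor the
  immunogen;
* **mismatched schedules** — independent antigen and adjuvant schedules,
  used to probe the requirement that the two arrive together.

Amounts are conserved exactly: antigen and adjuvant amounts each sum to the
configured total, and converting an impulse to a release preserves its
amount identically.

## Priming model

Seven compartments: adjuvant `A`, antigen `G`, activated innate/tissue
cells `I` (a single proxy for the cytokine/chemokine response), dendritic
cells `D`, activated antigen-loaded DCs `D*`, antigen-specific T cells `T`,
and Tfh cells `F`:

    A' = u_A(t) − δ_A A
    G' = u_G(t) − δ_G G
    I' = k_I A − δ_I I
    D' = k_DC I − δ_D (D − D0)
    D*' = k_u · [A/(A+K_A)] · [G/(G+K_G)] · D − δ_* D*
    T' = ρ · [D*/(D*+K_T)] T − δ_T (T − T0)
    F' = k_F T − δ_F F

Impulse doses are additive jumps in `A`/`G`; the stiff LSODA integrator is
restarted at every dose boundary so each segment is smooth.  Doubling the
integration tolerances changes outputs by far less than 0.1%.

The product saturation in `D*` encodes the requirement that adjuvant and
antigen be present simultaneously for DCs to become activated and loaded;
either one alone produces no `D*` and hence no T-cell expansion.  Tfh
differentiation is a constant per-capita rate that does not deplete the
proliferating pool (a depleting variant is available via
`tfh_depletes_tcells=True`).

Default parameters are order-of-magnitude choices set once so that the
model's qualitative behaviour matches what is known about this system:
site clearance of adjuvant and antigen with ~0.5-day half-life
(`δ_A = δ_G = 1.5/d`), DC excursions that peak within ~1 day of a bolus and
return to within 5% of baseline before a day-7 second dose
(`δ_D = 0.8/d`, baseline 200 cells), T-cell proliferation that saturates at
a small number of activated loaded DCs (`K_T = 5` cells, `ρ = 0.9/d`) — so
that even the small early injections of an escalating course start T-cell
expansion, which is what makes extended stimulation compound — and slow
T-cell contraction (`δ_T = 0.1/d`).  With these defaults the peak Tfh
ordering is bolus < 2-ED < 7-ED, and giving the adjuvant as a bolus while
escalating the antigen collapses the Tfh response (poor synchronization of
DC recruitment with antigen availability).

### Two-parameter fit

`fit_priming_params` fits the DC recruitment rate `k_DC` and the baseline
T-cell count `T0` to observed per-animal day-14 Tfh counts across regimens,
minimizing the sum over regimens of
`(log model_Tfh(14) − mean log observed)^2`.  Log-scale least squares is
used because counts span orders of magnitude.  The search runs over
`(log k_DC, log T0)` with Levenberg–Marquardt from a configurable number of
multiplicatively perturbed starts (default 3, seeded).  At least two
distinct regimens are required; with one, the two parameters are not
separable and an identifiability error is raised.

With the shipped defaults as ground truth, noiseless synthetic data recover
both parameters to well under 1%, and under lognormal animal noise
(CV 0.3, n = 5 per group, 7 regimens) the median relative error over 20
repeats is ~17% for `k_DC` and ~7% for `T0`.  `k_DC` identifiability
depends on recruitment dominating the baseline DC count; it degrades if
`D0` is made large relative to `k_DC · I`.

## Germinal-center model

One simulated lymph node couples deterministic antigen/antibody kinetics to
`n_gc` stochastic agent-based GCs.

### Antigen kinetics

Four pools, all normalized to the total dose: soluble native `S_n`, soluble
non-native (partially degraded) `S_d`, and their FDC-bound immune-complexed
counterparts `C_n`, `C_d`:

    S_n' = u(t) − k_deg S_n − δ_s S_n − κ(T_n) S_n
    S_d' = k_deg S_n − δ_s S_d − κ(T_d) S_d
    C_i' = κ(T_i) S_i − δ_c C_i

`k_deg = ln 2 / 6.2 h = 2.683/d` is fixed by the measured half-life of
intact antigen in the node.  FDC-bound antigen is protected: no `k_deg`
term applies to `C_n`, and ICs decay only through slow consumption `δ_c`.

The deposition coefficient is cooperative in the affinity-weighted titer
`T_i` of the matching specificity:

    κ(T) = k_dep · T² / (K_half + T)

i.e. quadratic at low titer, linear at high titer.  Trapping antigen on
FDCs requires decoration of the antigen by several antibodies (and
complement fixation, which itself requires clustered IgG), so deposition
should be weak until antibody is plentiful.  This cooperativity is also
functionally necessary: because non-native antibody exceeds native antibody
roughly tenfold at all times (the non-native epitope is immunodominant), a
deposition law linear in titer cannot simultaneously produce a modest
native share of captured antigen when the second dose arrives as an impulse
at day 7 and a near-complete native share when the same dose trickles in
over 10 days against a steeply rising native titer.  The cooperative law
separates these regimes cleanly.

The integrator uses operator-split sub-steps sized so no pool turns over
more than ~10% per sub-step; each pool's self-decay uses the exact
exponential factor, and every flow is accumulated into a mass audit, so
`input = pools + cleared + consumed` holds to float round-off (the suite
asserts < 1e-8 for every shipped regimen).

### Antibody kinetics

Exported GC cells accumulate in a plasma pool (a fraction `p_plasma`
secrete).  Concentration grows at `k_ab` per plasma cell per day; the titer
weights each cell's output by `10^(affinity − a_ref)` with `a_ref = 8` on a
−log10 Kd scale, so titer is "concentration weighted by affinity".  Both
decay at `δ_ab`.  The linear ODE is solved exactly per step.

### GC agents

B cells carry an epitope (native/non-native), an affinity (−log10 Kd,
bounded in [4, 10]), a lineage id and a mutation count.  Per step of
`dt = 0.01 d` in each GC:

* capture `c = s/(1+s)` with `s = 10^(affinity−6) · C_epitope / K_ic` —
  zero if the cell's epitope has no FDC antigen;
* competitive T-cell help `h = min(1, c / (⟨c⟩_GC + c₀))`, where `⟨c⟩_GC`
  is the mean capture in the cell's GC and `c₀` a constant help threshold;
* mutually exclusive event draws: death `μ dt`, export `ε dt`, division
  `β c h dt`.  The division probability is the *product* of absolute
  saturating capture and the competitive share: a GC with abundant antigen
  expands near `β` regardless of composition, while a uniformly starved GC
  contracts — a purely relative competition term cannot produce the latter;
* each division yields one daughter: unchanged (p = 0.5), lethally mutated
  (0.3, discarded), or affinity-changing (0.2) with
  `Δa = 1 − LogNormal(0.5, 0.3)` — ~5% of draws beneficial (up to +1 log),
  the rest deleterious with a fat tail;
* daughters beyond the per-GC capacity (2000 cells) are rejected uniformly
  at random.

Naive precursors seed each GC as a Poisson stream whose total rate
saturates in total available antigen (soluble + FDC-bound), and whose
epitope is drawn proportionally to precursor frequency (non-native 0.8 vs
native 0.2) times a saturating function of that epitope's own antigen
availability.  Native-specific B cells therefore stop entering once intact
antigen is exhausted — degraded antigen recruits off-target B cells — which
is what keeps the bolus GC essentially devoid of native-binding cells at
late times.  Immunodominance of the non-native epitope is encoded both in
precursor frequency and in a slightly higher mean germline affinity
(5.9 vs 5.7, SD 0.15).

Given identical seeds the simulation is bit-reproducible; per-replicate
generators are spawned deterministically from the user seed.

### Calibration

Parameters of the parent GC framework (selection functional forms, GC
counts, mutation distributions) are reconstructions, exposed in `GCParams`.
They were calibrated in a single documented pass against two quantitative
anchors and a set of
qualitative ones, then frozen:

* day-21 native share of FDC-bound IC ≈ 38% for the two-impulse 2-ED
  regimen and ≈ 92% when the second dose is released over 10 days.  The
  shipped defaults give ~37–40% and ~86–87% respectively (10 replicates,
  across seeds), within ±10 percentage points of both anchors and with a
  bolus→extended contrast of ~48 points;
* day-21 FDC-IC totals and day-21 native GC fraction each ordered
  bolus < 2-ED < 7-ED; GC size similar (within 2×) for bolus and 2-ED at
  day 7 but diverged by day 14; native IC share non-decreasing in the
  release duration of the second dose across 0–21 days.

The node size (`n_gc = 20` GCs, capacity 2000 cells each, seeding up to
40 cells/GC/day) is a desk-scale stand-in for the lymph node's GC ensemble;
it is large enough that replicate means of the headline fractions vary by
only ~±2 percentage points between seeds at 10 replicates.

## Synthetic cohorts

`gen_cohort` emulates per-animal flow-cytometry readouts: each animal's
value is the model mean times `exp(N(−σ²/2, σ))` with
`σ² = ln(1 + CV²)`, so the noise has expectation exactly 1 and coefficient
of variation exactly `CV`.  The default CV of 0.5 reflects typical
inter-animal spread in immunization experiments; the fit-recovery studies
use CV 0.3 with n = 5 animals per group.  The generator reproduces group
*means* faithfully by construction; it does not emulate gating artefacts,
detection limits, or inter-animal correlation, so passing recovery tests
demonstrate statistical identifiability under well-behaved noise, not
robustness to instrument systematics.

## Experiments and outputs

`run_experiment` drives five canned analyses (priming time courses, GC
panels, release-duration sweep, adjuvant-mismatch check, fit demo) and
writes one CSV per panel plus a manifest (row counts, SHA-256 checksums)
and a metadata JSON (config hash, seeds, package version, runtimes), so any
run is reproducible from its metadata alone.  CSV tables are the contract;
no figures are produced.  The default replicate count for stochastic
simulations is 10.

## Numerical choices and degenerate inputs

* Priming integration: LSODA, `rtol 1e-7 / atol 1e-10`, restarted at dose
  boundaries; trajectories are clipped at zero to remove integrator noise
  of order `atol`.
* Agent stepping: fixed `dt = 0.01 d`; the configuration is rejected if
  per-step event probabilities could exceed 1.
* `k_deg = 0` is allowed as an explicit limit (no degraded species ever
  exists; the native IC share is then exactly 1).
* Fractions with zero denominators (no ICs, or an empty GC) raise a
  dedicated error rather than returning NaN.
* A zero-dose regimen yields the resting fixed point of the priming model
  and an identically empty GC response.

## Known limitations

* Both models are deliberately coarse: no spatial structure, no DC subsets,
  no TCR/BCR sequence diversity, no memory-cell recall, no epitope masking
  by serum antibody.  The two models are run independently (a coupling of
  priming output to GC help capacity is deliberately not included).
* The reconstruction choices above (cooperative deposition, product-form
  selection, availability-weighted recruitment) are the package's own; they
  reproduce the anchors and orderings but are not unique in doing so.
* The extended-release native IC share sits ~5 points below its 92% anchor
  at the shipped calibration; pushing it higher degrades the two-impulse
  anchor under this parameterization.
* In-model mean affinities dip transiently during expansion phases (germline
  influx plus mutation load outpace selection early); maturation is
  monotone only once a response is established, and the suite tests it in
  that regime.
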