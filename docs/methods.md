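# Methods

This note documents the statistical model behind `nm3`, the defaults and
the reasoning for them, what the synthetic generator does and does not
emulate, and the numerical conventions the implementation fixes where the
framework itself leaves them open.

## Data model and taxonomy

Events follow the WHO ICPS / AHRQ Common Formats convention: *near miss*
(intercepted, did not reach the patient), *no-harm incident* (reached the
patient, no harm), *harmful incident* (reached the patient, caused harm).
The package enforces the reached-patient distinction as a hard validation
invariant: a near miss with `reached_patient = yes` (or a no-harm incident
with `no`) is a taxonomy conflict and is quarantined (or aborts, in strict
mode). No-harm incidents are carried through I/O and counted in total
reporting volume but enter no rate formula — only near misses and harmful
incidents do.

Validation is total: every input row is either accepted or appears exactly
once in the validation report. Unknown unit/domain codes map to `other`
with a warning rather than rejection, so hospital-wide (level-1) analysis
never loses events to stratification vocabulary.

## Rates and denominators

All rates are `(count ÷ exposure) × k` with `k` the domain's conventional
scaling constant: 10,000 for pharmacy doses, 1000 for everything else
(patient-days, specimens, transfusion units, procedures). The reported
near-miss-to-harm ratio is a plain quotient; with zero harm events it is a
typed *undefined* marker, never infinity or an exception — undefined values
propagate into reports as empty cells / JSON `null`.

**Quarterly aggregation.** When any monthly denominator in a series falls
below the stability threshold, the entire series is re-binned by calendar
quarter (numerators and denominators summed exactly — conservation is a
tested invariant). Aggregation is all-or-nothing per series so chart
periods stay homogeneous. The threshold is denominator-based and ships at
**500 exposure units/month**; it is an explicit tunable
(`stability_threshold`), not a published constant, chosen so that a unit
averaging a handful of events per month at typical rates aggregates while
ICU-scale denominators never do.

## Control charts

The u-chart for per-period counts c_i over exposures n_i uses

    ū = Σc_i / Σn_i,    UCL_i/LCL_i = ū ± 3·√(ū/n_i),  LCL floored at 0.

Limits are recomputed per period (variable n_i); there is no baseline
freezing unless a baseline window is configured explicitly.

**Overdispersion.** Hospital count series routinely vary more between
periods than Poisson sampling allows, which makes u-chart limits too tight
and manufactures false signals. The Laney U′ adjustment estimates the
dispersion of the period z-scores,

    z_i = (u_i − ū) / √(ū/n_i),    σ_z = mean|z_{i+1} − z_i| / 1.128,

(1.128 = d₂, the unbiasing constant for moving ranges of span 2) and
scales the limit half-widths by σ_z. Under pure Poisson variation σ_z ≈ 1
and the charts coincide; the test suite checks σ_z ∈ [0.85, 1.15] on a
seeded 500-period Poisson series and σ_z > 1.5 under injected gamma-Poisson
overdispersion.

**Chart selection.** `select_chart` fits the u-chart unless σ_z exceeds the
threshold, shipped at **1.3**. The framework prescribes the adjustment "if
overdispersed" without a numeric trigger, so the threshold is an explicit,
logged tunable; 1.3 sits well above the sampling noise of σ_z on typical
2–5-year windows while catching the ≥1.5 values that material
overdispersion produces. Underdispersion (σ_z < 1) does *not* switch charts
by default — shrunken limits would manufacture signals —; Laney shrinkage
must be opted into by calling `build_laney_chart` directly.

**Run rules.** Rule 1 (point outside the limits) is always evaluated.
A shift rule (8 consecutive points one side of center; points exactly on
the center break the run, for deterministic evaluation) and a trend rule
(6 consecutive strictly monotone points) are opt-in; each fires once per
run, at the point completing it.

## Severity weighting and the Near Miss Index

Each near miss is scored on the 4-point ordinal consequence scale of the
IHI Severity Assessment Code — the worst reasonable outcome had the event
not been intercepted. The full SAC likelihood × consequence grid is reduced
to its consequence axis; weights default to minor = 1, moderate = 2,
major = 3, catastrophic = 5 and must increase strictly (custom tables are
loadable from config). NMI = Σ(weight × count) over scored near misses in
scope; events without a severity class are excluded and tallied separately,
never scored zero. The index is additive over disjoint sets and scales
linearly in the weights (both tested against an event-by-event oracle). An
optional exposure-normalized form (NMI per 1000 patient-days) is provided
for cross-period comparison. A Cohen's-kappa helper supports the periodic
two-rater agreement checks severity scoring needs.

## Learning yields

* **90-day yield** = near misses with ≥1 corrective action implemented
  within 90 days of the report date ÷ near misses in scope. An event with
  several actions counts once; the clock starts at the action record's
  report date.
* **180-day yield** = implemented actions with verified sustainment ÷
  implemented actions. Sustainment requires objective evidence (audit or
  post-implementation performance data) dated at least **173 days** after
  implementation — the 180-day mark with a 7-day audit-timing grace, since
  audits rarely land on the exact day.

Windows not yet closed at the `as_of` date are computed anyway but flagged
*provisional*: dashboards need early reads, governance needs the caveat.
Both are process metrics — they measure responsiveness and persistence of
the organizational response, not whether the actions reduced harm.

## Interpretation matrix

`classify_pattern` is a pure function of four inputs: the near-miss trend,
harm trend, total-reporting trend (each increasing/decreasing/flat) and
whether the level-1 chart shows any rule-1 signal. Trends come from a
least-squares slope on the period index, declared flat when the fitted
drift over the window, |slope| × length, is below ε × the series mean
(ε default 0.10); at least 4 periods are required.

Precedence, first match wins:

1. **disengagement_risk** — near misses and harm both decreasing. Checked
   first because it is the riskiest misread (fatigue masquerading as
   improvement).
2. **equilibrium** — both flat, no SPC signal.
3. **culture_plus_strain** — near misses and reporting both increasing
   (harm not increasing).
4. **interception_improved** — near misses increasing, harm not increasing.
5. **detection_improved** — near misses increasing, reporting flat.
6. **unclassified** — everything else.

Near misses and harm rising together is deliberately *not* given a named
interpretation: those cells (except the one claimed by rule 5's literal
reporting-flat condition, which keeps that pattern reachable) fall to
`unclassified` with an "investigate harm rise" diagnostic. Classification
is exhaustively tested over all 54 input cells, every pattern is reachable,
and each assessment carries the row's diagnostic/interpretation/action
texts plus a precedence trace so users can audit (and re-order) the rules.

## Synthetic generator

`generate(SimulationConfig)` emulates the statistical structure the
analytics assume: monthly counts Poisson with intensity
rate/1000 × exposure; overdispersion injected by multiplying the intensity
by a gamma variable with mean 1 and variance `dispersion` (the squared CV
of the latent monthly rate — a negative-binomial marginal, the mechanism
the Laney adjustment exists to absorb); severities multinomial; action
follow-through Bernoulli with implementation uniform in (0, 90] days and
sustainment audits at day 180–194. Event dates are uniform within the
month; identical configs (including seed) give identical output.

Defaults are the reference hospital's conditions: 0.2 near misses and 1.0
harm events per 1000 patient-days, ~16,667 patient-days/month (50,000 per
quarter), severity mix (0.5, 0.3, 0.1, 0.1), 30% action-implementation and
2/3 sustainment probability. What the generator does **not** emulate:
reporting-culture dynamics (fear, workload, fatigue), weekday/seasonal
structure, case-mix, or correlation between severity and follow-through.
Passing tests therefore demonstrate correctness of the *analytics* under
the assumed count model, not robustness to the behavioural distortions real
voluntary reporting systems exhibit.

Problem sizes used in the test and acceptance suites — 500-month series for
the dispersion and rate-recovery checks, 20–100 random draws for the oracle
equivalences — were chosen as the smallest scales at which the asymptotic
properties (σ_z → 1, 5% rate recovery) are comfortably resolved.

## Pipeline conventions

Levels are cumulative (`--level 3` runs 1 and 2 first). Exit codes:
0 success (including partial success with recorded gaps), 1 validation
failure, 2 insufficient data. Artifacts are byte-deterministic given the
same inputs and config; wall-clock timestamps live only in
`run_meta.json`. Plots (PNG) are behind a `--plots` flag.

## Known limitations

* Ratios and yields are undefined (not zero) on empty denominators;
  downstream consumers must handle the null.
* The reached-patient invariant assumes coders follow WHO ICPS semantics;
  systems with local taxonomies need a mapping step first.
* No risk adjustment or case-mix standardization of rates; no EWMA/CUSUM/
  g-charts or funnel plots — u and Laney U′ only.
* Trend labels from short windows (4–8 periods) are coarse; the ε-band
  slope test is a pragmatic default, not an inference procedure.
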