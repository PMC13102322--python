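# nm3 — three-level near-miss analytics for hospital safety governance

Near misses — safety events intercepted before they reach the patient — are
the richest leading indicator a hospital has, but raw report counts are
nearly uninterpretable: they are confounded by patient volume, distorted by
reporting culture, and noisy enough that leaders routinely mistake random
variation for change. A rise in reports can mean worse safety *or* better
reporting, and most incident systems give no way to tell.

`nm3` converts coded event logs into decision-grade metrics through three
cumulative maturity levels:

1. **Level 1 — organization-wide baseline.** Standardized rates
   (near misses per 1000 patient-days), the reported near-miss-to-harm
   ratio, and statistical process control: a u-chart with limits
   ū ± 3√(ū/nᵢ), replaced by a **Laney U′** chart
   (limits ū ± 3·σ_z·√(ū/nᵢ), with σ_z the moving-range dispersion of the
   period z-scores) when the series is overdispersed.
2. **Level 2 — targeted stratification.** Per-unit rate series with
   domain-aligned denominators (ICU per 1000 patient-days, pharmacy per
   10,000 doses, laboratory per 1000 specimens, transfusion per 1000 units,
   procedures per 1000 studies), charted longitudinally — never as league
   tables — with automatic quarterly aggregation when monthly denominators
   are too small for stable limits.
3. **Level 3 — decision-grade analytics.** A severity-weighted
   **Near Miss Index** NMI = Σ(weight × count) over the 4-point ordinal
   consequence scale (minor = 1, moderate = 2, major = 3, catastrophic = 5);
   **learning yields** (share of near misses with a corrective action
   implemented within 90 days; share of implemented actions verifiably
   sustained at 180 days); and a deterministic **interpretation matrix**
   that classifies the joint movement of near-miss, harm, and reporting
   trends into five named leadership patterns.

It is written for hospital quality/patient-safety (QPS) analysts: a Python
library first, plus a thin `nm3` command for file-in/file-out runs, and a
seeded synthetic-log generator for testing and training.

## Worked example

The reference quarter ships as a deterministic fixture: 50 harmful
incidents and 10 near misses over 50,000 patient-days, severity tally
5 minor / 3 moderate / 1 major / 1 catastrophic, 3 corrective actions
implemented within 90 days, 2 sustained at 180 days.

```python
from nm3 import worked_example, level1_dashboard, level3_brief, compute_nmi

events, exposures, actions = worked_example()
lvl1 = level1_dashboard(events, exposures)
print(lvl1.dashboard_frame().to_string(index=False))
```

```
period_id  near_miss_count  harm_count  reports_total  denominator  near_miss_rate  harm_rate  nm_to_harm_ratio  spc_signal
  2025-Q1               10          50             60      50000.0             0.2        1.0               0.2       False
```

The near-miss rate is 0.2 and the harm rate 1.0 per 1000 patient-days; the
ratio 0.2:1 reflects the usual underreporting of near misses relative to
harm events.

```python
index = compute_nmi(events)          # -> 19  (5·1 + 3·2 + 1·3 + 1·5)
brief = level3_brief(events, exposures, actions, level1=lvl1)
print(index.value,
      brief.yield_90.value,          # 0.30  (3 of 10 near misses acted on)
      round(brief.yield_180.value, 2))  # 0.67  (2 of 3 actions sustained)
```

Or from a shell:

```bash
nm3 fixture --out data/
nm3 run --level 3 --events data/events.csv --exposures data/exposures.csv \
        --actions data/actions.csv --out reports/
```

which writes `dashboard.csv`, per-unit `unit_cards/`, `brief.json`,
`nmi.csv`, `learning.csv` and a deterministic `run_log.json`. The
`examples/` directory holds short narrative scripts for each capability
(worked example, overdispersion and the Laney adjustment, the
interpretation matrix, the full simulated pipeline).

## Synthetic data

`nm3 simulate` / `nm3.generate(SimulationConfig(...))` draws monthly
Poisson (optionally gamma-Poisson overdispersed) event logs with
controllable true rates, severity mix, and action follow-through, fully
reproducible from a seed. Defaults match the reference hospital: 0.2 near
misses and 1.0 harm events per 1000 patient-days at ~16,667 patient-days a
month.

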