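# firearmcost

National hospital-cost estimation for firearm injury visits, built as a
tested, fully offline pipeline around a synthetic administrative-claims
generator.

## The problem

Hospital claims detailed enough to cost firearm injury care (billed
charges, hospital identifiers, person-level visit linkage) exist only for
a handful of states. To say what initial firearm injury treatment costs
the whole country, state-level visit records must be extrapolated to the
states without such data. This package implements that estimation chain
for researchers in injury epidemiology and health economics:

1. **Cost construction.** A visit's cost is `charge x CCR(h, y)`, the
   billed charge times the hospital- and year-specific cost-to-charge
   ratio, converted to base-2024 dollars with an annual price index:
   `cost_2024 = charge x CCR(h, y) x I(2024) / I(y)`. Visits are kept only
   if their external-cause code marks a *new* injury encounter (final
   character `A`) and a charge is present; exclusions are counted, not
   silently dropped.
2. **Injury variables.** Intent from configurable cause-code prefixes,
   injured body region with a multiple-regions rule, the Injury Severity
   Score `ISS = sum of the squared highest AIS severities in the three
   most severely injured body regions` (AIS 6 forces 75), comorbidity
   count bands, and a same-calendar-year reinjury flag based on
   person-level visit linkage.
3. **Monte Carlo national extrapolation.** For each simulation and year,
   inpatient visits are drawn with replacement from the pooled
   sample-state inpatient visits until the external inpatient admission
   targets of the non-sample states are matched; ED-only draws equal each
   target times the year's sample ED:inpatient ratio (half-up rounding).
   Resampled and original visits form a national annual sample, tallied
   per stratum; hospital-volume quartile cut points are recomputed inside
   every simulated sample. Estimates are means across simulations, and
   the reported SE is the across-simulation standard deviation.

Because the real claims sources are restricted-access, a first-class
synthetic generator (`firearmcost.synthetic_data`) emulates their
structure — heavy-tailed log-normal charges by visit type, a
missing-charge fraction, person linkage within state and calendar year,
hospital survey attributes, and state-year admission targets — with
ground truth recorded at generation time so the estimator can be
validated analytically and exactly.

## Worked example

```python
import firearmcost as fc

cfg = fc.GeneratorConfig(seed=1, hospitals_per_state=4, visits_per_state_year=700.0)
ds = fc.generate_dataset(cfg, targets_mode="consistent")

costed, drops = fc.cost_pipeline(ds.sample_visits(), ds.ccr, ds.cpi)
visits = fc.attach_hospital_attributes(fc.derive_all(costed), ds.hospitals)

run = fc.run_monte_carlo(
    visits, ds.targets, fc.SimulationSpec(n_simulations=200, master_seed=1001)
)
est = fc.aggregate(run.results)
print(round(est.total("overall", "all", "overall") / 1e9, 2), "billion (2024 USD)")
print(fc.share_of_total(est, ("overall", "all", "inpatient"),
                        ("overall", "all", "overall")), "% inpatient")
print(round(est.cell("overall", "all", "ed_only")["pervisit_mean"]), "USD per ED visit")
```

prints

```
3.8 billion (2024 USD)
93.0 % inpatient
2016 USD per ED visit
```

i.e. a six-year national total of $3.8 billion at this synthetic scale,
93% of it from inpatient admissions, with a mean ED-only visit cost of
about $2,016. `fc.write_tables(est, fc.trend_table(run.results), "out/")`
emits the totals table (millions, 1 decimal), the per-visit means table,
annual trend series and a JSON run summary.

The same pipeline is scriptable from a shell:

```sh
firearmcost generate --config cfg.yaml --out work/ --seed 1
firearmcost cost --in work/
firearmcost derive --in work/ --self-pay-dialect-state AR --self-pay-dialect-state WI
firearmcost run-mc --in work/ --out work/mc --sims 200 --seed 1001
firearmcost report --in work/mc --out work/report
```

## Layout

- `firearmcost.synthetic_data` — claims/hospital/CCR/CPI/target generator with ground truth
- `firearmcost.cost_engine` — filters and charge-to-cost conversion
- `firearmcost.clinical_derivation` — intent, body region, ISS, reinjury, quartiles
- `firearmcost.national_simulation` — resampling extrapolation and stratified tallies
- `firearmcost.reporting` — aggregation, shares, trends, medians, table output
- `docs/methods.md` — model assumptions, parameter choices, limitations
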