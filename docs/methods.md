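# Methods

## Estimand and model

The pipeline estimates the total and mean hospital cost of initial
firearm-injury ED-only visits and inpatient admissions over a study
window (2016–2021 by default), nationally and by patient, injury and
hospital strata, from visit-level claims observed in a set of sample
states plus external inpatient-admission counts for every other state.

A visit's cost is the billed charge scaled by its hospital's year-specific
cost-to-charge ratio (CCR) and expressed in base-year dollars:

    cost_base(v) = charge(v) · CCR(h(v), y(v)) · I(base) / I(y(v))

with `I` an annual price index and base year 2024. The analytic sample
keeps visits whose external-cause code ends in the new-encounter
character `A` and whose charge is present; both exclusions are counted
and reported, never silently applied. CCRs are accepted in (0, 1.5]:
ratios above 1 occur in real hospital accounting data, values beyond 1.5
are treated as corrupt.

National extrapolation is a Monte Carlo resampling scheme. Per
simulation and per year:

1. draw, uniformly with replacement from the year's pooled sample-state
   inpatient visits, as many inpatient visits as the summed inpatient
   targets of the non-sample states;
2. draw ED-only visits analogously, the draw count per non-sample state
   being its inpatient target times the year's pooled ED:inpatient ratio
   in the sample states, rounded half-up (exact integer arithmetic, so a
   true .5 never depends on floating-point representation);
3. combine resampled and original visits into a national annual sample
   and tally cost totals and visit counts per (stratifier, level, visit
   type) cell.

Cell estimates are arithmetic means across simulations. The headline SE
is the across-simulation standard deviation; the standard error of the
Monte Carlo mean (SD/√n_sims) is emitted under its own label, since the
two interpretations differ by a factor of √n_sims and published "(SE)"
columns do not always say which is meant. Mean cost per visit is
computed within each simulation as total/count and then averaged
(zero-count cells are excluded and counted); the ratio-of-means variant
is emitted alongside for comparison.

Under this scheme the resampled inpatient total for year *y* is a sum of
T_ip(y) iid draws from the year's pool, so its expectation is
T_ip(y)·mean(pool) and its variance T_ip(y)·var(pool). These closed
forms are used as test oracles and reported as diagnostics by
`scripts/acceptance.py`, not used by the estimator itself.

## Derived clinical variables

- **Intent** — longest-prefix match of the cause code against an
  editable CSV table (shipped default: W32–W34 unintentional, X72–X74
  self-inflicted, X93–X95 assault, Y22–Y24 undetermined, Y35.0 legal
  intervention). The table is configurable because real code lists vary
  across studies; unmatched codes fall back to undetermined with a
  logged warning.
- **Body region** — a configurable region-code lookup; one mapped region
  gives its label, two or more distinct mapped regions give "multiple
  regions", none give "other". This replaces matrix-based body-region
  classifiers, whose full code inventories are out of scope; region
  codes are an input.
- **ISS** — by default the strict convention: the sum of squared highest
  AIS severities in the three most severely injured distinct body
  regions, any AIS 6 forcing 75, capped at 75. A `sum_all` switch sums
  every squared severity (capped) instead, since "squared and summed"
  descriptions in the literature are ambiguous between the two; strict
  is the field convention and the default. AIS severities are inputs
  (1–6), not derived from diagnosis codes.
- **Comorbidity** — a pre-computed count, banded 0 / 1 / 2 / ≥3.
- **Reinjury** — every visit of a (person-link, calendar year) group
  with ≥2 new-injury visits is flagged. Linkage is state-internal and
  resets at calendar-year boundaries, which biases reinjury downward;
  that bias is a property of the data model, reproduced deliberately.
  No restriction is imposed on whether the second visit occurs at a
  different hospital (nothing in the definition requires one).
- **Payer dialect** — states can be configured to fold "no charge" into
  self-pay before stratification, mirroring state reporting dialects.
- **Hospital quartiles** (Medicaid discharge share, total admissions,
  total ED visits) are recomputed *inside every simulated national
  sample*, over visit-level hospital values (hospitals weighted by their
  visit multiplicity), because the quartile membership of a hospital
  depends on the resampled composition. Cuts are inclusive
  linear-interpolation percentiles; ties at a cut go to the lower
  quartile for determinism.

## Synthetic data generator

The generator emulates the statistical structure of linked state
inpatient/ED claims joined to hospital survey data, with defaults chosen
to resemble hospital-treated firearm injury in the US:

- **Scale.** 6 sample states (labelled with the two-letter codes of a
  realistic sample-state set when exactly six) plus 44 unobserved
  states, years 2016–2021, 25 hospitals and a Poisson mean of 2,500
  visits per state-year.
- **Visit mix.** ED-only vs inpatient Bernoulli with an ED:inpatient
  ratio of 1.607 (the ratio implied by roughly 298.7k ED visits per
  185.8k admissions nationally).
- **Charges.** Log-normal by visit type: location 8.0/scale 1.0 for
  ED-only and 11.0/1.1 for inpatient nominal charges, which after a
  typical CCR (Beta(7,13), mean 0.35) and price indexing put mean costed
  visits near $2k (ED) and $40k–45k (inpatient) in 2024 dollars —
  right-skewed, as hospital charge data are. Charges are missing
  completely at random at rate 0.169.
- **Persons.** A reinjury-rate fraction (default 0.06) of persons
  receive two visits within one state and calendar year; demographics
  are drawn at person level, visit attributes at visit level. Person
  links never span states.
- **Stratifiers.** Categorical marginals (age, sex, race/ethnicity,
  payer, zip-income quartile with an explicit missing share, disposition,
  intent, comorbidity count) are drawn independently per visit/person;
  the joint distribution of patient attributes is not modelled because no
  target joint distribution is available. Injured regions per visit
  number 1/2/3 with probability 0.60/0.30/0.10 (weighted sampling
  without replacement), each with an AIS severity from a fixed
  distribution including 2% unsurvivable grades.
- **Ground truth.** True visit counts per (state, year, visit type) and
  base-year cost totals over the non-missing-charge visits (missing
  charges are unrecoverable by construction, mirroring the analytic
  exclusion), plus national totals by generation-time stratifier.
  The national total is accumulated per state so the
  national-equals-sum-of-states identity holds exactly in floating
  point.
- **Targets.** "Consistent" mode copies the true inpatient counts of
  the unobserved states, so the extrapolation's count identities are
  exact and its cost expectation has a closed form; "external" mode
  draws counts independently.

What passing tests on this generator do **not** show about real claims:
real charges correlate with severity, payer and hospital; missingness is
not completely at random; stratifiers are strongly dependent (payer with
age, region with intent); hospital attributes correlate with volume; and
non-sample states differ systematically from sample states — the very
assumption the resampling design must make. The tests validate the
estimation machinery, not the representativeness assumption.

## Numerical choices

- Currency is float dollars throughout (CCR/CPI products are
  non-integral); equality assertions on costs are tolerance-based,
  count assertions exact.
- ED target rounding: half-up via `(2·T·ed + ip) // (2·ip)` in integer
  arithmetic.
- Simulation k's generator is seeded from (master seed, spawn key k), so
  results are reproducible and independent of execution order.
- All stratifier columns are frozen to fixed categorical level sets
  before simulation, so every simulation shares one cell universe and a
  level absent from one resample yields an explicit zero cell rather
  than a missing row.
- Across-simulation SDs are forced to exactly 0 when every simulation
  produced the identical value, so the zero-resampling limit reports SE
  = 0 rather than accumulation noise.
- Medians are computed on the pooled per-visit cost distribution of a
  designated reference simulation (the first), original plus resampled
  visits, because medians do not aggregate across simulations the way
  means do.
- Degenerate inputs: quartiles require ≥4 finite values; an empty
  resampling pool with a positive draw count raises an error naming the
  year and visit type; an all-zero target table is legal and reduces
  every simulation to the original sample.

## Problem sizes

Tests exercise the analytic oracles on a consistent-mode dataset of
about 50,000 sample-state visits with 200 simulations; the acceptance
script uses about 25,000 sample visits and 200 simulations. These sizes
give oracle z-scores well inside their bounds while keeping a full run
in the minutes range; the estimator itself is size-agnostic, and the
default generator scale (2,500 visits per state-year) matches the
sample volume the six-state window is meant to emulate.

## Known limitations

- Only initial acute-care hospital costs are modelled: no professional
  fees, transport, trauma activation fees, readmissions, post-acute or
  indirect costs, and no charge imputation for missing values.
- Uncertainty in the external inpatient targets is not propagated; the
  Monte Carlo SE reflects resampling variability only.
- Resampled visits inherit the donor's hospital attributes, since no
  hospital data exist for non-sample states; hospital-level strata for
  non-sample states therefore mirror sample-state hospitals.
- Whether non-sample states are resampled individually or via their
  yearly sum is distributionally irrelevant for totals; draws are
  labelled per state so per-state output remains possible.
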