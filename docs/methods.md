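# Methods

## Model

`copdcem` implements a cohort-based semi-Markov cost-effectiveness model
comparing two fixed-dose triple therapies for moderate-to-very severe COPD:
budesonide/glycopyrronium/formoterol fumarate dihydrate (BGF) versus
fluticasone furoate/umeclidinium/vilanterol (FF/UMEC/VI), from a UK
third-party-payer perspective.

The state space has 16 states: nine chronic states (three GOLD severity
levels — moderate, severe, very severe — each replicated across three
exacerbation-history strata: none, post-moderate, post-severe), six one-cycle
exacerbation tunnel states (severity x moderate/severe event) and an
absorbing death state carrying a one-time end-of-life cost and utility 0.
One cycle is one month, taken as exactly 1/12 year (the trial probability
conversions equate 12 cycles with 52 trial weeks). Severity never improves.
Patients enter exacerbation-free, distributed 28.5% / 60.6% / 10.9% across
moderate / severe / very severe.

Within a cycle, competing risks are resolved in a fixed order: death first
(mortality inputs are all-cause, so death is taken off the top), then severe
and moderate exacerbation among survivors, then severity progression among
exacerbation-free survivors. The order is a deliberate design choice — the
source description does not specify one — and is localized in
`states.build_transition_matrix` so the alternative ordering can be tested.
At most one exacerbation per cycle; tunnel residents can neither progress nor
re-exacerbate within the tunnel cycle.

Tunnel states record only (severity, event type), so a patient in the
post-severe stratum who has a moderate exacerbation exits to the
post-moderate stratum. A "severe history is never downgraded" rule would
require tunnel states stratified by prior history (22 states); with the
16-state space this corner is accepted and noted as a limitation. Its effect
is confined to the progression probabilities applied afterwards, which are
identical across post-exacerbation strata in the default inputs.

### Severity progression

Monthly progression probabilities come from 52-week trial probabilities via
`1 - (1 - p)^(1/12)`: 2.27%/month (moderate→severe, from 24.10%/52wk) and
0.60%/month (severe→very severe, from 7%/52wk) for the first model year and
for all post-exacerbation strata; patients with no exacerbation history
switch from cycle 13 to the slower exacerbation-free-population rates
(1.13%, 0.87%). The comparator arm applies a relative risk of 1.00
(assumption for lack of head-to-head lung-function data).

### Mortality

Two modes. In `km_curve` mode (default) the overall monthly death
probability for cycles 1–12 is the conditional probability
`(M(t) - M(t-1)) / (1 - M(t-1))` read off the arm's cumulative-mortality
curve. In `constant` mode it is a flat monthly probability (0.118% BGF,
0.193% FF/UMEC/VI). Each cycle, the overall probability is split across
severity levels with relative risks 1.40 / 2.60 / 2.60 (vs general-population
mortality), solving `q_s = b·rr_s` with `b` chosen so the occupancy-weighted
mean reproduces the overall probability; the weights are the cohort's current
severity mix, so the mortality schedule is coupled to the live occupancy.
Post-exacerbation chronic states multiply by a relative risk of 1.00.

Severe-exacerbation tunnel states carry an additional one-cycle event
mortality: 0% in year 1 (trial curves already count those deaths) and 12%
afterwards — the published input combining in-hospital and 90-day
post-discharge mortality, `0.043 + (1 - 0.043)·0.08`, rounded to the nearest
0.1 percentage point.

Beyond month 12 the model extrapolates: per-state probability =
severity RR x general-population monthly probability x an arm-level
calibration scalar. The general-population track advances age in whole years
every 12 cycles and re-weights the sexes each year from the life table
(survival updated as `S ← (1 - qx)·S` per sex; proportion female
`p1·p2 / (p1·p2 + (1-p2)·p3)`; mortality `r1·p + r2·(1-p)`). The scalar is
the ratio of the arm's instantaneous hazard at month 12 (`-ln(1 - q12)`,
since the curve is only known monthly) to the severity-weighted
general-population hazard there, clamped to ≥ 1 so modelled patients are
never healthier than the matched general population. The anchor weighting
uses the baseline severity distribution rather than the month-12 occupancy:
this makes each arm's scalar a precomputable constant, which in turn lets
the waning scenario interpolate exactly onto the comparator's scalar; the
difference from using month-12 occupancy is third-order because the severity
mix moves little in twelve cycles.

Scenario hooks on the extrapolation:

- **waning** — the BGF scalar moves linearly from its own month-12 value to
  the FF/UMEC/VI scalar between months 12 and 60, so the arms' per-state
  death probabilities coincide at the five-year horizon.
- **lognormal** — the post-month-12 overall hazard is replaced by conditional
  probabilities from a least-squares fit of
  `S(t) = 1 - Φ((ln t - μ)/σ)` to the arm's monthly survival points
  (initialized by probit regression of cumulative mortality on `ln t`),
  then split by severity as in year 1.
- **eol_setting** — mortality untouched; the all-hospital end-of-life cost is
  replaced by a care-setting-mix weighted cost.

### Treatment status and discontinuation

Treatment status is a scalar fraction among the alive, not a doubling of the
state space: subsequent treatment (BGF + roflumilast) has the same efficacy
as initial treatment by assumption, so only cost attribution differs.
Monthly discontinuation risk is the arm's trial-based rate for cycles 1–12
and 1% per cycle thereafter; discontinued patients stay on subsequent
treatment until death (no third line exists). The "1% per cycle" input is
read as the post-year-1 discontinuation risk of initial treatment — the
reading under which the parameter affects costs.

### Economics

Monthly discounting uses `(1 + r)^(-t/12)` with annual rates of 3.5% for
both costs and outcomes, which compounds smoothly to the stated annual rate.
No half-cycle correction by default (Excel-style end-of-cycle accounting);
a switch enables the half-cycle average. Accrual conventions: state-time
costs and utilities on end-of-cycle occupancy; exacerbation event costs
(£53.23 moderate, £3667.35 severe) in the tunnel-entry cycle; end-of-life
cost (£4028 all-hospital base case) in the death cycle; adverse-event costs
once at model start, undiscounted. Exacerbation utility decrements (0.055
moderate, 0.090 severe) are applied as reduced utility during the one-cycle
tunnel residence — QALY loss = decrement/12 per event — because the tunnel
is the event's explicit one-month residence; a switch enables the lump-sum
alternative (full decrement per event), since "applied per exacerbation
event" admits both. AE disutilities are not applied (costs only), following
the utility-section statement that AE effects are captured in severity and
exacerbation disutilities.

Incremental statistics (BGF minus FF/UMEC/VI): ΔC, ΔQALY, ΔLY,
Δexacerbations, deaths avoided (percentage points of the cohort), ICUR
ΔC/ΔQ, ICER ΔC/ΔLY, incremental net benefit `λ·ΔQ - ΔC` at λ = £20,000/QALY,
and cost per death avoided. When one arm is cheaper and more effective the
ratio fields report "dominant"/"dominated" rather than misleading negative
quotients.

## Synthetic inputs

Two external inputs are generated rather than sourced, so every stage runs
from code alone.

**Curve pair.** The digitized, MAIC-adjusted Kaplan–Meier curves are stood in
for by parametric curves: reference (FF/UMEC/VI) cumulative mortality
`1 - exp(-h·t)` with `h` calibrated so the monthly conditional death
probability is the published 0.193%, and the BGF curve via proportional
hazards at the published hazard ratio 0.61 (which lands the BGF monthly
probability on its published 0.118%). A log-normal shape option provides a
distinguishable alternative for fit-recovery tests. A constant-hazard
stand-in is the natural choice — it is exactly the shape the model's own
constant-probability mode assumes — but it cannot reproduce the late
steepening of the real digitized curves, so curve-shape-dependent magnitudes
(five-year deaths avoided, cost totals) are synthetic-input-conditional.

**Life table.** Gompertz–Makeham hazards per sex,
`qx = 1 - exp(-(a + b·e^(c·age)))`, with male mortality above female at every
age. The defaults are calibrated so that the severity-weighted
general-population hazard at the month-12 anchor lies below both arms'
trial hazards. This is the regime the hazard-ratio extrapolation presumes —
a COPD trial cohort with excess mortality over the general population — and
it keeps both calibration scalars above the clamp; were the clamp to bind in
both arms, the extrapolation would erase the between-arm mortality
difference the model exists to quantify. The consequence is a table lighter
than current UK national lifetables; it is a synthetic stand-in, not a
demographic estimate.

**Supplementary-only parameters.** Exacerbation probabilities by severity,
discontinuation first-year rates, disease-management unit costs,
acquisition/rescue/adverse-event/subsequent-treatment costs and the
end-of-life setting mix are not printed in the source's main text. They ship
as synthetic defaults (tagged `synthetic_default` in
`parameters.PROVENANCE`), chosen once to be clinically plausible and to keep
the per-arm cost composition at the magnitude of the published five-year
totals (≈£66 per alive-month of disease management including exacerbation
events, ≈£49.50 acquisition+rescue, £71.50 subsequent treatment). They are
never presented as published values, and the published headline totals are
accordingly not reproduction targets: the directional result — BGF dominant
through higher treatment costs offset by end-of-life savings — is the
tested claim.

## Sensitivity analyses

- **One-way DSA**: each addressed scalar varied to exactly 0.8x and 1.2x its
  base value (probability-like quantities clamped into [0, 1] with a logged
  warning), full two-arm model at each bound, records sorted by incremental
  net benefit spread (ties by parameter id). INB is the primary tornado
  outcome because dominance makes ratio outcomes unstable; the ICUR is
  reported alongside when defined.
- **PSA**: probabilities and utilities from Beta, costs from Gamma, relative
  risks from log-normal distributions, moment-matched to mean = base value
  and SE = 20% of base (per-parameter overrides supported; infeasible Beta
  moment matching falls back to a clipped normal with a warning). Parameters
  are sampled independently — no correlation structure is published. Draw
  streams derive deterministically from a single seed. The CEAC reports the
  fraction of draws with positive INB on a threshold grid containing
  £20,000.

The distribution families and the 20% SE default are implementation choices,
documented as such, not published inputs.

## Numerical choices and degenerate inputs

- Severity splitting caps per-severity probabilities at 1 and re-normalizes
  the remainder over uncapped severities; an overall probability that cannot
  be absorbed raises an error.
- Probability-conversion inputs of exactly 1 are rejected (log of zero).
- Tunnel utilities that would go negative after a decrement clamp to 0 with
  a logged warning; lump-sum QALY totals clamp at 0.
- Zero survivors in the sex-mix update, degenerate (death-free) curves for
  the log-normal fit, and transition rows whose event probabilities exceed 1
  all raise errors naming the offending quantity.
- Cohort mass conservation is asserted every cycle at 1e-9; transition rows
  are validated row-stochastic at 1e-12.

## Verification problem sizes

The test suite exercises the full 60-month horizon throughout. The
individual-level oracle check resimulates 200,000 exchangeable patients
through the recorded per-cycle transition matrices (per-state multinomial
counts — an exact individual-level simulation for exchangeable patients) and
requires every state occupancy at months 12 and 60 to fall within four
binomial standard errors for both arms. Log-normal recovery standard errors
are estimated from 30 replicate noise realizations, because binomial noise
on a cumulative curve is autocorrelated and fit-covariance standard errors
would understate the sampling spread. PSA-based tests use tens of draws at a
12-month horizon; the reproduction script uses 500 draws at 60 months.

## Known limitations

- All curve-dependent magnitudes are conditional on the synthetic
  exponential stand-in; the digitized trial curves are not available.
- Tunnel states do not remember prior history (see above).
- No correlated PSA, no value-of-information analysis, no spline or
  mixture-cure mortality extrapolations, no societal costs, no price-year
  adjustment.
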