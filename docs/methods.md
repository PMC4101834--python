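# Methods

## Model structure

Three health states — undiagnosed syncope, diagnosis, death — with the two
latter absorbing: a diagnosed patient is assumed successfully treated and
accrues no further syncope events or costs; a dead patient likewise exits.
The cohort is propagated as expected (fractional) occupancies over quarterly
cycles; integers appear only in the presentation layer (`summarize`,
reports), rounded half-up.

Two arms share every parameter except the per-event diagnostic yield
schedule. The ILR arm applies δ_ILR = 0.628 per syncope event during the
3-year device battery life (12 cycles) and reverts to the conventional
δ_CDP = 0.125 afterwards — the device is not replaced. The conventional arm
applies δ_CDP at every cycle. Diagnosis is strictly event-driven: the
per-cycle diagnosis probability is σ_c · δ_t, so the recurrence rate and the
yield can be varied independently in sensitivity analyses.

## Parameters

| parameter | unit | default | note |
|---|---|---|---|
| cohort size | persons | 197 | 1,010 annual admissions × 19.5% unexplained-recurrent, rounded half-up |
| start age | years | 61 | cohort ages uniformly, 0.25 y per cycle |
| syncope recurrence σ | events/person-yr | 0.6 | at most one event per patient per cycle |
| yield δ_ILR / δ_CDP | per event | 0.628 / 0.125 | ILR yield limited to battery life (3 y) |
| mortality HR | — | 1.32 | excess all-cause mortality of unexplained syncope |
| injury probability | per episode | 0.522 | 16.16% of injuries severe |
| device / implantation | EUR | 2,000 / 127.80 | explantation = implantation tariff |
| follow-up | EUR | 2 × 31 /yr | while the device is active and undiagnosed |
| trauma cost | EUR/episode | 1,687.57 | canonical; tariff weighting recomputes 1,686.05 |
| workup cost | EUR/episode | 164.32 | base scenario; five scenarios bundled (72.41–1,112.02) |
| discount rate | /yr | 5% | |
| horizon | years | 3 or 30 | 30 y treated as lifetime; survivors exit uncosted |

Scenario workup tables carry a printed per-patient total which does not
always equal the sum of their own price × fraction rows (rounding residuals
of up to ~11 € in the source tables). The printed total is canonical — it is
what the engine consumes — and the recomputed sum is exposed for
transparency, with a logged warning when they disagree by more than 1 €.

## Conventions (each a flag)

* **Rate conversion** (`linear`, default | `exponential`): the per-cycle
  syncope probability is σ·c. The linear rule reproduces the model's
  characteristic 3-year diagnosis shares; the constant-hazard alternative
  1 − e^(−σc) is retained as an option.
* **Competing risks** (`simultaneous`, default | `death_first`): diagnosis
  and death fractions are both taken from the start-of-cycle pool; the
  engine rejects parameter sets where σ_c δ_t + q_c exceeds 1. Note the two
  exits are therefore mutually exclusive *within* a cycle; the
  microsimulation realises exactly this (below).
* **Discounting** (`per-cycle`, default | `annual`): present value
  (1 + r)^(−t·c) with costs booked at cycle start; the annual-boundary
  alternative discounts in whole-year steps. Reconstruction of the source
  cost rows suggests they sit between the two conventions; per-cycle is the
  package's choice and the difference is below 1% of totals.
* No half-cycle correction is applied.

## Cost booking

ILR: acquisition + implantation for the whole cohort at cycle 0; follow-up
booked per cycle (2 × 31 € / 4 = 15.50 €) per alive-undiagnosed patient
during battery life (apportioned rather than lumpy semi-annual bookings;
the difference is at most one cycle of discounting); explantation at the
cycle of diagnosis, or at the battery-expiry boundary (cycle 12) for
undiagnosed survivors — never for patients who died with the device;
trauma cost on every expected episode; workup cost only on post-battery
episodes. CDP: trauma + workup on every episode, no device components.
An accounting identity holds by construction: explanted devices plus deaths
during battery life equal the cohort size (tested at 1e-9).

## The synthetic life table

The bundled mortality fixture is a Gompertz–Makeham table,
q(a) = 1 − exp(−(A + B e^(C·a))) with A = 6.278e-3, B = 1.124e-6,
C = 0.13309 /yr over ages 50–100, fitted by least squares to approximate
Portuguese both-sex annual death probabilities around 2010 with the entry
level pinned at q(61) ≈ 0.010: the fit gives q(70) ≈ 0.019, q(80) ≈ 0.052,
q(90) ≈ 0.169. It is a synthetic stand-in, not official national data; any
real life table can be supplied as a two-column CSV via the config file's
`life_table_path`. Mortality is the dominant residual uncertainty for
30-year results: plausible life-table variation moves 3-year counts by a
patient or two and lifetime cost totals by a few percent.

## Microsimulation oracle

The patient-level simulation is constructed so that the cohort engine is its
*exact* expectation. Independent death/diagnosis draws would not achieve
this (the engine books both fractions from one pool, i.e. treats the exits
as mutually exclusive within a cycle), so per cycle one uniform partitions
each patient into death (mass q_c), syncope-with-diagnosis (mass σ_c δ_t) or
neither, and a second draw gives non-diagnosed patients — the dying
included, whose episode the engine counts — a non-diagnosing syncope at the
conditional rate σ_c(1 − δ_t)/(1 − σ_c δ_t), restoring a total per-cycle
syncope probability of exactly σ_c. Injuries are marked among syncope
cycles. Per-patient cost accounting applies the same booking rules, so
Monte-Carlo means of counts *and* costs converge to the deterministic
results; validation checks use a 3-standard-error band at n = 100,000.

What passing these checks shows: the deterministic recursion and the cost
ledger are internally consistent with the stated stochastic process. What it
does not show: that real syncope patients follow that process — real
recurrence is overdispersed and state-dependent, real mortality differs from
the synthetic table, and injury severity is richer than a minor/major
dichotomy.

## Sensitivity analyses

One-way ranges default to halving/doubling the base value, except where an
alternative published source pins a bound: ILR yield upper bound 0.78,
recurrence-rate upper bound 0.81/yr, injury-probability lower bound 0.25.
Bars are sorted by savings swing, ties broken by name. The threshold sweep
varies δ_ILR on a grid (default 0.125–0.78, step 0.005) and interpolates the
break-even yield linearly between the bracketing grid points; both published
decision rules (yield > 0.35; increment over CDP ≥ 0.175 — partially
redundant, so both are reported) are evaluated.

Within the sensitivity module the per-event trauma cost is always recomputed
from its components (tariffs × injury/severity probabilities) so component
overrides propagate; deterministic base-case reporting keeps the canonical
1,687.57 €.

PSA dispersions are not published for the source analysis, so defaults are
re-derived from the one-way logic: lognormal (hazard ratio, recurrence rate)
with median at the base value and 95% interval [base/2, 2·base]; gamma (unit
costs) with mean at the base value and a 97.5%/2.5% quantile ratio of 4;
beta (probabilities) with mean at the base value and effective sample size
100. Per-diagnostic-test uncertainty is aggregated into a single gamma on
the scenario workup total. The hazard-ratio draw is truncated at 4.0
(probability ≈ 3e-5) to keep the quarterly competing-risk fractions feasible
at the oldest model ages; the recurrence-rate draw is truncated just below
4/yr for the same reason. Draws are independent across parameters (no
correlation structure is specified), consumed in a fixed documented order
from one seeded generator. All dispersions are overridable via
`UncertaintySpec`.

## Problem sizes and determinism

The deterministic model is 120 quarterly cycles over two arms and runs in
well under a second; the default PSA (10,000 draws) takes a few seconds;
microsimulation validation uses 100,000 patients per arm over the 3-year
horizon. Identical configuration and seed produce byte-identical CSV
artifacts (fixed float formatting and ordering).

## Known limitations

* Budget impact only: no QALYs, no cost-effectiveness ratio, and no
  treatment costs after diagnosis (diagnosed patients exit).
* The 30-year "lifetime" horizon is a hard stop; surviving undiagnosed
  patients exit uncosted.
* Injury costing uses initial-admission tariffs only, ignoring long-term
  sequelae; this understates trauma costs.
* The bundled life table is synthetic (see above).
* At most one syncope event per patient per quarter; the quarterly cycle is
  the device that allows more than one event per year.
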