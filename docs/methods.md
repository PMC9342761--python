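# Methods

## Model structure

Both comparisons are cohort state-transition (Markov) models with
one-month cycles and a single absorbing death state. Fractions of a
cohort — not individuals — move through the states, so all results are
per-patient expectations; the nominal cohort of 1000 is cosmetic.

**Model 1 (destination therapy).** The control cohort occupies a single
medical-management state with constant monthly mortality 0.106 (range
0.079–0.132) and utility 0.53 (SE 0.135). Its monthly cost blends
inotrope-dependent hospitalization and outpatient care 25:75, reflecting
the assumption that such patients spend a quarter of their surviving
time hospitalized. The intervention cohort pays the device price
(ARS 7,104,276) plus an implantation cost at cycle 0 and then occupies a
stable pump state with a piecewise monthly mortality schedule (0.06 in
month 1 falling to 0.006 by months 49–60) and utility 0.51 in the first
month, 0.72 after. Eight adverse-event types (gastrointestinal bleeding,
pump failure/replacement, disabling and non-disabling stroke, driveline
infection, right-heart failure, sepsis, ventricular arrhythmia), each
with its own time-stratified monthly incidence, feed a single pooled
complication state.

**Model 2 (bridge to transplant).** The control cohort waits 3.05 months
(urgent list) under medical-management mortality and utility, undergoes
transplant surgery with per-event mortality 0.074, and then occupies a
post-transplant state with monthly mortality 0.0024 and utility 0.76
adjusted for six transplant complications. The intervention cohort is
implanted at cycle 0, waits 6.07 months (elective list) under the pump
mortality/complication schedules, and then passes through the same
surgery and post-transplant states.

## Conventions the structure left open

These are this package's own operational choices; each is flagged where
it materially matters.

* **Accrual.** Start-of-cycle membership accrues the full cycle's
  utility and cost; no half-cycle correction by default (a
  `half_cycle=True` flag is available). This convention reproduces the
  control arms' published cumulative QALYs to within 1%.
* **Discounting.** 5%/year compounded annually, applied at monthly
  resolution: an accrual at cycle *t* is scaled by `1.05^(-t/12)`.
  One-time costs are discounted at the cycle of the triggering
  transition.
* **Lifetime horizon.** Run until the surviving fraction falls below
  1e-6, hard-capped at 1200 cycles (100 years). Mortality and
  complication schedules beyond their last tabulated interval carry the
  last value forward.
* **Complication pooling.** One pooled one-cycle complication state per
  pump strategy. Death competes first each cycle; survivors enter the
  pooled state with the summed incidence of the active types (capped at
  the survivor mass). The state's utility and one-time episode cost are
  incidence-weighted mixtures; the ventricular-arrhythmia entry is a
  decrement (-0.02) on the concurrent pump utility rather than an
  absolute utility. Occupants face the same pump mortality as stable
  patients and return to the stable/waiting state after one cycle.
* **Stroke timing.** "First month" rates apply to cycle 1, "months
  1–6" to cycles 2–6, "beyond 6 months" from cycle 7; analogously for
  the one-month split of disabling stroke and the one-year splits of the
  remaining complications.
* **Transplant complications.** No explicit state: their constant
  monthly rates adjust the post-transplant utility and monthly cost by
  expected value each cycle.
* **Fractional waits.** A waiting time W becomes floor(W) full tunnel
  cycles plus one fractional cycle with occupancy fraction frac(W),
  death probability `1-(1-p)^frac(W)` and pro-rated accrual; surgery
  occupies the following cycle with utility equal to the
  medical-management utility. During the final full cycle and the
  fractional cycle only mortality competes, so survivors transplant on
  schedule; the waiting clock keeps running through complication
  episodes.
* **Waiting-list inputs.** Control waiting-list mortality is the
  medical-management rate (the only candidate among the inputs);
  urgent-list months are costed as hospitalized medical treatment and
  pump-carrier months as outpatient pump waiting. The elective BTT wait
  defaults to 6.07 months; a 6.7-month variant appears in the source
  material's prose and the value is configurable.
* **Ages** (59 and 51) are cohort metadata only; no age-specific
  background mortality enters the transitions, because none is
  parameterized in the inputs.

## Sensitivity analyses

The one-way analysis re-evaluates a full strategy pair at both ends of
every parameter's variability range, with cost items at ±25% and the
discount rate from 0 to 10%; parameters without a range (transplant
complication rates, utilities reported with SEs only) are skipped with
a logged notice. Rows are ordered by ICER swing; a bound that produces
dominance sorts first.

The waiting-time scenario re-evaluates the BTT pair over a grid of
waits, by default with equal waits in both arms (the published
alternative scenario); a mode varying only the control wait is also
available.

The probabilistic analysis draws all uncertain parameters jointly and
independently per iteration: beta for probabilities and utilities
(method of moments from mean and SE; a range with no SE is read as a
95% interval, SE = width/3.92), negated beta for the arrhythmia
disutility, uniform for waiting times, and gamma multiplicative factors
with CV = 0.25/1.96 for every cost item including the device price.
Cost factors are shared between payer perspectives, preserving the
PS ≥ SS ordering draw by draw. Infeasible beta moments are clamped to
95% of the feasible standard deviation with a warning; draws are
reproducible bit-for-bit under a seed. Acceptability curves report the
fraction of draws with positive net monetary benefit on a grid of 0–6
GDP per capita in 0.1-GDP steps.

## Synthetic cost tables

The generator emulates the *structure* of the unpublished micro-costing
inputs: five state-occupancy monthly costs, one-time implantation,
transplant and per-complication episode costs, for both perspectives.
Constraints: the device price is fixed at the published ARS 7,104,276;
hospitalized months cost more than outpatient months; implantation >
transplant surgery > any episode; PS = SS × per-key uplifts in
[1.05, 1.40]. Magnitudes are centred so the destination-therapy
incremental cost lands near ARS 8M, i.e. in the published regime where
the device dominates the increment; values are jittered log-uniformly
within [0.8×, 1.25×] of their centres, deterministically per seed.
Passing cost-side tests therefore demonstrates correct mechanics and
realistic magnitudes, not agreement with the confidential values — for
that, the calibration slot accepts a user-supplied cost file and
refuses to run on a missing file rather than silently substituting.

## Numerical choices

Transition rows must sum to 1 within 1e-12, with the death row an exact
unit vector; violations raise errors naming the state and cycle. Cohort
conservation holds to 1e-10 over 1200 cycles. Matrices and accrual
vectors are cached per distinct cycle (schedules are constant beyond
the last tabulated month), keeping a full lifetime run of a six-state
model around ten milliseconds. The engine is verified against an
independent brute-force path-enumeration oracle on small models
(1e-10) and against closed-form discounted geometric sums (1e-8).

## What is and is not recoverable

With the conventions above, the package reproduces the published
control arms closely (medical management 0.403 discounted / 0.417
undiscounted QALYs versus 0.399/0.414; direct transplant 6.45 versus
6.16 discounted) and the published qualitative findings: all PSA draws
in the northeast quadrant for destination therapy, tornado diagrams led
by the discount rate and device price, ICERs falling steeply with
waiting time, and bridge-to-transplant far less cost-effective than
destination therapy.

The published *incremental* QALYs (3.505 for destination therapy, 0.74
for bridge to transplant) are not recoverable from the published inputs
under any convention this package exposes: the original intervention
arms imply both a materially shorter survival tail beyond the
60-month device-mortality schedule and additional mortality attached to
complication episodes, neither of which is parameterized in the
published input table. This package deliberately does not invent either
quantity; its intervention arms survive longer, and its incremental
QALYs are correspondingly larger (4.54 and 1.42). Users comparing
against the original numbers should treat the incremental effects as
convention-dependent and lean on the sensitivity machinery instead.

## Limitations

Cohort-level modelling only (no microsimulation, no staggered entry or
donor-supply dynamics); independent parameter draws; no age-dependent
background mortality; complication history does not alter subsequent
risks; synthetic costs are structural stand-ins. The exchange rate
(USD 1 = ARS 59.95, December 2019) is stored as metadata only — no
currency conversion is performed.
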