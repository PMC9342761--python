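# lvad-cea

Markov cohort cost-effectiveness models for a centrifugal-flow left
ventricular assist device (LVAD) in advanced heart failure, from two
Argentine third-party-payer perspectives (Social Security, SS, and
Private Sector, PS).

Two monthly-cycle cohort comparisons are implemented:

* **Model 1 — destination therapy (DT):** permanent pump implantation in
  transplant-ineligible patients (NYHA III/IV, INTERMACS 1–4) versus
  standard medical management (inotrope-dependent hospitalization for a
  quarter of surviving time, outpatient care otherwise).
* **Model 2 — bridge to transplant (BTT):** pump implantation while on
  the heart-transplant waiting list versus waiting on medical treatment
  and transplanting directly.

For each strategy pair the package computes, per patient over a
lifetime horizon with annual discounting applied at monthly resolution,

- cumulative costs `C = Σ_t d^t Σ_s m_t(s) c(s,t)` and quality-adjusted
  life years `E = Σ_t d^t Σ_s m_t(s) u(s,t)/12`, where `m_t` is the
  cohort distribution propagated through cycle-indexed row-stochastic
  transition matrices, `u` are health-state utilities, `c` monthly plus
  one-time event costs, and `d = (1+r)^(-1/12)`;
- the incremental cost-effectiveness ratio `ICER = ΔC/ΔE` with explicit
  dominance handling, and net monetary benefit `NMB = λ·ΔE − ΔC` at
  willingness-to-pay thresholds of 1–5 GDP per capita (ARS 700,473 each);
- one-way deterministic sensitivity analysis (tornado) over every
  parameter with a variability range, cost items at ±25% and the
  discount rate over 0–10%;
- a waiting-time scenario analysis for the BTT model;
- probabilistic sensitivity analysis (second-order Monte Carlo, beta
  utilities/probabilities, gamma costs, uniform waiting times) with
  cost-effectiveness plane and acceptability-curve outputs.

Clinical, epidemiological and utility inputs ship as a packaged,
validated parameter table (`lvad_cea/data/table1.yaml`). The underlying
micro-costing values are not public, so the `synthetic` module generates
cost tables with the published structure, orderings and device price
(ARS 7,104,276); a calibration slot accepts the real supplementary cost
file if a user can supply one.

## Worked example

```python
from lvad_cea import (load_parameters, generate_cost_table,
                      evaluate_model, nmb)

params = load_parameters()                  # packaged parameter table
costs = generate_cost_table(42, "SS")       # synthetic SS cost table
for model_id in ("DT", "BTT"):
    res = evaluate_model(model_id, params, costs)
    d = res.discounted
    print(model_id, round(d.delta_effect, 3), round(d.delta_cost),
          round(d.icer.value), round(nmb(res, 5 * 700_473)))
```

prints

```
DT 4.542 9330745 2054424 6576229
BTT 1.416 8464590 5979746 -3506840
```

i.e. with this synthetic cost table the pump as destination therapy
gains 4.54 discounted QALYs per patient at an extra ARS 9.33M — about
ARS 2.05M per QALY, cost-effective below a 5-GDP threshold (positive
NMB) — while as bridge to transplant it gains 1.42 QALYs at ARS 5.98M
per QALY, not cost-effective at the same threshold. The QALY columns
depend only on the packaged clinical inputs; the peso columns reflect
the synthetic cost table's seed.

The same analyses are available from the shell:

```bash
lvad-cea base --cost-seed 42 --out results/           # base_case.csv
lvad-cea sens --mode dsa --model DT --out results/    # tornado.csv
lvad-cea sens --mode scenario --out results/          # scenario.csv
lvad-cea sens --mode psa --n-iter 1000 --seed 7 --out results/ --plots
lvad-cea synth-costs --seed 42 --out costs.yaml
```

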