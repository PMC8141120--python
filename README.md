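# demcare-cua

Cost-utility analysis of a structured, multidisciplinary **medication review
to deprescribe psychotropic drugs** in institutionalized dementia patients,
built as a reusable Python library around a three-state Markov cohort model.

## Who this is for

Health economists and health-services researchers who want to reproduce,
stress or extend a MAFEIP-style decision-analytic evaluation of a
deprescribing intervention: derive the model parameters from published trial
inputs, run the cohort model, and classify the result on the
cost-effectiveness plane.

## The model

A cohort is distributed over three mutually exclusive states — baseline
health, deteriorated health (dementia), dead — and evolves in annual cycles.
Four transition probabilities drive it: incidence *i* (baseline →
deteriorated), recovery *r* (deteriorated → baseline, 0 here: dementia is
not reversible), and two death probabilities obtained by scaling the life
table's age/sex-specific annual death probability `qx`:

    p(death | state s, age x) = min(1, RR_s · qx(x))

Death resolves first within a cycle; incidence/recovery apply among
survivors. Each state carries an annual cost `c_s` and a utility `u_s`
(dead = 0), accumulated at end-of-cycle occupancy with optional annual
discounting, giving per-arm totals C and E (in QALYs). The decision rule
compares the two arms by

    ΔC = C_int − C_ctrl,   ΔE = E_int − E_ctrl,
    ICER = ΔC / ΔE,        NMB = λ·ΔE − ΔC   (λ = willingness to pay)

with the usual quadrant classification: **dominant** (ΔC < 0, ΔE > 0, always
accepted), **dominated** (ΔC > 0, ΔE < 0, always rejected), otherwise the
ICER is compared to λ (15,000 €/QALY by default).

The deteriorated-state mortality multipliers are themselves derived: a
neuroleptic withdrawal trial reports cumulative survival of 70/46/30 % (12/24/36
months) under continued neuroleptics vs 77/71/59 % after withdrawal; the
arm's mortality rate is 1 − mean(survival) (0.51 vs 0.31, 2 dp) and the
relative risk is 1 + excess, i.e. RR 1.51 vs 1.31. Deteriorated-state annual
drug costs are €2265.68 (pre-review) vs the mean of the 1- and 6-month
follow-ups, €1630.335; the review itself costs €48.56 per patient per year
(30 min of staff time at €97.12/h). Utilities are 0.70 (baseline) and 0.27
(deteriorated) in both arms.

A synthetic **Gompertz–Makeham life table**,
`qx(x) = 1 − exp(−(c + a·e^{b·x}))`, stands in for a national all-cause
mortality schedule; the headline classification depends only on `qx`
increasing with age, not on its exact values. A drug-box costing module
(dose × frequency × treatment days, capped at one year, rounded up to whole
boxes × price) supports the medication-review cost inputs.

## Worked example

```python
from demcare_cua import run_base_case

bundle = run_base_case(out_dir="results")
print(bundle["summary"])
```

which prints (age-averaged over starting ages 65–90, 12-month horizon,
default synthetic life table):

```
mean delta cost   =   -523.11 EUR   (negative: the review saves money)
mean delta effect =   0.00281 QALY  (positive: patients live longer)
ICER class        = dominant  (cheaper AND more effective)
NMB at 15,000 EUR/QALY = 565.32 EUR  -> accepted = True
```

The review is *dominant*: it saves about €523 per patient over 12 months
while adding a small survival-weighted quality-of-life gain, so it is
accepted at any willingness-to-pay threshold. Incremental costs are negative
at every single starting age and shrink in magnitude with age (older cohorts
die sooner, so fewer drug costs are saved). Over 40 years, a 200-patient
cohort entering at age 87 saves ≈ €278,000 and gains ≈ 29 QALYs
(`examples/population_impact.py`).

The `examples/` directory holds one short script per capability (parameter
derivation, base-case analysis, population impact, drug costing, state
flows); each prints its numbers with a line on what they mean. A thin CLI
offers the same entry points: `demcare-cua run`, `demcare-cua derive-params`,
`demcare-cua make-life-table`, `demcare-cua make-plans`.

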