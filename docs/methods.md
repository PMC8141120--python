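# Methods

## Model structure

The cohort model has three mutually exclusive states — baseline health,
deteriorated health (dementia), dead — evolving in annual cycles. The dead
state is absorbing. Within a cycle, death is resolved first and lateral
movement (incidence, recovery) applies among survivors, so a 40% incidence
means 40% of *surviving* baseline-state patients deteriorate. This ordering
is a modelling choice: resolving incidence first would make the per-cycle
death probability a mixture of the two states' risks; the difference is
second order in `qx` and does not affect any qualitative result here, but
the chosen order is the one under which "incidence" keeps its plain meaning.

State membership is valued at end of cycle (cycle t ≥ 1 contributions); a
half-cycle-correction switch (`ModelConfig.half_cycle_correction`) instead
values the mean of the cycle's start and end occupancies, the standard
mitigation of discretization bias. It is off by default so the base case is
the plain end-of-cycle accumulation.

Discount rates for costs and effects default to 0: the base-case horizon is
a single 12-month cycle, where discounting is immaterial. For the 40-year
population runs they are configurable (`discount_rate_costs`,
`discount_rate_effects`, per year, applied as `(1+r)^{-(t-1)}` so the first
cycle is undiscounted).

## Parameters

| parameter | control | intervention | units | origin |
|---|---|---|---|---|
| incidence | 0.40 | 0.40 | /cycle | dementia prevalence in the reference institutions, used as the per-cycle transition probability |
| recovery | 0 | 0 | /cycle | dementia is not reversible |
| RR mortality, baseline | 1 | 1 | – | national all-cause mortality unchanged |
| RR mortality, deteriorated | 1.51 | 1.31 | – | 1 + mortality rate derived from trial survival |
| cost, baseline state | 0 | 0 | €/yr | review targets only deteriorated-state patients |
| cost, deteriorated state | 2265.68 | 1630.335 | €/yr | drug costs pre-review; mean of 1- and 6-month follow-ups |
| recurrent intervention cost | 0 | 48.56 | €/patient/yr | 30 min staff time at €97.12/h |
| one-off intervention cost | 0 | 0 | €/patient | the guideline itself is free at point of use |
| utility baseline / deteriorated | 0.70 / 0.27 | same | – | secondary HR-QoL sources; the review affects mortality, not utility |

Derivation conventions:

* **Mortality rate** = 1 − arithmetic mean of the cumulative survival series
  (0.70, 0.46, 0.30 → 0.5133; 0.77, 0.71, 0.59 → 0.31). The mean of a
  cumulative series is a crude summary — it is used deliberately because it
  is the published derivation, reproduced digit for digit.
* **Relative risk** = 1 + excess, with the excess rounded to two decimals
  first so the published chain 0.5133 → 0.51 → 1.51 is exact;
  `rr_from_excess_mortality(..., round_excess=False)` keeps full precision
  for sensitivity work. The source material also describes the RR as a ratio
  of mortality rates; only the additive-excess reading reproduces the
  published values, so that is what is implemented. The RR is then applied
  *multiplicatively* to the life-table probability, `min(1, RR·qx)` — for a
  state-attributable excess this is the same thing, since excess =
  (RR−1)·baseline mortality; the cap at 1 keeps extreme ages valid.
* **Post-review state cost** uses the unrounded mean 1630.335 in all
  computation; the integer €1630 is a display rendering.
* The cohort size behind the €11,654.40 total intervention cost is 240
  (180 women at 75%).

The base case starts the cohort 100% in the deteriorated state — the review
is only applied to patients who already have dementia — with a 75% female
mix; female and male cohorts are simulated separately on their own
life-table columns and outcomes mixed linearly. A mixed-start preset is a
one-line config change (`initial_state_distribution`) and reproduces
two-alive-state flow curves. Whether the recurrent intervention cost applies
to all alive patients or only deteriorated ones is configurable
(`recurrent_cost_scope`, default `alive`); with a 100%-deteriorated start
and zero recovery the two coincide.

## Synthetic life table

`generate_gompertz_life_table` builds `qx(x) = 1 − exp(−(c + a·e^{bx}))`
over ages 65–110 by default (extendable; population runs from age 87 over 40
years need a table to age ≥ 126). Defaults a = 2.7·10⁻⁵, b = 0.095, c = 0
give qx ≈ 1.3% at 65, ≈ 10% at 87 and ≈ 60% at 110 — a plausible late-life
all-cause schedule for a high-income country. The same schedule is used for
both sexes unless per-sex parameters are supplied.

What this emulates, and what it does not: it reproduces the one property the
analysis depends on — mortality increasing with age — but not the level,
curvature or sex gap of any particular national table, nor period-vs-cohort
distinctions. Tests passing on these tables therefore establish the
*structural* results (dominance at every age for any age-increasing
schedule, arm survival ordering), not the euro values a specific national
table would produce; the by-age magnitudes in the worked example are
specific to the default schedule.

## Drug-box costing

Boxes = ⌈units/administration × administrations/day × min(days, 365) /
units/box⌉. Whole boxes (ceiling) because fractional boxes cannot be
dispensed; the rounding direction is this package's choice, as the source
states only "number of boxes". The one-year cap makes the result an annual
cost. The synthetic plan generator draws per-patient drug counts from a
Poisson with mean 8.04 (baseline polypharmacy of the cohort) and dosing,
pack size and price from the documented ranges in
`drug_costs.SYNTHETIC_RANGES`; it exists to exercise the costing pipeline,
not to mimic a real price catalogue.

## Decision analysis

`classify_icer` assigns the cost-effectiveness-plane quadrant: dominant
(ΔC < 0, ΔE > 0), dominated (ΔC > 0, ΔE < 0), otherwise a ratio compared to
the WTP (accept a gain priced ≤ λ per QALY; accept a QALY loss only if it
saves ≥ λ per QALY). Degenerate conventions, documented because the main
analysis never hits them: ΔE = 0 with ΔC ≠ 0 is a ratio with undefined ICER,
accepted iff ΔC < 0; ΔE = ΔC = 0 is flagged `equivalent` and accepted. The
summary ICER over the by-age grid uses the unweighted mean ΔC and ΔE across
starting ages (a uniform age profile), since no aggregation rule is
prescribed by the tool being emulated.

`population_cumulative` follows one cohort of `population_size` (default
200) entering at `population_start_age` (default 87, the cohort's mean age,
truncated to `age_max`) for T years, accumulating per-cycle incremental
contributions. Year 0 carries only the one-off cost difference (0 in the
base case).

## Numerical choices

* Probability conservation is exact up to float error; tests enforce 1e−10
  per cycle, and engine-vs-path-enumeration agreement at 1e−12 for horizons
  ≤ 3.
* Life-table CSVs are read with round-trip float precision so
  write-then-read is an identity.
* `min(1, RR·qx)` caps death probabilities; transition rows always sum to 1
  by constructing the stay-probability as the remainder.
* Report CSVs print floats with 6 decimals and are byte-identical across
  reruns of the same configuration.

## Problem sizes

The test suite and the reproduction script run the full by-age grid (26
starting ages × 2 sexes × 2 arms) at the 12-month horizon, 40-year
population runs, 100-draw engine-vs-enumeration checks (horizons ≤ 3, where
exhaustive path enumeration is tractable), and 1000-prescription costing
checks; the whole suite completes in a few seconds.

## Known limitations

* A cohort model: no patient-level heterogeneity, no time-in-state (tunnel)
  effects, exactly three states.
* The trial-derived mortality summary (1 − mean cumulative survival) mixes
  time horizons; it is reproduced as published, not re-estimated.
* All effectiveness inputs are taken as given parameters; the package does
  not estimate them from patient-level data.
* The 40-year cumulative incremental cost is not monotone: savings bottom
  out (≈ −€294k around year 10 for the default schedule) and then drift
  slightly upward, because the faster-dying control cohort stops incurring
  drug costs before the intervention cohort does. The curve stays strictly
  negative throughout.
* Societal costs and probabilistic sensitivity analysis are out of scope.
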