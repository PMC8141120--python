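"""Derive the Markov model's arm parameters from their published inputs.

The two mortality relative risks and the post-review state cost are not
primary data: they come from a neuroleptic withdrawal trial's survival
series and from the medication review's follow-up drug costs.
"""

from demcare_cua import (
    SurvivalSeries,
    mortality_rate_from_survival,
    post_intervention_state_cost,
    rr_from_excess_mortality,
)

# Cumulative survival at 12/24/36 months: continued neuroleptics vs withdrawal.
control = SurvivalSeries((12, 24, 36), (0.70, 0.46, 0.30))
intervention = SurvivalSeries((12, 24, 36), (0.77, 0.71, 0.59))

for label, s in (("control", control), ("intervention", intervention)):
    m = mortality_rate_from_survival(s)
    rr = rr_from_excess_mortality(m)
    print(f"{label:12s} mortality rate = 1 - mean{s.survival} = {m:.4f}"
          f"  ->  RR (deteriorated state) = {rr}")

cost = post_intervention_state_cost([1720.77, 1539.90])
print(f"post-review deteriorated-state cost = mean(1720.77, 1539.90)"
      f" = {cost:.3f} EUR/patient/year (prints as {round(cost)})")

# The RR is the mortality multiplier the cohort model applies to the life
# table's qx in the deteriorated (dementia) state; 1.51 vs 1.31 encodes the
# excess mortality attributable to continued neuroleptic use.
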