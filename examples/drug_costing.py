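"""Cost a therapeutic plan in whole dispensed boxes, and the review itself.

The medication-review costing converts each prescription's dose x frequency
x treatment length (capped at one year) into whole boxes; the intervention
is costed as structured staff time.
"""

from demcare_cua import (
    PrescriptionRecord,
    StaffTimeCost,
    annual_drug_cost,
    boxes_required,
    generate_synthetic_plans,
    per_patient_intervention_cost,
    total_intervention_cost,
)

rx = PrescriptionRecord(
    drug_name="risperidone 1 mg",
    units_per_administration=2,
    administrations_per_day=1,
    units_per_box=28,
    price_per_box=10.0,
    treatment_days=365,
)
print(f"{rx.drug_name}: {boxes_required(rx)} boxes/year "
      f"-> {annual_drug_cost([rx]):.2f} EUR/year")

staff = StaffTimeCost(minutes_per_patient=30, staff_rate_per_hour=97.12, n_patients=240)
print(f"review cost: {per_patient_intervention_cost(staff):.2f} EUR/patient, "
      f"{total_intervention_cost(staff):,.2f} EUR for the cohort")

# Synthetic plans at the baseline polypharmacy level (8.04 drugs/patient).
plans = generate_synthetic_plans(n_patients=240, mean_drugs=8.04, seed=42)
mean_cost = sum(annual_drug_cost(p) for p in plans) / len(plans)
print(f"synthetic cohort: mean {sum(map(len, plans)) / len(plans):.2f} drugs/patient, "
      f"mean annual drug cost {mean_cost:.2f} EUR/patient")
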