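"""Drug-box costing for medication reviews, and intervention staff costs.

The medication-review costing works at the level of dispensed boxes: for each
prescribed drug, the number of units consumed over the treatment (dose per
administration x administrations per day x treatment days, capped at one
year) is converted to whole boxes, and the annual drug cost is the sum over
the therapeutic plan of boxes x price per box. Boxes are rounded up — a
partial box must still be dispensed.

The intervention itself is costed as structured staff time: minutes of
multidisciplinary review per patient at an hourly staff rate. With the
default 30 min per patient and a rate of EUR 97.12/h this comes to
EUR 48.56 per patient, EUR 11,654.40 for a 240-patient cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

#: Treatment length is costed over at most one year.
MAX_TREATMENT_DAYS = 365

PRESCRIPTION_COLUMNS = [
    "patient_id",
    "drug_name",
    "units_per_administration",
    "administrations_per_day",
    "units_per_box",
    "price_per_box",
    "treatment_days",
]


@dataclass(frozen=True)
class PrescriptionRecord:
    """One drug line of a patient's therapeutic plan."""

    drug_name: str
    units_per_administration: float
    administrations_per_day: float
    units_per_box: int
    price_per_box: float
    treatment_days: int

    def __post_init__(self) -> None:
        if self.units_per_administration <= 0:
            raise ParameterError("units_per_administration must be > 0")
        if self.administrations_per_day <= 0:
            raise ParameterError("administrations_per_day must be > 0")
        if self.units_per_box < 1:
            raise ParameterError("units_per_box must be a positive integer")
        if self.price_per_box < 0:
            raise ParameterError("price_per_box must be >= 0")
        if self.treatment_days <= 0:
            raise ParameterError("treatment_days must be > 0")


@dataclass(frozen=True)
class StaffTimeCost:
    """Staff time spent per patient and its hourly rate."""

    minutes_per_patient: float
    staff_rate_per_hour: float
    n_patients: int

    def __post_init__(self) -> None:
        if self.minutes_per_patient <= 0:
            raise ParameterError("minutes_per_patient must be > 0")
        if self.staff_rate_per_hour < 0:
            raise ParameterError("staff_rate_per_hour must be >= 0")
        if self.n_patients <= 0:
            raise ParameterError("n_patients must be a positive integer")


def boxes_required(p: PrescriptionRecord) -> int:
    """Whole boxes needed to cover the treatment, capped at one year.

    ceil(units/administration * administrations/day * min(days, 365)
         / units/box)
    """
    days = min(p.treatment_days, MAX_TREATMENT_DAYS)
    units = p.units_per_administration * p.administrations_per_day * days
    return math.ceil(units / p.units_per_box)


def annual_drug_cost(plan: list[PrescriptionRecord]) -> float:
    """Total cost of a therapeutic plan: sum of boxes x price per box.

    An empty plan costs 0.
    """
    return float(sum(boxes_required(p) * p.price_per_box for p in plan))


def per_patient_intervention_cost(s: StaffTimeCost) -> float:
    """Staff cost of the review for one patient: (minutes / 60) x rate."""
    return s.minutes_per_patient / 60.0 * s.staff_rate_per_hour


def total_intervention_cost(s: StaffTimeCost) -> float:
    """Staff cost of reviewing the whole cohort."""
    return per_patient_intervention_cost(s) * s.n_patients


# --- synthetic therapeutic plans -------------------------------------------

#: Dosing and pricing ranges for the synthetic plan generator. Units per
#: administration and frequency cover common oral regimens; box sizes are
#: typical retail pack sizes; prices span cheap generics to mid-price brands.
SYNTHETIC_RANGES = {
    "units_per_administration": (0.5, 1.0, 2.0),
    "administrations_per_day": (1, 2, 3),
    "units_per_box": (10, 14, 20, 28, 30, 56, 60),
    "price_per_box": (2.0, 60.0),  # uniform
    "treatment_days": (30, 500),  # uniform integer; >365 exercises the cap
}


def generate_synthetic_plans(
    n_patients: int,
    mean_drugs: float = 8.04,
    seed: int = 0,
) -> list[list[PrescriptionRecord]]:
    """Draw reproducible synthetic therapeutic plans.

    Per-patient drug counts are Poisson with the given mean (default 8.04,
    the typical polypharmacy level of institutionalized dementia patients at
    review baseline); dosing, pack size and price are drawn from
    ``SYNTHETIC_RANGES``. Deterministic for a fixed seed.
    """
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    if mean_drugs <= 0:
        raise ParameterError("mean_drugs must be > 0")
    rng = np.random.default_rng(seed)
    plans: list[list[PrescriptionRecord]] = []
    for i in range(n_patients):
        n_drugs = int(rng.poisson(mean_drugs))
        plan = []
        for j in range(n_drugs):
            lo, hi = SYNTHETIC_RANGES["price_per_box"]
            dlo, dhi = SYNTHETIC_RANGES["treatment_days"]
            plan.append(
                PrescriptionRecord(
                    drug_name=f"drug_{i}_{j}",
                    units_per_administration=float(
                        rng.choice(SYNTHETIC_RANGES["units_per_administration"])
                    ),
                    administrations_per_day=float(
                        rng.choice(SYNTHETIC_RANGES["administrations_per_day"])
                    ),
                    units_per_box=int(rng.choice(SYNTHETIC_RANGES["units_per_box"])),
                    price_per_box=float(rng.uniform(lo, hi)),
                    treatment_days=int(rng.integers(dlo, dhi + 1)),
                )
            )
        plans.append(plan)
    return plans


def plans_to_frame(plans: list[list[PrescriptionRecord]]) -> pd.DataFrame:
    """Flatten plans to the prescription CSV layout (one row per drug line)."""
    rows = []
    for pid, plan in enumerate(plans):
        for p in plan:
            rows.append(
                (
                    pid,
                    p.drug_name,
                    p.units_per_administration,
                    p.administrations_per_day,
                    p.units_per_box,
                    p.price_per_box,
                    p.treatment_days,
                )
            )
    return pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS)


def read_prescriptions(path) -> list[list[PrescriptionRecord]]:
    """Read a prescription CSV into per-patient plans."""
    frame = pd.read_csv(path)
    missing = set(PRESCRIPTION_COLUMNS) - set(frame.columns)
    if missing:
        raise ParameterError(f"{path}: missing columns {sorted(missing)}")
    plans = []
    for _, grp in frame.groupby("patient_id", sort=True):
        plans.append(
            [
                PrescriptionRecord(
                    drug_name=str(r.drug_name),
                    units_per_administration=float(r.units_per_administration),
                    administrations_per_day=float(r.administrations_per_day),
                    units_per_box=int(r.units_per_box),
                    price_per_box=float(r.price_per_box),
                    treatment_days=int(r.treatment_days),
                )
                for r in grp.itertuples()
            ]
        )
    return plans
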