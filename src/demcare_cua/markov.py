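"""Three-state Markov cohort engine.

A cohort is distributed over three mutually exclusive health states —
baseline health, deteriorated health, dead — and evolves in annual cycles.
Four transition probabilities drive the movement: incidence (baseline ->
deteriorated), recovery (deteriorated -> baseline), and the two
state-specific death probabilities, obtained by multiplying the life table's
age- and sex-specific annual death probability qx by each state's relative
risk of mortality (capped at 1). Dead is absorbing.

Within a cycle, death is resolved first and incidence/recovery apply among
survivors, so a 40% incidence means 40% of surviving baseline-state patients
deteriorate. Costs and utilities attach to state membership at the end of
each cycle (no half-cycle correction by default; a switch is provided), and
an optional annual discount applies from the second cycle onward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AgeRangeError, ConsistencyError
from .life_tables import LifeTable
from .parameters import ArmParameters, ModelConfig

STATES = ("baseline", "deteriorated", "dead")
BASELINE, DETERIORATED, DEAD = 0, 1, 2


@dataclass(frozen=True)
class OccupancyTrajectory:
    """Per-cycle state-occupancy probabilities of one cohort.

    ``occupancy`` has shape (horizon + 1, 3); row 0 is the initial
    distribution, row t the distribution after t annual cycles.
    """

    occupancy: np.ndarray
    start_age: int
    sex: str
    arm_label: str = ""

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a table: cycle, age, p_baseline, p_deteriorated, p_dead."""
        cycles = np.arange(self.occupancy.shape[0])
        return pd.DataFrame(
            {
                "cycle": cycles,
                "age": self.start_age + cycles,
                "p_baseline": self.occupancy[:, BASELINE],
                "p_deteriorated": self.occupancy[:, DETERIORATED],
                "p_dead": self.occupancy[:, DEAD],
            }
        )


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for one arm: cost (EUR) and QALYs."""

    total_cost: float
    total_qalys: float
    trajectory: OccupancyTrajectory


def build_transition_matrix(
    age: int, sex: str, arm: ArmParameters, lt: LifeTable
) -> np.ndarray:
    """Per-cycle transition matrix at a given age.

    Rows are the from-states (baseline, deteriorated, dead); rows sum to 1.
    Death probabilities are min(1, RR * qx); incidence and recovery apply
    among survivors.
    """
    qx = lt.qx(age, sex)  # raises AgeRangeError if outside the table
    p_death_base = min(1.0, arm.rr_baseline * qx)
    p_death_det = min(1.0, arm.rr_deteriorated * qx)
    m = np.zeros((3, 3))
    m[BASELINE, DEAD] = p_death_base
    m[BASELINE, DETERIORATED] = (1.0 - p_death_base) * arm.incidence
    m[BASELINE, BASELINE] = (1.0 - p_death_base) * (1.0 - arm.incidence)
    m[DETERIORATED, DEAD] = p_death_det
    m[DETERIORATED, BASELINE] = (1.0 - p_death_det) * arm.recovery
    m[DETERIORATED, DETERIORATED] = (1.0 - p_death_det) * (1.0 - arm.recovery)
    m[DEAD, DEAD] = 1.0
    return m


def simulate_cohort(
    start_age: int,
    sex: str,
    arm: ArmParameters,
    cfg: ModelConfig,
    lt: LifeTable,
) -> OccupancyTrajectory:
    """Propagate the cohort distribution over ``cfg.horizon_cycles`` cycles.

    The transition matrix is rebuilt each cycle at the cohort's current age
    (start_age + t); the whole age span [start_age, start_age + horizon - 1]
    must be covered by the life table.
    """
    h = cfg.horizon_cycles
    if h > 0 and (start_age < lt.age_min or start_age + h - 1 > lt.age_max):
        raise AgeRangeError(
            f"horizon {h} from age {start_age} exceeds life table "
            f"[{lt.age_min}, {lt.age_max}]"
        )
    occ = np.zeros((h + 1, 3))
    occ[0, BASELINE], occ[0, DETERIORATED] = cfg.initial_state_distribution
    for t in range(h):
        m = build_transition_matrix(start_age + t, sex, arm, lt)
        occ[t + 1] = occ[t] @ m
    return OccupancyTrajectory(occ, start_age, sex, arm.label)


def cycle_contributions(
    traj: OccupancyTrajectory, arm: ArmParameters, cfg: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle discounted cost and QALY contributions.

    Index 0 carries only the undiscounted one-off intervention cost; cycle
    t >= 1 carries state-membership costs and utilities, discounted by
    (1 + r)^(t-1). With half-cycle correction, membership is valued at the
    mean of the cycle's start and end occupancies.
    """
    if traj.horizon != cfg.horizon_cycles:
        raise ConsistencyError(
            f"trajectory horizon {traj.horizon} != config horizon {cfg.horizon_cycles}"
        )
    h = traj.horizon
    costs = np.zeros(h + 1)
    qalys = np.zeros(h + 1)
    costs[0] = arm.intervention_oneoff_cost
    for t in range(1, h + 1):
        occ = traj.occupancy[t]
        if cfg.half_cycle_correction:
            occ = 0.5 * (traj.occupancy[t - 1] + traj.occupancy[t])
        alive = occ[BASELINE] + occ[DETERIORATED]
        recurrent_base = alive if cfg.recurrent_cost_scope == "alive" else occ[DETERIORATED]
        cost = (
            occ[BASELINE] * arm.cost_baseline
            + occ[DETERIORATED] * arm.cost_deteriorated
            + recurrent_base * arm.intervention_recurrent_cost
        )
        qaly = (
            occ[BASELINE] * arm.utility_baseline
            + occ[DETERIORATED] * arm.utility_deteriorated
        )
        costs[t] = cost / (1.0 + cfg.discount_rate_costs) ** (t - 1)
        qalys[t] = qaly / (1.0 + cfg.discount_rate_effects) ** (t - 1)
    return costs, qalys


def accumulate_outcomes(
    traj: OccupancyTrajectory, arm: ArmParameters, cfg: ModelConfig
) -> ArmOutcome:
    """Total discounted cost and QALYs over the horizon."""
    costs, qalys = cycle_contributions(traj, arm, cfg)
    return ArmOutcome(float(costs.sum()), float(qalys.sum()), traj)


def sex_mixed_outcome(
    start_age: int,
    arm: ArmParameters,
    cfg: ModelConfig,
    lt: LifeTable,
) -> tuple[float, float]:
    """(cost, QALYs) mixing female and male cohorts by ``cfg.sex_mix``.

    Female and male cohorts are simulated separately on their own life-table
    columns and the discounted totals combined as
    sex_mix * female + (1 - sex_mix) * male.
    """
    total_cost = 0.0
    total_qalys = 0.0
    for sex, w in (("female", cfg.sex_mix), ("male", 1.0 - cfg.sex_mix)):
        if w == 0.0:
            continue
        out = accumulate_outcomes(simulate_cohort(start_age, sex, arm, cfg, lt), arm, cfg)
        total_cost += w * out.total_cost
        total_qalys += w * out.total_qalys
    return total_cost, total_qalys
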