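"""Cost-effectiveness analysis on top of the Markov engine.

Incremental cost (delta C) and incremental effect (delta E, in QALYs) are
intervention minus control. The incremental cost-effectiveness ratio
ICER = delta C / delta E is classified against a willingness-to-pay (WTP)
threshold on the cost-effectiveness plane:

* **dominant** — cheaper and more effective (delta C < 0, delta E > 0);
  always accepted;
* **dominated** — dearer and less effective (delta C > 0, delta E < 0);
  always rejected;
* **ratio** — the remaining quadrants, accepted when the euros paid (or
  saved) per QALY gained (or forgone) compare favourably with the WTP.

Net monetary benefit NMB = WTP * delta E - delta C gives the same accept
decision on a monetary scale whenever delta E > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .life_tables import LifeTable, generate_gompertz_life_table
from .markov import cycle_contributions, simulate_cohort, sex_mixed_outcome
from .parameters import (
    ArmParameters,
    ModelConfig,
    load_config,
    packaged_base_case_path,
)

__all__ = [
    "CEAResult",
    "classify_icer",
    "incremental_by_age",
    "population_cumulative",
    "run_base_case",
]


@dataclass(frozen=True)
class CEAResult:
    """Incremental outcome and its decision classification.

    ``icer_value`` is present only for ratio-class results with a nonzero
    effect difference; ``equivalent`` flags the degenerate delta C = delta E
    = 0 case (accepted by convention). ``nmb`` is the net monetary benefit
    at the WTP used for classification.
    """

    delta_cost: float
    delta_effect: float
    icer_class: str  # dominant | dominated | ratio
    icer_value: float | None
    nmb: float
    accepted: bool
    equivalent: bool = False


def classify_icer(delta_cost: float, delta_effect: float, wtp: float) -> CEAResult:
    """Classify an incremental (cost, effect) pair against a WTP threshold."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    nmb = wtp * delta_effect - delta_cost
    if delta_cost < 0 and delta_effect > 0:
        return CEAResult(delta_cost, delta_effect, "dominant", None, nmb, True)
    if delta_cost > 0 and delta_effect < 0:
        return CEAResult(delta_cost, delta_effect, "dominated", None, nmb, False)
    if delta_effect == 0:
        # Undefined ratio: accept pure savings, reject pure extra cost.
        if delta_cost == 0:
            return CEAResult(0.0, 0.0, "ratio", None, nmb, True, equivalent=True)
        return CEAResult(delta_cost, 0.0, "ratio", None, nmb, delta_cost < 0)
    icer = delta_cost / delta_effect
    if delta_effect > 0:
        accepted = icer <= wtp  # paying at most WTP per QALY gained
    else:
        accepted = delta_cost < 0 and icer >= wtp  # saving at least WTP per QALY lost
    return CEAResult(delta_cost, delta_effect, "ratio", icer, nmb, accepted)


def incremental_by_age(
    control: ArmParameters,
    intervention: ArmParameters,
    cfg: ModelConfig,
    lt: LifeTable,
) -> pd.DataFrame:
    """Sex-mixed delta cost / delta effect for a fresh cohort at each
    starting age in [age_min, age_max]."""
    rows = []
    for age in range(cfg.age_min, cfg.age_max + 1):
        cost_c, qaly_c = sex_mixed_outcome(age, control, cfg, lt)
        cost_i, qaly_i = sex_mixed_outcome(age, intervention, cfg, lt)
        rows.append((age, cost_i - cost_c, qaly_i - qaly_c))
    return pd.DataFrame(rows, columns=["age", "delta_cost", "delta_effect"])


def _mixed_cycle_contributions(
    start_age: int, arm: ArmParameters, cfg: ModelConfig, lt: LifeTable
) -> tuple[np.ndarray, np.ndarray]:
    costs = np.zeros(cfg.horizon_cycles + 1)
    qalys = np.zeros(cfg.horizon_cycles + 1)
    for sex, w in (("female", cfg.sex_mix), ("male", 1.0 - cfg.sex_mix)):
        if w == 0.0:
            continue
        traj = simulate_cohort(start_age, sex, arm, cfg, lt)
        c, q = cycle_contributions(traj, arm, cfg)
        costs += w * c
        qalys += w * q
    return costs, qalys


def population_cumulative(
    control: ArmParameters,
    intervention: ArmParameters,
    cfg: ModelConfig,
    lt: LifeTable,
    T: int,
) -> pd.DataFrame:
    """Cumulative incremental cost and QALYs for a population over T years.

    A cohort of ``cfg.population_size`` enters at
    min(cfg.population_start_age, cfg.age_max) — by default the cohort's
    mean age, 87 — and is followed for T annual cycles. Year 0 carries only
    the one-off cost difference; later years accumulate the per-cycle
    incremental contributions.
    """
    start_age = min(cfg.population_start_age, cfg.age_max)
    run_cfg = ModelConfig(
        **{
            **_cfg_dict(cfg),
            "horizon_cycles": T,
        }
    )
    c_costs, c_qalys = _mixed_cycle_contributions(start_age, control, run_cfg, lt)
    i_costs, i_qalys = _mixed_cycle_contributions(start_age, intervention, run_cfg, lt)
    n = cfg.population_size
    inc_cost = n * (i_costs - c_costs)
    inc_qaly = n * (i_qalys - c_qalys)
    return pd.DataFrame(
        {
            "year": np.arange(T + 1),
            "cumulative_delta_cost": np.cumsum(inc_cost),
            "cumulative_delta_qalys": np.cumsum(inc_qaly),
        }
    )


def _cfg_dict(cfg: ModelConfig) -> dict:
    from dataclasses import asdict

    d = asdict(cfg)
    d["initial_state_distribution"] = tuple(d["initial_state_distribution"])
    return d


def run_base_case(
    config_path=None,
    out_dir="results",
    lt: LifeTable | None = None,
    population_years: int = 40,
) -> dict:
    """Run the full base-case analysis and write its report bundle.

    Loads the packaged base-case config unless ``config_path`` is given,
    computes incremental outcomes at every starting age, classifies the
    summary ICER (age-averaged delta C, delta E) against the configured WTP,
    follows a population cohort for ``population_years``, and writes:

    * ``incremental_by_age.csv`` — delta cost / delta effect per starting age
    * ``population_trajectory.csv`` — cumulative incremental cost and QALYs
    * ``trajectory_<arm>_<sex>.csv`` — state-occupancy flows at the
      population start age
    * ``cea_summary.csv`` — ICER class, value, NMB, accept decision
    * ``derived_parameters.txt`` — the parameter derivation chain

    Returns the bundle as a dict of DataFrames plus the ``CEAResult``.
    Deterministic: rerunning with the same config writes identical files.
    """
    if config_path is None:
        config_path = packaged_base_case_path()
    control, intervention, cfg = load_config(config_path)
    if lt is None:
        # Cover the population run: start age + horizon.
        lt = generate_gompertz_life_table(
            age_max=max(110, min(cfg.population_start_age, cfg.age_max) + population_years)
        )
    start_for_pop = min(cfg.population_start_age, cfg.age_max)
    max_years = lt.age_max - start_for_pop + 1
    if population_years > max_years:
        import warnings

        warnings.warn(
            f"population horizon truncated from {population_years} to {max_years} "
            f"years to fit the life table (max age {lt.age_max})",
            stacklevel=2,
        )
        population_years = max_years
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    by_age = incremental_by_age(control, intervention, cfg, lt)
    summary = classify_icer(
        float(by_age.delta_cost.mean()),
        float(by_age.delta_effect.mean()),
        cfg.wtp_threshold,
    )
    pop = population_cumulative(control, intervention, cfg, lt, population_years)

    ff = "%.6f"
    by_age.to_csv(out / "incremental_by_age.csv", index=False, float_format=ff)
    pop.to_csv(out / "population_trajectory.csv", index=False, float_format=ff)
    flow_cfg = ModelConfig(**{**_cfg_dict(cfg), "horizon_cycles": population_years})
    start_age = min(cfg.population_start_age, cfg.age_max)
    for arm in (control, intervention):
        for sex in ("female", "male"):
            traj = simulate_cohort(start_age, sex, arm, flow_cfg, lt)
            traj.to_frame().to_csv(
                out / f"trajectory_{arm.label}_{sex}.csv", index=False, float_format=ff
            )
    summary_frame = pd.DataFrame(
        [
            {
                "delta_cost": summary.delta_cost,
                "delta_effect": summary.delta_effect,
                "icer_class": summary.icer_class,
                "icer_value": "" if summary.icer_value is None else summary.icer_value,
                "nmb": summary.nmb,
                "wtp_threshold": cfg.wtp_threshold,
                "accepted": summary.accepted,
            }
        ]
    )
    summary_frame.to_csv(out / "cea_summary.csv", index=False, float_format=ff)
    (out / "derived_parameters.txt").write_text(_derivation_log(control, intervention))
    return {
        "incremental_by_age": by_age,
        "population_trajectory": pop,
        "summary": summary,
        "control": control,
        "intervention": intervention,
        "config": cfg,
    }


def _derivation_log(control: ArmParameters, intervention: ArmParameters) -> str:
    from . import parameters as P

    lines = [
        "Parameter derivation chain",
        "==========================",
        "",
        "Trial cumulative survival at 12/24/36 months:",
        f"  control (neuroleptic continuation): {list(P.CONTROL_SURVIVAL[1])}",
        f"  intervention (withdrawal):          {list(P.INTERVENTION_SURVIVAL[1])}",
        "",
        "Mortality rate = 1 - mean(survival):",
        f"  control:      1 - {np.mean(P.CONTROL_SURVIVAL[1]):.4f} = "
        f"{1 - np.mean(P.CONTROL_SURVIVAL[1]):.4f} -> 0.51 (2 dp)",
        f"  intervention: 1 - {np.mean(P.INTERVENTION_SURVIVAL[1]):.4f} = "
        f"{1 - np.mean(P.INTERVENTION_SURVIVAL[1]):.4f} -> 0.31 (2 dp)",
        "",
        "Relative risk (deteriorated state) = 1 + excess mortality:",
        f"  control:      {control.rr_deteriorated}",
        f"  intervention: {intervention.rr_deteriorated}",
        "",
        "Deteriorated-state annual drug cost (EUR/patient/year):",
        f"  control (pre-review):           {control.cost_deteriorated}",
        f"  intervention (mean of 1- and 6-month follow-ups "
        f"{list(P.FOLLOWUP_DRUG_COSTS)}): {intervention.cost_deteriorated}",
        "",
        "Intervention recurrent cost (staff time, EUR/patient/year): "
        f"{intervention.intervention_recurrent_cost}",
        f"Intervention one-off cost: {intervention.intervention_oneoff_cost}",
        "",
    ]
    return "\n".join(lines)
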