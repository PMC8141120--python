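import dataclasses

import numpy as np
import pytest

from demcare_cua import (
    AgeRangeError,
    ArmParameters,
    ConsistencyError,
    ModelConfig,
    accumulate_outcomes,
    build_transition_matrix,
    generate_gompertz_life_table,
    simulate_cohort,
)
from demcare_cua.markov import BASELINE, DEAD, DETERIORATED, cycle_contributions

from conftest import enumerate_occupancies, random_arm_kwargs


def neutral_arm(**kw):
    base = dict(
        incidence=0.0,
        recovery=0.0,
        rr_baseline=1.0,
        rr_deteriorated=1.0,
        cost_baseline=0.0,
        cost_deteriorated=0.0,
        intervention_recurrent_cost=0.0,
        intervention_oneoff_cost=0.0,
        utility_baseline=1.0,
        utility_deteriorated=1.0,
    )
    base.update(kw)
    return ArmParameters(**base)


class TestTransitionMatrix:
    def test_rows_sum_to_one(self, arms, life_table):
        for arm in arms:
            for age in (65, 80, 110):
                m = build_transition_matrix(age, "female", arm, life_table)
                assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
                assert ((m >= 0) & (m <= 1)).all()

    def test_dead_state_absorbing(self, arms, life_table):
        m = build_transition_matrix(80, "male", arms[0], life_table)
        assert m[DEAD, DEAD] == 1.0
        assert m[DEAD, BASELINE] == m[DEAD, DETERIORATED] == 0.0

    def test_neutral_parameters_leave_alive_states_parallel(self, life_table):
        m = build_transition_matrix(80, "female", neutral_arm(), life_table)
        qx = life_table.qx(80, "female")
        assert m[BASELINE, DEAD] == pytest.approx(qx)
        assert m[DETERIORATED, DEAD] == pytest.approx(qx)
        assert m[BASELINE, DETERIORATED] == 0.0
        assert m[DETERIORATED, BASELINE] == 0.0

    def test_zero_mortality_exposes_incidence_exactly(self):
        lt = generate_gompertz_life_table(a=0.0, b=1.0, c=0.0)
        m = build_transition_matrix(80, "female", neutral_arm(incidence=0.4), lt)
        assert m[BASELINE, DEAD] == 0.0
        assert m[BASELINE, DETERIORATED] == pytest.approx(0.4)

    def test_no_recovery_blocks_return_to_baseline(self, arms, life_table):
        m = build_transition_matrix(75, "female", arms[0], life_table)
        assert m[DETERIORATED, BASELINE] == 0.0

    def test_intervention_lowers_deteriorated_death_probability(self, arms, life_table):
        control, intervention = arms
        for age in range(65, 111):
            mc = build_transition_matrix(age, "female", control, life_table)
            mi = build_transition_matrix(age, "female", intervention, life_table)
            assert mc[DETERIORATED, DEAD] >= mi[DETERIORATED, DEAD]

    def test_rr_capped_at_one(self, life_table):
        arm = neutral_arm(rr_deteriorated=3.0)
        m = build_transition_matrix(130, "female", arm, life_table)
        assert m[DETERIORATED, DEAD] <= 1.0

    def test_age_outside_table_raises(self, arms, life_table):
        with pytest.raises(AgeRangeError):
            build_transition_matrix(131, "female", arms[0], life_table)


class TestSimulateCohort:
    def test_zero_horizon_returns_initial_distribution(self, arms, life_table):
        cfg = ModelConfig(horizon_cycles=0)
        traj = simulate_cohort(70, "female", arms[0], cfg, life_table)
        assert np.allclose(traj.occupancy, [[0.0, 1.0, 0.0]])

    def test_horizon_exceeding_table_raises(self, arms):
        lt = generate_gompertz_life_table(age_min=65, age_max=80)
        cfg = ModelConfig(horizon_cycles=10)
        with pytest.raises(AgeRangeError):
            simulate_cohort(75, "female", arms[0], cfg, lt)

    @pytest.mark.parametrize("horizon", [1, 2, 3])
    def test_matches_exhaustive_path_enumeration(self, life_table, horizon):
        rng = np.random.default_rng(42)
        for _ in range(100):
            arm = ArmParameters(**random_arm_kwargs(rng))
            init = rng.dirichlet([1, 1])
            cfg = ModelConfig(
                horizon_cycles=horizon,
                initial_state_distribution=(float(init[0]), float(init[1])),
            )
            start_age = int(rng.integers(65, 100))
            traj = simulate_cohort(start_age, "female", arm, cfg, life_table)
            mats = [
                build_transition_matrix(start_age + t, "female", arm, life_table)
                for t in range(horizon)
            ]
            oracle = enumerate_occupancies(
                np.array([init[0], init[1], 0.0]), mats
            )
            assert np.allclose(traj.occupancy, oracle, atol=1e-12)

    def test_conservation_and_monotonicity_on_random_draws(self, life_table):
        rng = np.random.default_rng(7)
        cfg = ModelConfig(horizon_cycles=20)
        for _ in range(50):
            arm = ArmParameters(**random_arm_kwargs(rng))
            traj = simulate_cohort(int(rng.integers(65, 110)), "male", arm, cfg, life_table)
            occ = traj.occupancy
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(np.diff(occ[:, DEAD]) >= -1e-12)

    def test_baseline_occupancy_non_increasing_without_recovery(self, arms, life_table):
        cfg = ModelConfig(horizon_cycles=20, initial_state_distribution=(0.6, 0.4))
        traj = simulate_cohort(65, "female", arms[0], cfg, life_table)
        assert np.all(np.diff(traj.occupancy[:, BASELINE]) <= 1e-12)

    def test_lower_relative_risk_dominates_survival(self, arms, life_table):
        # Lower deteriorated-state RR keeps more of the cohort alive at
        # every cycle, from every starting age.
        control, intervention = arms
        cfg = ModelConfig(horizon_cycles=20)
        for start_age in range(65, 91):
            tc = simulate_cohort(start_age, "female", control, cfg, life_table)
            ti = simulate_cohort(start_age, "female", intervention, cfg, life_table)
            alive_c = 1.0 - tc.occupancy[:, DEAD]
            alive_i = 1.0 - ti.occupancy[:, DEAD]
            assert np.all(alive_i >= alive_c - 1e-14)
            assert np.all(ti.occupancy[:, DEAD] <= tc.occupancy[:, DEAD] + 1e-14)


class TestAccumulateOutcomes:
    def test_full_health_no_discounting_counts_cycles(self):
        lt = generate_gompertz_life_table(a=0.0, b=1.0, c=0.0)
        arm = neutral_arm()
        cfg = ModelConfig(horizon_cycles=8, initial_state_distribution=(1.0, 0.0))
        out = accumulate_outcomes(simulate_cohort(70, "female", arm, cfg, lt), arm, cfg)
        assert out.total_qalys == pytest.approx(8.0)
        assert out.total_cost == 0.0

    def test_one_cycle_half_dead_deteriorated_cohort(self, arms):
        # qx chosen so the control arm's deteriorated death probability is
        # exactly 0.5; expected one-cycle totals by hand:
        # cost = 0.5 * 2265.68, QALYs = 0.5 * 0.27.
        control = arms[0]
        qx = 0.5 / control.rr_deteriorated
        import pandas as pd

        from demcare_cua import LifeTable

        frame = pd.DataFrame(
            [(a, s, qx) for s in ("female", "male") for a in (70, 71)],
            columns=["age", "sex", "qx"],
        )
        lt = LifeTable(frame)
        cfg = ModelConfig(horizon_cycles=1)
        out = accumulate_outcomes(
            simulate_cohort(70, "female", control, cfg, lt), control, cfg
        )
        assert out.total_cost == pytest.approx(0.5 * 2265.68)
        assert out.total_qalys == pytest.approx(0.5 * 0.27)

    def test_oneoff_cost_charged_undiscounted_at_entry(self, life_table):
        arm = neutral_arm(intervention_oneoff_cost=100.0)
        cfg = ModelConfig(horizon_cycles=0)
        out = accumulate_outcomes(simulate_cohort(70, "female", arm, cfg, life_table), arm, cfg)
        assert out.total_cost == 100.0

    def test_discounting_shrinks_later_contributions(self, arms, life_table):
        cfg0 = ModelConfig(horizon_cycles=10)
        cfg3 = ModelConfig(horizon_cycles=10, discount_rate_costs=0.03,
                           discount_rate_effects=0.03)
        traj = simulate_cohort(65, "female", arms[0], cfg0, life_table)
        out0 = accumulate_outcomes(traj, arms[0], cfg0)
        out3 = accumulate_outcomes(traj, arms[0], cfg3)
        assert out3.total_cost < out0.total_cost
        assert out3.total_qalys < out0.total_qalys
        # First-cycle contributions are undiscounted under both rates.
        c0, _ = cycle_contributions(traj, arms[0], cfg0)
        c3, _ = cycle_contributions(traj, arms[0], cfg3)
        assert c0[1] == pytest.approx(c3[1])

    def test_half_cycle_correction_averages_cycle_endpoints(self, arms, life_table):
        cfg = ModelConfig(horizon_cycles=1)
        cfg_hc = ModelConfig(horizon_cycles=1, half_cycle_correction=True)
        traj = simulate_cohort(80, "female", arms[0], cfg, life_table)
        plain = accumulate_outcomes(traj, arms[0], cfg)
        half = accumulate_outcomes(traj, arms[0], cfg_hc)
        # Starting 100% deteriorated with deaths during the cycle, mid-cycle
        # valuation credits more occupancy than end-of-cycle valuation.
        assert half.total_qalys > plain.total_qalys
        expected = 0.5 * (1.0 + traj.occupancy[1, DETERIORATED]) * 0.27
        assert half.total_qalys == pytest.approx(expected)

    def test_monotone_in_cost_and_utility_parameters(self, arms, life_table):
        cfg = ModelConfig(horizon_cycles=5)
        base = arms[0]
        traj = simulate_cohort(70, "female", base, cfg, life_table)
        out = accumulate_outcomes(traj, base, cfg)
        richer = dataclasses.replace(base, cost_deteriorated=base.cost_deteriorated + 100)
        happier = dataclasses.replace(
            base, utility_deteriorated=min(1.0, base.utility_deteriorated + 0.1)
        )
        assert accumulate_outcomes(traj, richer, cfg).total_cost >= out.total_cost
        assert accumulate_outcomes(traj, happier, cfg).total_qalys >= out.total_qalys

    def test_mismatched_horizon_rejected(self, arms, life_table):
        traj = simulate_cohort(70, "female", arms[0], ModelConfig(horizon_cycles=2), life_table)
        with pytest.raises(ConsistencyError):
            accumulate_outcomes(traj, arms[0], ModelConfig(horizon_cycles=3))
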