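import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from demcare_cua import (
    base_case_arms,
    base_case_config,
    generate_gompertz_life_table,
)


@pytest.fixture(scope="session")
def life_table():
    """Default synthetic Gompertz table, extended to cover 40-year runs."""
    return generate_gompertz_life_table(age_max=130)


@pytest.fixture(scope="session")
def arms():
    return base_case_arms()


@pytest.fixture(scope="session")
def config():
    return base_case_config()


def enumerate_occupancies(initial, matrices):
    """Independent oracle: occupancy per cycle by exhaustive path enumeration.

    Sums the probability of every explicit state path s0 -> s1 -> ... -> sH
    (initial probability times the product of per-cycle transition entries),
    grouped by the state occupied at each cycle. Exponential in the horizon;
    usable only for tiny H.
    """
    h = len(matrices)
    occ = np.zeros((h + 1, 3))
    for t in range(h + 1):
        for path in itertools.product(range(3), repeat=t + 1):
            p = initial[path[0]]
            for k in range(t):
                p *= matrices[k][path[k], path[k + 1]]
            occ[t, path[t]] += p
    return occ


def random_arm_kwargs(rng):
    """Random valid arm parameters for property tests."""
    return dict(
        incidence=rng.uniform(0, 1),
        recovery=rng.uniform(0, 1),
        rr_baseline=rng.uniform(0, 3),
        rr_deteriorated=rng.uniform(0, 3),
        cost_baseline=rng.uniform(0, 5000),
        cost_deteriorated=rng.uniform(0, 5000),
        intervention_recurrent_cost=rng.uniform(0, 100),
        intervention_oneoff_cost=rng.uniform(0, 100),
        utility_baseline=rng.uniform(0, 1),
        utility_deteriorated=rng.uniform(0, 1),
    )
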