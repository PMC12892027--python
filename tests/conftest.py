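"""Shared fixtures: small synthetic populations, a default simulation run,
and the deterministic reference bundle with its cleaned outputs."""

import numpy as np
import pytest

from webrds import (
    REFERENCE_INTAKE_CONFIG,
    PopulationConfig,
    SimulationConfig,
    generate_population,
    make_reference_fixture,
    run_intake,
    run_recruitment,
)

NO_FRAUD = dict(
    p_ineligible_use=0.0,
    p_duplicate_attempt=0.0,
    p_self_recruit=0.0,
    p_incomplete=0.0,
    p_inconsistent=0.0,
    participation_prob={"low": 1.0, "high": 1.0},
    incentive_schedule={0: "high"},
)


@pytest.fixture(scope="session")
def small_population():
    return generate_population(
        PopulationConfig(
            n_total=6000, prevalence_eligible=0.10, mean_degree=7, rng_seed=11
        )
    )


@pytest.fixture(scope="session")
def sim_result(small_population):
    return run_recruitment(
        small_population, SimulationConfig(rng_seed=11, target_n=250)
    )


@pytest.fixture(scope="session")
def clean_sim_result(small_population):
    """Simulation with every pathology switched off."""
    return run_recruitment(
        small_population,
        SimulationConfig(rng_seed=13, target_n=250, **NO_FRAUD),
    )


@pytest.fixture(scope="session")
def reference_bundle():
    return make_reference_fixture()


@pytest.fixture(scope="session")
def reference_intake(reference_bundle):
    return run_intake(
        reference_bundle.roster, reference_bundle.ledger, REFERENCE_INTAKE_CONFIG
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
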