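"""Estimator-validation loops on synthetic populations.

The study design applies no estimator to its own data; the weighting
machinery here is validated the only way it can be — by parameter recovery
on populations whose truth is known. A binary trait is planted with a
known prevalence and a positive degree correlation, chain-referral samples
are drawn by the simulator, and the RDS-II (reciprocal-degree) estimate is
compared with the unweighted sample mean against the true share.
"""

from __future__ import annotations

import numpy as np

from .degrees import build_degree_records, impute_degrees
from .intake import run_intake
from .population import PopulationConfig, degree_correlated_trait, generate_population
from .analysis import rds2_estimate
from .simulator import SimulationConfig, run_recruitment

NO_PATHOLOGY = dict(
    p_ineligible_use=0.0,
    p_duplicate_attempt=0.0,
    p_self_recruit=0.0,
    p_incomplete=0.0,
    p_inconsistent=0.0,
    participation_prob={"low": 0.9, "high": 0.9},
    incentive_schedule={0: "high"},
)


def estimator_recovery(
    sample_n: int = 500,
    n_populations: int = 10,
    runs_per_population: int = 10,
    prevalence: float = 0.30,
    degree_slope: float = 0.035,
    n_total: int = 40_000,
    prevalence_eligible: float = 0.10,
    mean_degree: float = 8.0,
    rng_seed: int = 0,
) -> dict:
    """Parameter recovery of a planted trait share via RDS-II weighting.

    Draws `runs_per_population` chain-referral samples of `sample_n` from
    each of `n_populations` independent populations; the planted trait has
    expected share `prevalence` and probability rising with degree
    (`degree_slope` points per unit degree), so chain-referral sampling —
    which reaches high-degree members more often — biases the unweighted
    mean upward. Returns per-replicate estimates and mean signed biases
    relative to each population's realized truth.
    """
    est_rds2, est_plain, truths = [], [], []
    for i in range(n_populations):
        pop = generate_population(
            PopulationConfig(
                n_total=n_total,
                prevalence_eligible=prevalence_eligible,
                mean_degree=mean_degree,
                rng_seed=rng_seed * 1000 + i,
            )
        )
        trait_rng = np.random.default_rng(rng_seed * 1000 + 500 + i)
        trait = degree_correlated_trait(pop, prevalence, degree_slope, trait_rng)
        truth = float(trait.mean())
        for j in range(runs_per_population):
            sim = run_recruitment(
                pop,
                SimulationConfig(
                    rng_seed=rng_seed * 1000 + 10 * i + j,
                    target_n=sample_n,
                    **NO_PATHOLOGY,
                ),
            )
            cleaned = run_intake(sim.roster, sim.ledger)
            degrees = impute_degrees(
                build_degree_records(cleaned.analysis_roster, sim.forest)
            ).set_index("person_id")["degree_final"]
            labels = trait.loc[degrees.index].map({True: "yes", False: "no"})
            est = rds2_estimate(labels, degrees)
            est_rds2.append(est.proportions.get("yes", 0.0))
            est_plain.append(float(labels.eq("yes").mean()))
            truths.append(truth)
    est_rds2 = np.asarray(est_rds2)
    est_plain = np.asarray(est_plain)
    truths = np.asarray(truths)
    return {
        "n_replicates": len(est_rds2),
        "sample_n": sample_n,
        "truth_mean": float(truths.mean()),
        "mean_rds2": float(est_rds2.mean()),
        "mean_unweighted": float(est_plain.mean()),
        "bias_rds2": float((est_rds2 - truths).mean()),
        "bias_unweighted": float((est_plain - truths).mean()),
        "abs_error_rds2": float(np.abs(est_rds2 - truths).mean()),
        "abs_error_unweighted": float(np.abs(est_plain - truths).mean()),
    }
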