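"""End-to-end pipeline driver, run manifest and study-report renderer.

run_all ties the stages together — generate population, simulate
recruitment, clean the roster, impute degrees, run diagnostics — and
renders a markdown report in which every number is recomputed from the
stage outputs. The manifest records the configuration hash, seeds and
output checksums so a run can be audited and reproduced byte for byte.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .analysis import (
    convergence_trace,
    rds2_estimate,
    recruitment_homophily,
    wave_statistics,
)
from .degrees import build_degree_records, degree_summary, impute_degrees
from .intake import IntakeConfig, IntakeResult, run_intake
from .population import Population, PopulationConfig, generate_population
from .simulator import (
    SimulationConfig,
    SimulationResult,
    coupon_exhaustion,
    recruiter_productivity,
    run_recruitment,
)


class AnalysisOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    convergence_variables: list[str] = Field(
        default_factory=lambda: ["age_group", "sex"]
    )
    window_frac: float = 0.25
    tol: float = 0.02
    estimate_variables: list[str] = Field(default_factory=lambda: ["sex"])
    include_seeds: bool = True


class PipelineConfig(BaseModel):
    """Single JSON configuration with one block per stage."""

    model_config = ConfigDict(extra="forbid")

    population: PopulationConfig
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    intake: IntakeConfig = Field(default_factory=IntakeConfig)
    analysis: AnalysisOptions = Field(default_factory=AnalysisOptions)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


@dataclass
class RunManifest:
    config_hash: str
    rng_seeds: dict[str, int]
    package_version: str
    checksums: dict[str, str] = dc_field(default_factory=dict)
    created_at: str = dc_field(
        default_factory=lambda: dt.datetime.now(dt.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class RunResult:
    config: PipelineConfig
    population: Population
    simulation: SimulationResult
    intake: IntakeResult
    degrees: pd.DataFrame
    report_md: str
    manifest: RunManifest

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.simulation.write(out / "simulated")
        self.intake.write(out / "cleaned")
        self.degrees.to_csv(out / "degrees.csv", index=False)
        (out / "report.md").write_text(self.report_md)
        for rel in [
            "simulated/attempt_roster.csv",
            "simulated/coupon_ledger.csv",
            "simulated/forest_edges.csv",
            "cleaned/analysis_roster.csv",
            "degrees.csv",
        ]:
            self.manifest.checksums[rel] = _sha256(out / rel)
        (out / "manifest.json").write_text(self.manifest.to_json())


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def analysis_person_ids(intake: IntakeResult, simulation: SimulationResult) -> set[str]:
    """Forest person_ids of the analysis roster (linked via the enrollment
    coupon, the only identifier the observed bundle shares with the
    forest)."""
    codes = set(intake.analysis_roster["coupon_code"].astype(str))
    parts = simulation.forest.participants
    return set(parts.index[parts["coupon_code"].astype(str).isin(codes)])


def run_all(config: PipelineConfig) -> RunResult:
    """Simulate -> clean -> impute -> analyze, and render the report."""
    population = generate_population(config.population)
    simulation = run_recruitment(population, config.simulation)
    intake = run_intake(simulation.roster, simulation.ledger, config.intake)
    records = build_degree_records(intake.analysis_roster, simulation.forest)
    degrees = impute_degrees(records)
    report = render_report(config, population, simulation, intake, degrees)
    manifest = RunManifest(
        config_hash=_config_hash(config),
        rng_seeds={
            "population": config.population.rng_seed,
            "simulation": config.simulation.rng_seed,
        },
        package_version=__version__,
    )
    return RunResult(
        config=config,
        population=population,
        simulation=simulation,
        intake=intake,
        degrees=degrees,
        report_md=report,
        manifest=manifest,
    )


def render_report(
    config: PipelineConfig,
    population: Population,
    simulation: SimulationResult,
    intake: IntakeResult,
    degrees: pd.DataFrame,
) -> str:
    """Markdown study report; every figure is recomputed from the frames."""
    funnel = intake.funnel
    ws = wave_statistics(simulation.forest)
    analysis_ids = analysis_person_ids(intake, simulation)
    prod = recruiter_productivity(simulation.forest, include=analysis_ids)
    n_prod = sum(prod.values())
    n_exh, n_any, exh_pct = coupon_exhaustion(
        simulation.ledger, config.simulation.coupons_per_participant
    )
    summ = degree_summary(degrees)

    lines = [
        "# web-RDS run report",
        "",
        "## Cleaning funnel",
        "",
        "| stage | n | % |",
        "|---|---|---|",
        f"| access attempts | {funnel.n_attempts} | |",
        f"| blocked automatically | {funnel.n_blocked_auto} | {funnel.percentages['blocked_auto']} |",
        f"| removed in manual review | {funnel.n_invalid_manual} | {funnel.percentages['invalid_manual']} |",
        f"| ineligible | {funnel.n_ineligible} | {funnel.percentages['ineligible']} |",
        f"| duplicate or ineligible (total) | {funnel.n_invalid_or_ineligible} | {funnel.percentages['invalid_or_ineligible']} |",
        f"| incomplete | {funnel.n_incomplete} | {funnel.percentages['incomplete']} |",
        f"| valid participants | {funnel.n_valid} | {funnel.percentages['valid']} |",
        f"| device-use inconsistencies | {funnel.n_inconsistent} | {funnel.percentages['inconsistent_of_valid']} of valid |",
        f"| analysis roster | {funnel.n_analysis} | |",
        "",
        "## Recruitment",
        "",
        f"- participants in forest: {ws.n_participants}; maximum wave depth: {ws.max_depth}",
        f"- seeds without recruits: {ws.n_unproductive_seeds} of {len(simulation.forest.seed_ids())}",
        f"- productive recruiters: {n_prod}"
        + (
            " ("
            + ", ".join(
                f"{k} recruit{'s' if k > 1 else ''}: {v} "
                f"[{100.0 * v / n_prod:.1f}%]"
                for k, v in sorted(prod.items())
            )
            + ")"
            if n_prod
            else ""
        ),
        f"- invitation exhaustion: {n_exh}/{n_any} participants with any coupon use spent all "
        f"{config.simulation.coupons_per_participant} ({exh_pct}%)",
        "",
        "## Network size",
        "",
        f"- analyzed respondents: {summ['n']}; degree <= 5: {summ['n_le5']} ({summ['pct_le5']}%); "
        f"degree > 10: {summ['n_gt10']} ({summ['pct_gt10']}%); max {summ['max']}; mode {summ['mode']}",
        f"- imputed: {summ['n_imputed']} ({summ['pct_imputed']}%) — "
        f"q1 substituted: {summ['imputed']['q1_substituted']}, "
        f"mean substituted: {summ['imputed']['mean_substituted']}",
        "",
        "## Convergence",
        "",
    ]
    for var in config.analysis.convergence_variables:
        try:
            tr = convergence_trace(
                intake.analysis_roster,
                var,
                window_frac=config.analysis.window_frac,
                tol=config.analysis.tol,
            )
        except (KeyError, ValueError) as exc:
            lines.append(f"- {var}: not assessed ({exc})")
            continue
        verdict = "converged" if tr.converged else "NOT converged"
        cat = f" (category {tr.category})" if tr.category is not None else ""
        lines.append(
            f"- {var}{cat}: {verdict} at final value {tr.trace[-1]:.3f} "
            f"(window {tr.window_frac}, tol {tr.tol})"
        )

    if config.analysis.estimate_variables:
        lines += ["", "## RDS-II estimates", ""]
        parts = simulation.forest.participants
        code_to_pid = {
            str(r["coupon_code"]): pid for pid, r in parts.iterrows()
        }
        roster = intake.analysis_roster
        pids = [code_to_pid[str(c)] for c in roster["coupon_code"]]
        dmap = degrees.set_index("person_id")["degree_final"]
        for var in config.analysis.estimate_variables:
            if var not in roster.columns:
                lines.append(f"- {var}: not present")
                continue
            traits = pd.Series(list(roster[var]), index=pids)
            est = rds2_estimate(traits, dmap.loc[pids], variable=var)
            pretty = ", ".join(f"{c}: {p:.3f}" for c, p in est.proportions.items())
            lines.append(f"- {var}: {pretty} (n={est.n})")
        hom = recruitment_homophily(
            simulation.forest, population.nodes["zone"]
        )
        pretty = ", ".join(
            f"{c}: {('%.2f' % v) if v is not None else 'undefined'}"
            for c, v in hom.items()
        )
        lines += ["", f"Recruitment homophily (zone): {pretty}"]

    return "\n".join(lines) + "\n"
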