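"""Recruitment diagnostics, RDS-II weighting and design-effect tooling.

Covers the standard analysis companion to a chain-referral survey:

* the design-effect sample-size calculation n = p(1-p)/SE^2, inflated by
  the design effect and an anticipated loss fraction;
* recruitment-forest diagnostics — wave depth, per-wave counts, seed
  productivity and a per-category recruitment homophily index;
* convergence traces — cumulative sample proportions (or means) in
  enrollment order, with a window/tolerance stabilization check replacing
  the usual visual read of the plots;
* the Volz-Heckathorn (RDS-II) estimator, which weights each participant
  by the reciprocal of their reported network size to undo the
  degree-proportional inclusion of chain-referral sampling;
* a seed-level chain bootstrap that resamples whole recruitment chains to
  estimate the design effect of the realized chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from ._util import STREAM_BOOTSTRAP, derived_rng
from .simulator import RecruitmentForest


class SampleSizeSpec(BaseModel):
    """Inputs of the design-effect sample-size calculation."""

    model_config = ConfigDict(extra="forbid")

    p: float
    se: float = Field(gt=0)
    deff: float = Field(default=1.0, ge=1.0)
    loss_rate: float = Field(default=0.0, ge=0.0)

    @field_validator("p")
    @classmethod
    def _p_open(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("anticipated proportion must lie in (0, 1)")
        return v


def sample_size(spec: SampleSizeSpec) -> tuple[int, int, int]:
    """(n_unadjusted, n_min, n_target).

    n_unadjusted = ceil(p(1-p)/se^2) assumes simple random sampling;
    n_min multiplies by the design effect; n_target adds the anticipated
    loss margin. With p=0.5, se=0.05, deff=2.5, loss=0.2 this yields
    (100, 250, 300).
    """
    n_unadjusted = math.ceil(spec.p * (1.0 - spec.p) / spec.se**2)
    n_min = math.ceil(n_unadjusted * spec.deff)
    n_target = math.ceil(n_min * (1.0 + spec.loss_rate))
    return n_unadjusted, n_min, n_target


# --------------------------------------------------------------------------
# forest diagnostics
# --------------------------------------------------------------------------

@dataclass
class WaveStatistics:
    max_depth: int
    per_wave: dict[int, int]
    n_participants: int
    seeds_without_recruits: list[str]

    @property
    def n_unproductive_seeds(self) -> int:
        return len(self.seeds_without_recruits)


def wave_statistics(forest: RecruitmentForest) -> WaveStatistics:
    p = forest.participants
    per_wave = {int(w): int(c) for w, c in p["wave"].value_counts().sort_index().items()}
    recruiters = set(p["recruiter_id"].dropna().astype(str))
    unproductive = [s for s in forest.seed_ids() if s not in recruiters]
    return WaveStatistics(
        max_depth=int(p["wave"].max()) if len(p) else 0,
        per_wave=per_wave,
        n_participants=len(p),
        seeds_without_recruits=sorted(unproductive),
    )


def recruitment_homophily(
    forest: RecruitmentForest, traits: pd.Series
) -> dict[str, float | None]:
    """Per-category recruitment homophily index.

    For category c: (share of c-recruiters' recruitments that stay within
    c) divided by (sample share of c). 1 means proportionate mixing, >1
    within-group preference, 0 no within-group recruitment. Categories
    absent from the sample are reported as None (undefined).
    """
    edges = forest.edges
    labels = traits.astype(str)
    sample = labels.loc[forest.participants.index]
    shares = sample.value_counts(normalize=True)
    out: dict[str, float | None] = {}
    for c in sorted(shares.index):
        share = float(shares[c])
        if share == 0:
            out[c] = None
            continue
        mask = labels.loc[edges["recruiter_id"]].values == c
        n_from_c = int(mask.sum())
        if n_from_c == 0:
            out[c] = None
            continue
        within = int(
            (labels.loc[edges.loc[mask, "recruit_id"]].values == c).sum()
        )
        out[c] = (within / n_from_c) / share
    return out


# --------------------------------------------------------------------------
# convergence
# --------------------------------------------------------------------------

@dataclass
class ConvergenceTrace:
    variable: str
    category: str | None
    trace: np.ndarray  # cumulative proportion/mean after each enrollment
    converged: bool
    window_frac: float
    tol: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "enrollment_index": np.arange(1, len(self.trace) + 1),
                "cumulative_value": self.trace,
            }
        )


def convergence_trace(
    roster: pd.DataFrame,
    variable: str,
    category: str | None = None,
    window_frac: float = 0.25,
    tol: float = 0.02,
    order_by: str = "attempt_id",
) -> ConvergenceTrace:
    """Cumulative sample proportion (or mean) of a variable in enrollment
    order, with a stabilization verdict.

    For a categorical variable pass the category of interest (default: the
    most frequent one). converged is True iff every value in the final
    window_frac of enrollments deviates from the final value by less than
    tol — a mechanical stand-in for reading the cumulative plot.
    """
    if variable not in roster.columns:
        raise KeyError(f"variable {variable!r} not in roster")
    ordered = roster.sort_values(order_by, kind="mergesort")[variable].dropna()
    if len(ordered) == 0:
        raise ValueError(f"variable {variable!r} has no observed values")
    if pd.api.types.is_numeric_dtype(ordered) and category is None:
        values = ordered.astype(float).to_numpy()
    else:
        if category is None:
            category = str(ordered.astype(str).value_counts().idxmax())
        values = (ordered.astype(str) == category).astype(float).to_numpy()
    trace = np.cumsum(values) / np.arange(1, len(values) + 1)
    n_window = max(1, int(math.ceil(window_frac * len(trace))))
    final = trace[-1]
    converged = bool(np.all(np.abs(trace[-n_window:] - final) < tol))
    return ConvergenceTrace(
        variable=variable,
        category=category,
        trace=trace,
        converged=converged,
        window_frac=window_frac,
        tol=tol,
    )


# --------------------------------------------------------------------------
# RDS-II estimation
# --------------------------------------------------------------------------

@dataclass
class RDS2Estimate:
    variable: str
    proportions: dict[str, float]
    weights: pd.Series  # normalized, indexed by person_id
    n: int


def rds2_estimate(
    traits: pd.Series,
    degrees: pd.Series,
    variable: str = "trait",
    include_seeds: bool = True,
    seed_ids: set[str] | None = None,
) -> RDS2Estimate:
    """Volz-Heckathorn weighted proportions.

    Each participant i with operative degree d_i gets weight proportional
    to 1/d_i (their selection probability under chain-referral sampling is
    approximately proportional to d_i). For category c the estimate is
    sum_{i: x_i=c} 1/d_i over sum_i 1/d_i. traits and degrees must share a
    person_id index; set include_seeds=False (with seed_ids) to drop the
    researcher-selected seeds from estimation.
    """
    joined = pd.DataFrame({"x": traits, "d": degrees}).dropna()
    if not include_seeds:
        if seed_ids is None:
            raise ValueError("seed_ids required when include_seeds=False")
        joined = joined[~joined.index.isin(seed_ids)]
    if len(joined) == 0:
        raise ValueError("no participants left to estimate from")
    d = joined["d"].astype(float)
    if (d <= 0).any():
        raise ValueError("all degrees must be positive (impute first)")
    w = (1.0 / d) / (1.0 / d).sum()
    props = {
        str(c): float(w[joined["x"].astype(str) == str(c)].sum())
        for c in sorted(joined["x"].astype(str).unique())
    }
    return RDS2Estimate(
        variable=variable, proportions=props, weights=w, n=len(joined)
    )


def chain_bootstrap_deff(
    traits: pd.Series,
    degrees: pd.Series,
    forest: RecruitmentForest,
    category: str,
    n_boot: int = 500,
    rng_seed: int = 0,
) -> dict:
    """Design effect of the realized chains for one category share,
    via a seed-level bootstrap.

    Seeds are resampled with replacement and each drawn seed carries its
    whole recruitment chain; the RDS-II estimate is recomputed per
    replicate. deff = bootstrap variance / (p_hat (1 - p_hat) / n), the
    variance an SRS of the same size would have.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    seeds = forest.seed_ids()
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds to bootstrap chains")
    rng = derived_rng(rng_seed, STREAM_BOOTSTRAP)
    chains = {
        s: list(forest.participants.index[forest.participants["seed_id"] == s])
        for s in seeds
    }
    obs = pd.DataFrame({"x": traits, "d": degrees}).dropna()
    point = rds2_estimate(obs["x"], obs["d"]).proportions.get(str(category), 0.0)
    x_all = obs["x"].astype(str)
    inv_w = 1.0 / obs["d"].astype(float)
    # per-chain sufficient statistics: the RDS-II ratio is (sum of chain
    # numerators) / (sum of chain denominators) of the drawn chains
    chain_num: dict[str, float] = {}
    chain_den: dict[str, float] = {}
    for s in seeds:
        members = [m for m in chains[s] if m in obs.index]
        wi = inv_w[members]
        chain_num[s] = float(wi[x_all[members] == str(category)].sum())
        chain_den[s] = float(wi.sum())
    reps = np.empty(n_boot)
    for b in range(n_boot):
        drawn = rng.choice(seeds, size=len(seeds), replace=True)
        num = sum(chain_num[s] for s in drawn)
        den = sum(chain_den[s] for s in drawn)
        reps[b] = num / den if den > 0 else 0.0
    n = len(obs)
    p_hat = point
    var_srs = p_hat * (1.0 - p_hat) / n
    var_boot = float(np.var(reps, ddof=1))
    return {
        "point": p_hat,
        "bootstrap_var": var_boot,
        "srs_var": var_srs,
        "deff": var_boot / var_srs if var_srs > 0 else float("inf"),
        "n_boot": n_boot,
        "n": n,
    }
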