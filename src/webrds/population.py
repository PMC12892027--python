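"""Synthetic city population with a hidden, networked subpopulation of
electronic nicotine delivery system (ENDS) users.

The generator embeds a small eligible subpopulation (past-12-month ENDS use,
age >= 15, city resident) inside a larger ineligible population, wires the
eligible members into an undirected contact network with a configurable
right-skewed degree distribution, and optionally biases ties toward
same-trait pairs (homophily). Only eligible-eligible ties are modelled:
they are the only ties a chain-referral recruitment can traverse.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import optimize, stats

from ._util import STREAM_IDENTITY, STREAM_POPULATION, STREAM_TRAITS, derived_rng

TRAITS = ("age_group", "sex", "zone")

DEFAULT_TRAIT_MARGINALS: dict[str, dict[str, float]] = {
    "age_group": {"15-24": 0.38, "25-34": 0.42, "35+": 0.20},
    "sex": {"female": 0.44, "male": 0.56},
    "zone": {"south": 0.30, "north": 0.40, "west": 0.20, "center": 0.10},
}

_AGE_RANGE = {"15-24": (15, 24), "25-34": (25, 34), "35+": (35, 60)}

DEVICES = ("e-cigarette", "heated-tobacco", "vaporizer")
# Marginal use probabilities among eligibles; at least one device is forced.
_DEVICE_P = {"e-cigarette": 0.95, "heated-tobacco": 0.34, "vaporizer": 0.33}

_FIRST_NAMES = [
    "ana", "joao", "maria", "pedro", "lucas", "julia", "carla", "rafael",
    "beatriz", "gabriel", "larissa", "felipe", "camila", "bruno", "aline",
    "diego", "renata", "thiago", "patricia", "marcos", "vanessa", "andre",
    "leticia", "gustavo", "amanda", "rodrigo", "fernanda", "caio", "bianca",
    "vitor", "sabrina", "eduardo", "tatiane", "henrique", "priscila",
    "leandro", "daniela", "igor", "monica", "otavio",
]
_LAST_NAMES = [
    "silva", "santos", "oliveira", "souza", "lima", "pereira", "costa",
    "almeida", "ferreira", "rodrigues", "gomes", "martins", "araujo",
    "barbosa", "ribeiro", "carvalho", "rocha", "dias", "nunes", "moreira",
    "teixeira", "correia", "cardoso", "ramos", "vieira", "castro", "campos",
    "freitas", "pinto", "monteiro", "moura", "cavalcanti", "batista",
    "farias", "mendes", "azevedo", "cunha", "duarte", "fonseca", "tavares",
]

# All synthetic dates of birth are laid out relative to this reference date.
REFERENCE_DATE = dt.date(2022, 8, 1)


class PopulationConfig(BaseModel):
    """Parameters of the synthetic population.

    mean_degree is the target mean of the *realized* eligible-contact degree;
    the underlying draw is a negative binomial truncated to [1, degree_max],
    recalibrated so the truncated mean hits the target.
    """

    model_config = ConfigDict(extra="forbid")

    n_total: int = Field(gt=1)
    prevalence_eligible: float
    mean_degree: float = Field(gt=0)
    degree_dispersion: float = Field(default=1.5, gt=0)
    degree_max: int = Field(default=99, ge=1)
    homophily: dict[str, float] = Field(default_factory=dict)
    trait_marginals: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAIT_MARGINALS.items()}
    )
    rng_seed: int = 0

    @field_validator("prevalence_eligible")
    @classmethod
    def _prevalence_open_interval(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("prevalence_eligible must lie in (0, 1)")
        return v

    @field_validator("homophily")
    @classmethod
    def _homophily_unit(cls, v: dict[str, float]) -> dict[str, float]:
        for trait, h in v.items():
            if trait not in TRAITS:
                raise ValueError(f"unknown trait {trait!r}")
            if not 0.0 <= h <= 1.0:
                raise ValueError("homophily coefficients must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_marginals(self) -> "PopulationConfig":
        for trait, marg in self.trait_marginals.items():
            if trait not in TRAITS:
                raise ValueError(f"unknown trait {trait!r}")
            total = sum(marg.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"marginals for {trait!r} sum to {total}, not 1")
        if not 1.0 < self.mean_degree < self.degree_max:
            raise ValueError("mean_degree must lie strictly between 1 and degree_max")
        return self


@dataclass
class Population:
    """Nodes table plus the contact graph over eligible members.

    nodes is indexed by person_id with columns: eligible, age_group, sex,
    zone, ever_cigarette, one boolean column per device, true_degree, email,
    dob. graph is an undirected simple graph whose vertices are the eligible
    person_ids.
    """

    nodes: pd.DataFrame
    graph: nx.Graph
    config: PopulationConfig | None = field(default=None, repr=False)

    @property
    def eligible_ids(self) -> list[str]:
        return list(self.nodes.index[self.nodes["eligible"]])

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges())

    def to_csv(self, nodes_path, edges_path) -> None:
        out = self.nodes.copy()
        out.index.name = "person_id"
        out.to_csv(nodes_path)
        pd.DataFrame(self.edges(), columns=["person_id_a", "person_id_b"]).to_csv(
            edges_path, index=False
        )

    @classmethod
    def from_csv(cls, nodes_path, edges_path) -> "Population":
        nodes = pd.read_csv(nodes_path, index_col="person_id", parse_dates=["dob"])
        nodes["dob"] = nodes["dob"].dt.date
        edges = pd.read_csv(edges_path)
        g = nx.Graph()
        g.add_nodes_from(nodes.index[nodes["eligible"]])
        g.add_edges_from(edges.itertuples(index=False, name=None))
        return cls(nodes=nodes, graph=g)


def _truncated_nbinom(mu: float, k: float, dmax: int):
    p = k / (k + mu)
    d = np.arange(1, dmax + 1)
    pmf = stats.nbinom.pmf(d, k, p)
    s = pmf.sum()
    if s <= 0:
        raise ValueError("degenerate truncated degree distribution")
    return d, pmf / s


def _calibrate_mu(target_mean: float, k: float, dmax: int) -> float:
    """Untruncated negative-binomial mean whose [1, dmax] truncation has the
    requested mean."""

    def gap(mu: float) -> float:
        d, pmf = _truncated_nbinom(mu, k, dmax)
        return float((d * pmf).sum()) - target_mean

    lo, hi = 1e-6, float(dmax)
    while gap(hi) < 0 and hi < 1e7:
        hi *= 4
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"mean_degree {target_mean} infeasible for degree_max {dmax}")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-9))


def sample_degree_sequence(
    n: int, mean_degree: float, dispersion: float, degree_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n degrees from a negative binomial truncated to [1, degree_max]."""
    dmax = min(degree_max, max(n - 1, 1))
    target = min(mean_degree, 0.9 * dmax) if dmax > 1 else 1.0
    mu = _calibrate_mu(target, dispersion, dmax) if dmax > 1 else 1.0
    d, pmf = _truncated_nbinom(mu, dispersion, dmax)
    return rng.choice(d, size=n, p=pmf)


def _pair_stubs(degrees: np.ndarray, rng: np.random.Generator) -> list[tuple[int, int]]:
    stubs = np.repeat(np.arange(len(degrees)), degrees)
    rng.shuffle(stubs)
    return list(zip(stubs[0::2], stubs[1::2]))


def _repair_to_simple(
    pairs: list[tuple[int, int]], rng: np.random.Generator, max_tries: int = 200
) -> set[tuple[int, int]]:
    """Turn a stub pairing into a simple edge set, preserving the degree
    sequence via edge swaps; irreparable self-loops/multi-edges are dropped
    (rare, and the realized degree is what downstream modules use)."""
    edge_set: set[tuple[int, int]] = set()
    bad: list[tuple[int, int]] = []
    for u, v in pairs:
        e = (min(u, v), max(u, v))
        if u == v or e in edge_set:
            bad.append((u, v))
        else:
            edge_set.add(e)
    for u, v in bad:
        placed = False
        edges_list = list(edge_set)
        for _ in range(max_tries):
            x, y = edges_list[rng.integers(len(edges_list))]
            if rng.random() < 0.5:
                x, y = y, x
            # swap (u,v),(x,y) -> (u,x),(v,y)
            if len({u, v, x, y}) < 4:
                continue
            e1 = (min(u, x), max(u, x))
            e2 = (min(v, y), max(v, y))
            if e1 in edge_set or e2 in edge_set:
                continue
            edge_set.discard((min(x, y), max(x, y)))
            edge_set.add(e1)
            edge_set.add(e2)
            placed = True
            break
        if not placed:
            continue
    return edge_set


def _homophily_rewire(
    g: nx.Graph, labels: dict, h: float, rng: np.random.Generator
) -> None:
    """Bias edges toward same-label pairs by degree-preserving swaps.

    The number of accepted label-improving swaps scales with h * |E|, so
    h=0 leaves the configuration-model graph (assortativity ~ 0) untouched
    and h=1 pushes hard toward within-group ties.
    """
    if h <= 0 or g.number_of_edges() < 2:
        return
    target_swaps = int(np.ceil(h * g.number_of_edges() * 2))
    edges = list(g.edges())
    accepted = 0
    attempts = 0
    max_attempts = 40 * target_swaps + 100
    while accepted < target_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(len(edges), size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if len({a, b, c, d}) < 4:
            continue
        # choose the orientation that maximizes same-label endpoints
        same = lambda u, v: labels[u] == labels[v]
        cur = same(a, b) + same(c, d)
        opts = [((a, c), (b, d)), ((a, d), (b, c))]
        best = max(opts, key=lambda o: same(*o[0]) + same(*o[1]))
        gain = same(*best[0]) + same(*best[1]) - cur
        if gain <= 0:
            continue
        (e1, e2) = best
        if g.has_edge(*e1) or g.has_edge(*e2):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(*e1)
        g.add_edge(*e2)
        edges[i], edges[j] = e1, e2
        accepted += 1


def _sample_categorical(
    marg: dict[str, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    cats = list(marg.keys())
    p = np.array([marg[c] for c in cats], dtype=float)
    return rng.choice(cats, size=n, p=p / p.sum())


def _make_emails(n: int, rng: np.random.Generator) -> list[str]:
    """Unique synthetic addresses 'first.last@example.test'.

    Identities stay distinct even after fraud-style normalization (no two
    honest addresses differ only by separators or trailing digits): name
    collisions fall back to double surnames rather than digit suffixes, so
    near-duplicate addresses in a roster are exactly the injected ones.
    """
    emails: list[str] = []
    seen: set[str] = set()
    while len(emails) < n:
        first = _FIRST_NAMES[rng.integers(len(_FIRST_NAMES))]
        last = _LAST_NAMES[rng.integers(len(_LAST_NAMES))]
        local = f"{first}.{last}"
        if local in seen:
            local = f"{first}.{last}-{_LAST_NAMES[rng.integers(len(_LAST_NAMES))]}"
        if local in seen:
            continue
        seen.add(local)
        emails.append(f"{local}@example.test")
    return emails


def _make_dobs(
    age_groups: np.ndarray, eligible: np.ndarray, rng: np.random.Generator
) -> list[dt.date]:
    """Dates of birth consistent with the age-group trait.

    Eligible members get pairwise-distinct dates (identities are unique
    before fraud injection, so a repeated registration DOB in a roster is
    always an injected signal); the ineligible background population may
    share birthdays.
    """
    used: set[int] = set()
    dobs = []
    for grp, elig in zip(age_groups, eligible):
        lo, hi = _AGE_RANGE[str(grp)]
        lo_d, hi_d = lo * 365 + 180, (hi + 1) * 365
        age_days = int(rng.integers(lo_d, hi_d))
        if elig:
            tries = 0
            while age_days in used:
                age_days = int(rng.integers(lo_d, hi_d))
                tries += 1
                if tries > 20 * (hi_d - lo_d):
                    raise ValueError(
                        "too many eligible members for distinct dates of birth "
                        f"in age band {grp}"
                    )
            used.add(age_days)
        dobs.append(REFERENCE_DATE - dt.timedelta(days=age_days))
    return dobs


def generate_population(config: PopulationConfig) -> Population:
    """Generate the synthetic population and its eligible contact graph.

    Deterministic given config.rng_seed: repeated calls return identical
    node tables and edge lists.
    """
    rng_net = derived_rng(config.rng_seed, STREAM_POPULATION)
    rng_traits = derived_rng(config.rng_seed, STREAM_TRAITS)
    rng_id = derived_rng(config.rng_seed, STREAM_IDENTITY)

    n = config.n_total
    eligible = rng_traits.random(n) < config.prevalence_eligible
    n_elig = int(eligible.sum())
    if n_elig < 2:
        raise ValueError(
            f"only {n_elig} eligible member(s) drawn; no contact network possible "
            "(increase n_total or prevalence_eligible)"
        )

    person_ids = np.array([f"P{i:06d}" for i in range(n)])
    traits = {
        t: _sample_categorical(config.trait_marginals[t], n, rng_traits) for t in TRAITS
    }

    device = {d: np.zeros(n, dtype=bool) for d in DEVICES}
    elig_idx = np.flatnonzero(eligible)
    for d in DEVICES:
        device[d][elig_idx] = rng_traits.random(n_elig) < _DEVICE_P[d]
    none_mask = elig_idx[~np.any([device[d][elig_idx] for d in DEVICES], axis=0)]
    device["e-cigarette"][none_mask] = True

    degrees = sample_degree_sequence(
        n_elig, config.mean_degree, config.degree_dispersion, config.degree_max, rng_net
    )
    if degrees.sum() % 2 == 1:
        j = int(rng_net.integers(n_elig))
        degrees[j] += 1 if degrees[j] < min(config.degree_max, n_elig - 1) else -1

    pairs = _pair_stubs(degrees, rng_net)
    edge_set = _repair_to_simple(pairs, rng_net)
    g = nx.Graph()
    g.add_nodes_from(range(n_elig))
    g.add_edges_from(edge_set)

    for trait, h in sorted(config.homophily.items()):
        labels = {i: traits[trait][elig_idx[i]] for i in range(n_elig)}
        _homophily_rewire(g, labels, h, rng_net)

    g = nx.relabel_nodes(g, {i: person_ids[elig_idx[i]] for i in range(n_elig)})

    true_degree = np.zeros(n, dtype=int)
    deg_view = dict(g.degree())
    for i, pid in zip(elig_idx, person_ids[elig_idx]):
        true_degree[i] = deg_view[pid]

    nodes = pd.DataFrame(
        {
            "eligible": eligible,
            "age_group": traits["age_group"],
            "sex": traits["sex"],
            "zone": traits["zone"],
            "ever_cigarette": rng_traits.random(n) < 0.6,
            "device_e-cigarette": device["e-cigarette"],
            "device_heated-tobacco": device["heated-tobacco"],
            "device_vaporizer": device["vaporizer"],
            "true_degree": true_degree,
            "email": _make_emails(n, rng_id),
            "dob": _make_dobs(traits["age_group"], eligible, rng_id),
        },
        index=pd.Index(person_ids, name="person_id"),
    )
    return Population(nodes=nodes, graph=g, config=config)


def degree_correlated_trait(
    population: Population,
    prevalence: float,
    strength: float,
    rng: np.random.Generator,
) -> pd.Series:
    """Binary trait over eligible members whose probability rises with
    degree while the expected population share stays at `prevalence`.

    Used in estimator-validation loops: chain-referral sampling
    oversamples high-degree members, so a degree-correlated trait makes
    the unweighted sample mean biased and lets reciprocal-degree weighting
    show its worth. strength is the slope (probability points per unit
    degree); probabilities are clipped to [0, 1], which slightly attenuates
    the realized share at extreme settings — use the realized share as the
    ground truth.
    """
    elig = population.nodes[population.nodes["eligible"]]
    d = elig["true_degree"].to_numpy(dtype=float)
    p = prevalence + strength * (d - d.mean())
    p = np.clip(p, 0.0, 1.0)
    values = rng.random(len(elig)) < p
    return pd.Series(values, index=elig.index, name="trait")


def apply_degree_heaping(
    true_degree: int,
    rng: np.random.Generator,
    heap_prob: float = 0.5,
    cap: int = 99,
) -> int:
    """Self-report a network size the way respondents do.

    Sizes of at most 5 are reported exactly; larger sizes are rounded to the
    nearest multiple of 5 with probability heap_prob. Reports are capped at
    `cap` (respondents do not report beyond it) and never negative.
    """
    if true_degree < 0:
        raise ValueError("true_degree must be nonnegative")
    d = int(true_degree)
    if d > 5 and rng.random() < heap_prob:
        d = int(5 * round(d / 5))
    return max(0, min(d, cap))
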