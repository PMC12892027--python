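"""Web-based respondent-driven sampling (web-RDS) recruitment simulator.

Runs a discrete-day chain-referral process on a synthetic population:
researcher-selected seeds enroll first, every participant who completes the
questionnaire receives a fixed number of single-use invitation codes, and
codes are spent on network neighbors whose decision to participate depends
on the incentive level in force that day. The simulator also injects the
pathologies an incentive-driven online survey attracts — codes spent on
ineligible contacts, repeat participation under mutated email addresses,
and self-recruitment under a fake address — and emits the raw attempt
roster, coupon ledger and recruitment forest exactly as the intake system
would observe them, plus a hidden ground-truth table for validation.
"""

from __future__ import annotations

import datetime as dt
import re
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from ._util import STREAM_FRAUD, STREAM_RECRUITMENT, STREAM_RESPONSES, derived_rng
from .population import DEVICES, Population, apply_degree_heaping

SEED_ISSUER = "STUDY"

ROSTER_COLUMNS = [
    "attempt_id",
    "coupon_code",
    "email",
    "dob",
    "day",
    "screen_used_12mo",
    "screen_age_ok",
    "screen_resident",
    "completed",
    "device_e-cigarette",
    "device_heated-tobacco",
    "device_vaporizer",
    "q1_network",
    "q2_network",
    "age_group",
    "sex",
    "zone",
    "ever_cigarette",
]

LEDGER_COLUMNS = ["coupon_code", "issuer_id", "status", "used_by", "issued_at", "used_at"]


class StalledRecruitmentError(RuntimeError):
    """No seed produced a valid enrollment within the simulation horizon."""


class SimulationConfig(BaseModel):
    """Recruitment process parameters.

    participation_prob maps incentive level to the per-approach probability
    that an invited contact decides to participate; incentive_schedule maps
    a start day to the level in force from that day on.
    """

    model_config = ConfigDict(extra="forbid")

    n_seeds: int = Field(default=12, ge=1)
    coupons_per_participant: int = Field(default=3, ge=1)
    participation_prob: dict[str, float] = Field(
        default_factory=lambda: {"low": 0.0, "high": 0.65}
    )
    incentive_schedule: dict[int, str] = Field(default_factory=lambda: {0: "low", 60: "high"})
    spend_prob: float = Field(default=0.25, gt=0, le=1)
    p_ineligible_use: float = 0.24
    p_duplicate_attempt: float = 0.10
    p_self_recruit: float = 0.02
    p_incomplete: float = 0.043
    p_inconsistent: float = 0.018
    heap_prob: float = 0.5
    target_n: int = Field(default=330, ge=1)
    horizon_days: int = Field(default=300, ge=1)
    rng_seed: int = 0

    @field_validator(
        "p_ineligible_use",
        "p_duplicate_attempt",
        "p_self_recruit",
        "p_incomplete",
        "p_inconsistent",
        "heap_prob",
    )
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @field_validator("participation_prob")
    @classmethod
    def _probs_unit(cls, v: dict[str, float]) -> dict[str, float]:
        for lvl, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"participation_prob[{lvl!r}] outside [0, 1]")
        return v

    def incentive_level(self, day: int) -> str:
        starts = sorted(self.incentive_schedule)
        level = self.incentive_schedule[starts[0]]
        for s in starts:
            if day >= s:
                level = self.incentive_schedule[s]
        return level


@dataclass
class RecruitmentForest:
    """Seed-rooted recruitment trees.

    participants is indexed by person_id with columns wave (seeds are wave
    0), seed_id (root of the chain), recruiter_id (<NA> for seeds),
    coupon_code, and enrollment day.
    """

    participants: pd.DataFrame

    @property
    def edges(self) -> pd.DataFrame:
        rec = self.participants[self.participants["recruiter_id"].notna()]
        out = rec.reset_index().rename(columns={"person_id": "recruit_id"})
        return out[["recruiter_id", "recruit_id", "coupon_code", "day", "wave"]]

    def seed_ids(self) -> list[str]:
        return list(self.participants.index[self.participants["wave"] == 0])

    def wave_of(self, person_id: str) -> int:
        return int(self.participants.loc[person_id, "wave"])

    def is_seed(self, person_id: str) -> bool:
        return self.wave_of(person_id) == 0

    def recruits_of(self, person_id: str) -> list[str]:
        p = self.participants
        return list(p.index[p["recruiter_id"] == person_id])

    def validate(self, coupons_per_participant: int = 3) -> None:
        p = self.participants
        nonseed = p[p["wave"] > 0]
        if nonseed["recruiter_id"].isna().any():
            raise ValueError("non-seed participant without a recruiter")
        for pid, row in nonseed.iterrows():
            rid = row["recruiter_id"]
            if rid not in p.index:
                raise ValueError(f"recruiter {rid} of {pid} not enrolled")
            if p.loc[rid, "wave"] + 1 != row["wave"]:
                raise ValueError(f"wave of {pid} is not recruiter wave + 1")
            if p.loc[rid, "seed_id"] != row["seed_id"]:
                raise ValueError(f"{pid} not rooted at its recruiter's seed")
        counts = nonseed["recruiter_id"].value_counts()
        if (counts > coupons_per_participant).any():
            raise ValueError("recruiter exceeded coupon quota")

    def to_csv(self, path) -> None:
        out = self.participants.reset_index()
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RecruitmentForest":
        df = pd.read_csv(path, dtype={"person_id": str})
        df["recruiter_id"] = df["recruiter_id"].astype("string")
        df["seed_id"] = df["seed_id"].astype("string")
        return cls(df.set_index("person_id"))


@dataclass
class SimulationResult:
    roster: pd.DataFrame
    ledger: pd.DataFrame
    forest: RecruitmentForest
    truth: pd.DataFrame = field(repr=False)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.roster.to_csv(out / "attempt_roster.csv", index=False)
        self.ledger.to_csv(out / "coupon_ledger.csv", index=False)
        self.forest.to_csv(out / "forest_edges.csv")
        self.truth.to_csv(out / "truth_table.csv", index=False)


def select_seeds(
    population: Population,
    n_seeds: int,
    diversity_traits: tuple[str, ...] = ("zone", "age_group"),
    rng: np.random.Generator | None = None,
    strict: bool = False,
) -> list[str]:
    """Pick seeds stratified across diversity traits, highest degree first.

    Seeds are allocated round-robin over the categories of the first trait
    (as evenly as the eligible counts permit); within a category, candidates
    are ordered to alternate the remaining traits and prefer well-connected
    members, mirroring the formative-phase goal of diverse, well-connected
    starters. Deterministic for a given rng seed.
    """
    elig = population.nodes[population.nodes["eligible"]]
    if n_seeds > len(elig):
        raise ValueError(f"requested {n_seeds} seeds but only {len(elig)} eligible")
    if not diversity_traits or n_seeds == 1:
        ranked = elig.sort_values(["true_degree"], ascending=False, kind="mergesort")
        return list(ranked.index[:n_seeds])

    primary = diversity_traits[0]
    cats = sorted(elig[primary].unique())
    if strict:
        for c in sorted(population.nodes[primary].unique()):
            if c not in cats:
                raise ValueError(f"no eligible candidate in {primary}={c!r}")
    pools: dict[str, list[str]] = {}
    for c in cats:
        sub = elig[elig[primary] == c].sort_values(
            "true_degree", ascending=False, kind="mergesort"
        )
        # interleave secondary-trait categories to spread the remaining traits
        if len(diversity_traits) > 1:
            sec = diversity_traits[1]
            groups = [list(g.index) for _, g in sub.groupby(sec, sort=True)]
            inter: list[str] = []
            i = 0
            while any(groups):
                g = groups[i % len(groups)]
                if g:
                    inter.append(g.pop(0))
                i += 1
                if i > 10 * len(sub) + 10:
                    break
            pools[c] = inter + [x for g in groups for x in g]
        else:
            pools[c] = list(sub.index)

    order = sorted(cats, key=lambda c: -len(pools[c]))
    chosen: list[str] = []
    i = 0
    while len(chosen) < n_seeds:
        c = order[i % len(order)]
        if pools[c]:
            chosen.append(pools[c].pop(0))
        i += 1
        if i > 10 * n_seeds * max(1, len(order)) and not any(pools.values()):
            break
    if len(chosen) < n_seeds:
        raise ValueError("eligible pool exhausted during stratified selection")
    return chosen


def _new_code(rng: np.random.Generator, existing: set[str]) -> str:
    alphabet = string.ascii_uppercase + string.digits
    while True:
        code = "".join(alphabet[i] for i in rng.integers(len(alphabet), size=8))
        if code not in existing:
            existing.add(code)
            return code


def mutate_email(email: str, rng: np.random.Generator) -> str:
    """Disguise an address the way repeat participants do: invert name
    tokens, append/increment digits, or toggle the separator."""
    local, _, domain = email.partition("@")
    ops = ["invert", "digits", "separator"]
    op = ops[int(rng.integers(len(ops)))]
    tokens = re.split(r"[._]", local)
    if op == "invert" and len(tokens) >= 2:
        sep = "." if "." in local else ("_" if "_" in local else ".")
        local = sep.join(reversed(tokens))
    elif op == "digits":
        m = re.search(r"(\d+)$", local)
        if m:
            local = local[: m.start()] + str(int(m.group(1)) + 1)
        else:
            local = local + str(int(rng.integers(1, 100)))
    else:
        if "." in local:
            local = local.replace(".", "_")
        elif "_" in local:
            local = local.replace("_", "")
        else:
            local = local + str(int(rng.integers(1, 10)))
    return f"{local}@{domain}"


class _Run:
    """Mutable state of one simulation; collects roster/ledger/forest rows."""

    def __init__(self, population: Population, config: SimulationConfig):
        self.pop = population
        self.cfg = config
        self.rng = derived_rng(config.rng_seed, STREAM_RECRUITMENT)
        self.rng_fraud = derived_rng(config.rng_seed, STREAM_FRAUD)
        self.rng_resp = derived_rng(config.rng_seed, STREAM_RESPONSES)
        self.codes: set[str] = set()
        self.coupons: dict[str, dict] = {}
        self.rows: list[dict] = []
        self.truth: list[dict] = []
        self.enrolled: dict[str, dict] = {}  # person_id -> {wave, seed_id, ...}
        self.targeted: set[str] = set()
        self.events: dict[int, list[tuple]] = {}
        self.n_valid = 0
        self.active = True
        self.next_attempt_id = 1
        self.ineligible_pool = list(
            population.nodes.index[~population.nodes["eligible"]]
        )
        # registration DOBs already spoken for: eligible identities are
        # generated distinct; injected identities must not collide with
        # them (a collision would get a genuine later attempt blocked)
        self.reserved_dobs: set = set(
            population.nodes.loc[population.nodes["eligible"], "dob"]
        )
        self.seen_dobs: set = set()

    # -- bookkeeping -------------------------------------------------------
    def schedule(self, day: int, event: tuple) -> None:
        self.events.setdefault(day, []).append(event)

    def issue_coupon(self, issuer: str, day: int) -> str:
        code = _new_code(self.rng, self.codes)
        self.coupons[code] = {
            "coupon_code": code,
            "issuer_id": issuer,
            "status": "unused",
            "used_by": pd.NA,
            "issued_at": day,
            "used_at": pd.NA,
        }
        return code

    def consume(self, code: str, person: str | None, day: int, status: str = "used") -> None:
        c = self.coupons[code]
        if c["status"] == "unused":
            c["status"] = status
            c["used_by"] = person if person is not None else pd.NA
            c["used_at"] = day

    def _geom(self, rng: np.random.Generator) -> int:
        return int(rng.geometric(self.cfg.spend_prob))

    # -- attempt row construction -----------------------------------------
    def add_attempt(
        self,
        coupon_code: str,
        email: str,
        dob: dt.date,
        day: int,
        screen: tuple[bool, bool, bool],
        completed: bool,
        person_row: pd.Series | None,
        truth_person: str,
        truth_kind: str,
        devices: dict[str, bool] | None = None,
        q1: int | float = np.nan,
        q2: int | float = np.nan,
    ) -> int:
        aid = self.next_attempt_id
        self.next_attempt_id += 1
        row = {
            "attempt_id": aid,
            "coupon_code": coupon_code,
            "email": email,
            "dob": dob.isoformat(),
            "day": day,
            "screen_used_12mo": screen[0],
            "screen_age_ok": screen[1],
            "screen_resident": screen[2],
            "completed": completed,
        }
        for d in DEVICES:
            col = f"device_{d}"
            if devices is None:
                row[col] = pd.NA
            else:
                row[col] = bool(devices[d])
        row["q1_network"] = q1
        row["q2_network"] = q2
        for t in ("age_group", "sex", "zone"):
            row[t] = person_row[t] if person_row is not None and completed else pd.NA
        row["ever_cigarette"] = (
            bool(person_row["ever_cigarette"])
            if person_row is not None and completed
            else pd.NA
        )
        self.seen_dobs.add(dob)
        self.rows.append(row)
        self.truth.append(
            {"attempt_id": aid, "truth_person_id": truth_person, "truth_kind": truth_kind}
        )
        return aid

    def _degrees(self, pid: str) -> tuple[int, int]:
        true_deg = int(self.pop.nodes.loc[pid, "true_degree"])
        extra = int(self.rng_resp.poisson(0.8))
        q2 = apply_degree_heaping(true_deg, self.rng_resp, self.cfg.heap_prob)
        q1 = apply_degree_heaping(true_deg + extra, self.rng_resp, self.cfg.heap_prob)
        return max(q1, q2), q2

    # -- enrollment --------------------------------------------------------
    def enroll(
        self, pid: str, coupon_code: str, recruiter: str | None, day: int
    ) -> None:
        node = self.pop.nodes.loc[pid]
        incomplete = self.rng.random() < self.cfg.p_incomplete
        if incomplete:
            self.add_attempt(
                coupon_code, node["email"], node["dob"], day,
                (True, True, True), False, node, pid, "incomplete",
            )
            return
        inconsistent = self.rng_fraud.random() < self.cfg.p_inconsistent
        devices = {d: (False if inconsistent else bool(node[f"device_{d}"])) for d in DEVICES}
        q1, q2 = self._degrees(pid)
        self.add_attempt(
            coupon_code, node["email"], node["dob"], day,
            (True, True, True), True, node, pid,
            "inconsistent" if inconsistent else "valid",
            devices=devices, q1=q1, q2=q2,
        )
        wave = 0 if recruiter is None else self.enrolled[recruiter]["wave"] + 1
        seed_id = pid if recruiter is None else self.enrolled[recruiter]["seed_id"]
        self.enrolled[pid] = {
            "wave": wave,
            "seed_id": seed_id,
            "recruiter_id": recruiter,
            "coupon_code": coupon_code,
            "day": day,
            "email": node["email"],
            "dob": node["dob"],
        }
        self.n_valid += 1
        self._issue_and_schedule(pid, day)
        if self.rng_fraud.random() < self.cfg.p_duplicate_attempt:
            self.schedule(day + 2 + self._geom(self.rng_fraud), ("duplicate", pid))

    def _issue_and_schedule(self, pid: str, day: int) -> None:
        cfg = self.cfg
        own_codes = [
            self.issue_coupon(pid, day) for _ in range(cfg.coupons_per_participant)
        ]
        self_recruit_done = False
        for code in own_codes:
            if not self_recruit_done and self.rng_fraud.random() < cfg.p_self_recruit:
                self.schedule(day + 1 + self._geom(self.rng_fraud), ("self_recruit", pid, code))
                self_recruit_done = True
                continue
            if self.rng.random() < cfg.p_ineligible_use:
                self.schedule(day + 1 + self._geom(self.rng), ("spend_inelig", pid, code))
            else:
                target = self._pick_neighbor(pid)
                if target is None:
                    continue
                self.targeted.add(target)
                self.schedule(day + 1 + self._geom(self.rng), ("spend", pid, code, target))

    def _pick_neighbor(self, pid: str) -> str | None:
        if pid not in self.pop.graph:
            return None
        free = [
            n
            for n in self.pop.graph.neighbors(pid)
            if n not in self.enrolled and n not in self.targeted
        ]
        if not free:
            return None
        return free[int(self.rng.integers(len(free)))]

    # -- event handlers ----------------------------------------------------
    def handle(self, day: int, event: tuple) -> None:
        kind = event[0]
        if kind == "spend":
            _, issuer, code, target = event
            if target in self.enrolled or self.coupons[code]["status"] != "unused":
                return
            level = self.cfg.incentive_level(day)
            if self.rng.random() >= self.cfg.participation_prob.get(level, 0.0):
                retry = day + 1 + self._geom(self.rng)
                if retry <= self.cfg.horizon_days:
                    self.schedule(retry, event)
                return
            self.consume(code, target, day)
            self.enroll(target, code, issuer, day)
        elif kind == "spend_inelig":
            _, issuer, code = event
            if self.coupons[code]["status"] != "unused":
                return
            level = self.cfg.incentive_level(day)
            if self.rng.random() >= self.cfg.participation_prob.get(level, 0.0):
                retry = day + 1 + self._geom(self.rng)
                if retry <= self.cfg.horizon_days:
                    self.schedule(retry, event)
                return
            pid = self._pop_ineligible()
            if pid is None:
                return
            node = self.pop.nodes.loc[pid]
            screen = self._failed_screen()
            self.consume(code, pid, day, status="invalidated")
            self.add_attempt(
                code, node["email"], node["dob"], day, screen, False, node, pid, "ineligible"
            )
        elif kind == "duplicate":
            _, pid = event
            if not self.active:
                return
            if not self._fraud_motivated(day, event):
                return
            info = self.enrolled[pid]
            email = mutate_email(info["email"], self.rng_fraud)
            if self.rng_fraud.random() < 0.5:
                dob = info["dob"]  # exact repeat: caught by the automatic block
            else:
                delta = int(self.rng_fraud.choice([-1, 1]))
                dob = info["dob"] + dt.timedelta(days=delta)
                if dob in self.reserved_dobs or dob in self.seen_dobs:
                    dob = info["dob"] - dt.timedelta(days=delta)
            code = self._fraud_coupon(pid)
            if code is None:
                return
            self.consume(code, pid, day)
            node = self.pop.nodes.loc[pid]
            q1, q2 = self._degrees(pid)
            devices = {d: bool(node[f"device_{d}"]) for d in DEVICES}
            self.add_attempt(
                code, email, dob, day, (True, True, True), True, node, pid,
                "duplicate", devices=devices, q1=q1, q2=q2,
            )
        elif kind == "self_recruit":
            _, pid, code = event
            if not self._fraud_motivated(day, event):
                return
            info = self.enrolled[pid]
            fake_local = f"x{pid.lower()}{int(self.rng_fraud.integers(10, 99))}"
            email = f"{fake_local}@example.test"
            self.consume(code, pid, day)
            node = self.pop.nodes.loc[pid]
            q1, q2 = self._degrees(pid)
            devices = {d: bool(node[f"device_{d}"]) for d in DEVICES}
            self.add_attempt(
                code, email, info["dob"], day, (True, True, True), True, node, pid,
                "self_recruit", devices=devices, q1=q1, q2=q2,
            )

    def _fraud_motivated(self, day: int, event: tuple) -> bool:
        """Repeat participation chases the incentive like first
        participation does; under a stalled (zero-probability) incentive the
        fraudster waits too."""
        level = self.cfg.incentive_level(day)
        if self.rng_fraud.random() < self.cfg.participation_prob.get(level, 0.0):
            return True
        retry = day + 1 + self._geom(self.rng_fraud)
        if retry <= self.cfg.horizon_days:
            self.schedule(retry, event)
        return False

    def _failed_screen(self) -> tuple[bool, bool, bool]:
        which = int(self.rng.integers(3))
        screen = [True, True, True]
        # most ineligible contacts fail the use criterion; others age/residence
        screen[0 if self.rng.random() < 0.7 else which] = False
        return tuple(screen)

    def _pop_ineligible(self) -> str | None:
        """Draw an unused ineligible contact whose date of birth does not
        clash with any registered or reserved identity."""
        for _ in range(50):
            if not self.ineligible_pool:
                return None
            i = int(self.rng.integers(len(self.ineligible_pool)))
            pid = self.ineligible_pool.pop(i)
            dob = self.pop.nodes.loc[pid, "dob"]
            if dob not in self.reserved_dobs and dob not in self.seen_dobs:
                return pid
        return None

    def _fraud_coupon(self, pid: str) -> str | None:
        unused = [c for c, v in self.coupons.items() if v["status"] == "unused"]
        if unused and self.rng_fraud.random() < 0.5:
            return unused[int(self.rng_fraud.integers(len(unused)))]
        return self.enrolled[pid]["coupon_code"]  # reuse of an already-spent code


def run_recruitment(
    population: Population, config: SimulationConfig
) -> SimulationResult:
    """Run the full web-RDS process and return the raw observable bundle.

    The attempt roster contains every access attempt — valid, duplicate,
    self-recruitment, ineligible and incomplete — in arrival order; the
    hidden truth table labels each attempt for validation and is never part
    of the observed bundle. Enrollment closes at the end of the first day on
    which the valid completed count reaches target_n. Deterministic given
    config.rng_seed.
    """
    run = _Run(population, config)
    seeds = select_seeds(
        population, config.n_seeds, rng=derived_rng(config.rng_seed, STREAM_RECRUITMENT)
    )
    for pid in seeds:
        code = run.issue_coupon(SEED_ISSUER, 0)
        run.consume(code, pid, 0)
        run.enroll(pid, code, None, 0)

    for day in range(config.horizon_days + 1):
        if not run.active:
            break
        for event in run.events.pop(day, []):
            run.handle(day, event)
        if run.n_valid >= config.target_n:
            run.active = False

    if not any(v["wave"] == 0 for v in run.enrolled.values()):
        raise StalledRecruitmentError(
            "no seed enrolled within the horizon; recruitment never started"
        )

    roster = pd.DataFrame(run.rows, columns=ROSTER_COLUMNS)
    ledger = pd.DataFrame(list(run.coupons.values()), columns=LEDGER_COLUMNS)
    parts = pd.DataFrame.from_dict(run.enrolled, orient="index")
    parts.index.name = "person_id"
    parts = parts[["wave", "seed_id", "recruiter_id", "coupon_code", "day"]]
    parts["recruiter_id"] = parts["recruiter_id"].astype("string")
    forest = RecruitmentForest(parts)
    truth = pd.DataFrame(run.truth, columns=["attempt_id", "truth_person_id", "truth_kind"])
    return SimulationResult(roster=roster, ledger=ledger, forest=forest, truth=truth)


def recruiter_productivity(
    forest: RecruitmentForest, include: set[str] | None = None
) -> dict[int, int]:
    """Counts of recruiters by number of recruits, among recruiters with at
    least one counted recruit.

    include restricts which recruits are counted (e.g. the analysis roster,
    so that consistency-excluded recruits do not inflate productivity);
    None counts every recruit in the forest.
    """
    edges = forest.edges
    if include is not None:
        edges = edges[edges["recruit_id"].isin(include)]
    counts = edges["recruiter_id"].value_counts()
    out: dict[int, int] = {}
    for c in counts:
        out[int(c)] = out.get(int(c), 0) + 1
    return dict(sorted(out.items()))


def coupon_exhaustion(
    ledger: pd.DataFrame, coupons_per_participant: int = 3
) -> tuple[int, int, float]:
    """(n_exhausted, n_with_any_use, share%) over participants who had at
    least one invitation consumed; a coupon counts as consumed whether it
    enrolled someone, was invalidated on an ineligible contact, or was spent
    on an attempt later removed."""
    own = ledger[ledger["issuer_id"] != SEED_ISSUER]
    consumed = own[own["status"].isin(["used", "invalidated"])]
    per = consumed.groupby("issuer_id").size()
    n_any = int((per >= 1).sum())
    n_all = int((per >= coupons_per_participant).sum())
    from ._util import pct

    return n_all, n_any, pct(n_all, n_any)
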