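"""Deterministic reference dataset emulating a completed web-RDS survey of
ENDS users.

The bundle (attempt roster, coupon ledger, recruitment forest, truth table)
is laid out so that the intake funnel, recruiter productivity, coupon
exhaustion, degree distribution and wave structure land on the headline
counts of a real single-city web-RDS implementation: 508 access attempts
funneling down to 330 valid participants and 324 analyzed; 174 productive
recruiters splitting 75/60/39 by number of recruits; 113 of 218
coupon-using participants spending all 3 invitations; 12 seeds (5 of them
unproductive) with chains reaching wave 21; and 47.5% of analyzed
respondents reporting an operative network size of at most 5 (mode 5,
maximum 99).

Everything is synthetic and fully deterministic: no randomness, no I/O.
Rebuilding the bundle twice yields byte-identical tables.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

from .intake import IntakeConfig
from .population import REFERENCE_DATE
from .simulator import (
    LEDGER_COLUMNS,
    ROSTER_COLUMNS,
    SEED_ISSUER,
    RecruitmentForest,
    SimulationResult,
)

# The deployed system auto-blocked on invitation code and registration
# email; date-of-birth patterns (including self-recruitment) were part of
# the manual review, which is where the fixture routes them.
REFERENCE_INTAKE_CONFIG = IntakeConfig(auto_keys=("coupon_code", "email"))

_FIRST = [
    "ana", "joao", "maria", "pedro", "lucas", "julia", "carla", "rafael",
    "beatriz", "gabriel", "larissa", "felipe", "camila", "bruno", "aline",
    "diego", "renata", "thiago", "patricia", "marcos", "vanessa", "andre",
    "leticia", "gustavo", "amanda", "rodrigo", "fernanda", "caio", "bianca",
    "vitor", "sabrina", "eduardo",
]
_LAST = [
    "silva", "santos", "oliveira", "souza", "lima", "pereira", "costa",
    "almeida", "ferreira", "rodrigues", "gomes", "martins", "araujo",
    "barbosa", "ribeiro", "carvalho", "rocha", "dias", "nunes", "moreira",
    "teixeira", "correia", "cardoso", "ramos", "vieira", "castro",
]

_SEED_ZONES = ["south"] * 6 + ["north"] * 4 + ["west", "center"]
_SEED_SEX = ["male"] * 9 + ["female"] * 3
_SEED_AGE = ["15-24"] * 3 + ["25-34"] * 4 + ["35+"] * 5

_ZONE_CYCLE = ["south", "north", "north", "south", "west", "north", "center", "west"]
_AGE_CYCLE = ["15-24", "25-34", "25-34", "15-24", "35+", "25-34", "15-24", "25-34", "35+", "15-24"]
_SEX_CYCLE = ["male", "female", "male", "female", "male", "male", "female", "male"]


def _email(k: int) -> str:
    f = _FIRST[k % len(_FIRST)]
    l = _LAST[(k // len(_FIRST)) % len(_LAST)]
    rep = k // (len(_FIRST) * len(_LAST))
    suffix = "" if rep == 0 else f"{rep + 1}"  # suffix never used below 832 identities
    return f"{f}.{l}{suffix}@example.test"


def _dob(k: int) -> dt.date:
    # 37-day spacing: no two identities are born within +/-1 day of each
    # other, so the manual DOB-proximity rule fires only where intended.
    return REFERENCE_DATE - dt.timedelta(days=15 * 365 + 180 + 37 * k)


def _q2_values() -> list[int]:
    """324 operative degrees: 154 at <=5 (mode 5), 87 in 6-10, 83 above 10
    with a single maximum of 99."""
    gt10 = (
        [99, 60, 50, 45, 40]
        + [35] * 4 + [30] * 6 + [25] * 8 + [20] * 14 + [15] * 20
        + [18] * 2 + [16] * 2 + [14] * 4 + [13] * 4 + [12] * 6 + [11] * 8
    )
    mid = [10] * 40 + [9] * 10 + [8] * 12 + [7] * 10 + [6] * 15
    le5 = [5] * 70 + [4] * 30 + [3] * 25 + [2] * 15 + [1] * 14
    vals = gt10 + mid + le5
    assert len(vals) == 324
    return vals


class _Person:
    __slots__ = (
        "pid", "wave", "seed_id", "recruiter", "n_children", "children",
        "inconsistent", "email", "dob", "zone", "age_group", "sex",
        "coupon_in", "coupons", "day", "q1", "q2",
    )

    def __init__(self, pid: str, wave: int, seed_id: str, recruiter: str | None):
        self.pid = pid
        self.wave = wave
        self.seed_id = seed_id
        self.recruiter = recruiter
        self.n_children = 0
        self.children: list[str] = []
        self.inconsistent = False


def _build_forest() -> dict[str, _Person]:
    """330 participants: 12 seeds, 318 recruits; recruiter out-degrees
    69x1 / 66x2 / 39x3; one chain to wave 21; 5 seeds unproductive."""
    people: dict[str, _Person] = {}
    n_next = 0

    def new_person(wave: int, seed_id: str | None, recruiter: str | None) -> _Person:
        nonlocal n_next
        n_next += 1
        pid = f"R{n_next:04d}" if recruiter is not None else f"S{n_next:02d}"
        p = _Person(pid, wave, seed_id or pid, recruiter)
        people[pid] = p
        return p

    seeds = [new_person(0, None, None) for _ in range(12)]
    # productive seeds: 3 recruit 3, 3 recruit 2, 1 starts the deep chain
    seed_children = [3, 3, 3, 2, 2, 2, 1, 0, 0, 0, 0, 0]
    for s, c in zip(seeds, seed_children):
        s.n_children = c

    # deep chain under the out-degree-1 seed: 21 waves
    chain_seed = seeds[6]
    parent = chain_seed
    for w in range(1, 22):
        child = new_person(w, chain_seed.seed_id, parent.pid)
        parent.children.append(child.pid)
        child.n_children = 1 if w < 21 else 0
        parent = child

    # remaining recruiter roles to hand out breadth-first under seeds 1-6
    roles = [3] * 36 + [2] * 63 + [1] * 48  # then leaves
    role_i = 0
    queue: list[str] = []
    for s in seeds[:6]:
        queue.extend([s.pid] * s.n_children)
    while queue:
        rec_pid = queue.pop(0)
        rec = people[rec_pid]
        child = new_person(rec.wave + 1, rec.seed_id, rec_pid)
        rec.children.append(child.pid)
        if role_i < len(roles):
            child.n_children = roles[role_i]
            role_i += 1
            queue.extend([child.pid] * child.n_children)
        else:
            child.n_children = 0

    assert len(people) == 330, len(people)
    out_counts = {0: 0, 1: 0, 2: 0, 3: 0}
    for p in people.values():
        out_counts[len(p.children)] += 1
    assert out_counts == {0: 156, 1: 69, 2: 66, 3: 39}, out_counts

    # six consistency exclusions: leaf children of six out-degree-2
    # recruiters, so analysis productivity shifts 6 recruiters from 2 to 1
    chosen = 0
    for p in reversed(list(people.values())):
        if chosen == 6:
            break
        if len(p.children) == 2:
            leaf_kids = [c for c in p.children if not people[c].children]
            if leaf_kids:
                people[leaf_kids[-1]].inconsistent = True
                chosen += 1
    assert chosen == 6
    return people


def make_reference_fixture() -> SimulationResult:
    """Build the reference bundle (roster, ledger, forest, truth).

    Run it through the intake pipeline with REFERENCE_INTAKE_CONFIG to
    reproduce the reference funnel.
    """
    people = _build_forest()
    order = sorted(people.values(), key=lambda p: (p.wave, p.pid))

    ident = 0

    def next_identity() -> tuple[str, dt.date]:
        nonlocal ident
        e, d = _email(ident), _dob(ident)
        ident += 1
        return e, d

    # --- identities, traits, enrollment days -----------------------------
    for i, p in enumerate(order):
        p.email, p.dob = next_identity()
        p.day = p.wave * 4
        if p.wave == 0:
            k = int(p.pid[1:]) - 1
            p.zone, p.sex, p.age_group = _SEED_ZONES[k], _SEED_SEX[k], _SEED_AGE[k]
        else:
            p.zone = _ZONE_CYCLE[i % len(_ZONE_CYCLE)]
            p.age_group = _AGE_CYCLE[i % len(_AGE_CYCLE)]
            p.sex = _SEX_CYCLE[i % len(_SEX_CYCLE)]

    # --- operative degrees: largest reports to the best-connected --------
    analysis = [p for p in order if not p.inconsistent]
    q2 = _q2_values()
    by_tree = sorted(
        analysis,
        key=lambda p: (-(len(p.children) + (0 if p.wave == 0 else 1)), p.pid),
    )
    for p, v in zip(by_tree, sorted(q2, reverse=True)):
        p.q2 = v
        p.q1 = min(v + (0, 2, 5)[v % 3], 99) if v < 99 else 99
        p.q1 = max(p.q1, p.q2)
    for p in order:
        if p.inconsistent:
            p.q2, p.q1 = 5, 7

    # --- coupons ----------------------------------------------------------
    code_n = 0

    def new_code() -> str:
        nonlocal code_n
        code_n += 1
        return f"FX{code_n:06d}"

    ledger_rows: list[dict] = []
    study_codes = [new_code() for _ in range(15)]
    for p, code in zip(order[:12], study_codes[:12]):
        p.coupon_in = code
        ledger_rows.append(
            dict(coupon_code=code, issuer_id=SEED_ISSUER, status="used",
                 used_by=p.pid, issued_at=0, used_at=0)
        )
    # three contacted seed candidates never finished the questionnaire
    candidate_codes = study_codes[12:]
    for code in candidate_codes:
        ledger_rows.append(
            dict(coupon_code=code, issuer_id=SEED_ISSUER, status="used",
                 used_by=pd.NA, issued_at=0, used_at=1)
        )

    # every participant is issued 3 coupons; recruits consume their
    # recruiter's coupons in child order
    for p in order:
        p.coupons = [new_code() for _ in range(3)]
    for p in order:
        for slot, c in enumerate(p.children):
            people[c].coupon_in = p.coupons[slot]

    # --- junk-coupon slots ------------------------------------------------
    # usage classes: every out-degree-3 recruiter spends 3; out-degree-2
    # recruiters spend 3 (one junk); 8 out-degree-1 recruiters spend 3, 20
    # spend 2; 9 non-recruiters spend 2 and 35 spend 1. Totals: 113 spend
    # all 3 coupons, 218 spend at least one, 473 coupons consumed.
    deg1 = sorted((p for p in order if len(p.children) == 1), key=lambda p: p.pid)
    deg2 = sorted((p for p in order if len(p.children) == 2), key=lambda p: p.pid)
    deg0 = sorted((p for p in order if len(p.children) == 0), key=lambda p: p.pid)

    junk_slots: list[tuple[_Person, str]] = []  # (issuer, coupon code)
    self_recruit_slots: list[tuple[_Person, str]] = []
    for i, p in enumerate(deg2):
        slot = (p, p.coupons[2])
        (self_recruit_slots if i < 12 else junk_slots).append(slot)
    for p in deg1[:8]:
        junk_slots.append((p, p.coupons[1]))
        junk_slots.append((p, p.coupons[2]))
    for p in deg1[8:28]:
        junk_slots.append((p, p.coupons[1]))
    for p in deg0[:9]:
        junk_slots.append((p, p.coupons[0]))
        junk_slots.append((p, p.coupons[1]))
    for p in deg0[9:44]:
        junk_slots.append((p, p.coupons[0]))
    assert len(junk_slots) == 143 and len(self_recruit_slots) == 12

    # --- attempt rows -----------------------------------------------------
    rows: list[tuple] = []  # (day, seq, dict, truth_kind, truth_person)
    seq = 0

    def add(day: int, rec: dict, kind: str, person: str) -> None:
        nonlocal seq
        seq += 1
        rec.update(day=day)
        rows.append((day, seq, rec, kind, person))

    def participant_row(p: _Person) -> dict:
        devices = {
            "device_e-cigarette": not p.inconsistent,
            "device_heated-tobacco": (not p.inconsistent) and (ord(p.pid[-1]) % 3 == 0),
            "device_vaporizer": (not p.inconsistent) and (ord(p.pid[-1]) % 3 == 1),
        }
        return dict(
            coupon_code=p.coupon_in, email=p.email, dob=p.dob.isoformat(),
            screen_used_12mo=True, screen_age_ok=True, screen_resident=True,
            completed=True, **devices, q1_network=p.q1, q2_network=p.q2,
            age_group=p.age_group, sex=p.sex, zone=p.zone,
            ever_cigarette=(ord(p.pid[-1]) % 5) < 4,
        )

    for p in order:
        add(p.day, participant_row(p), "inconsistent" if p.inconsistent else "valid", p.pid)

    blank = dict(
        **{f"device_{d}": pd.NA for d in ("e-cigarette", "heated-tobacco", "vaporizer")},
        q1_network=pd.NA, q2_network=pd.NA,
        age_group=pd.NA, sex=pd.NA, zone=pd.NA, ever_cigarette=pd.NA,
    )

    # 3 incomplete seed candidates (screen passed, questionnaire abandoned)
    for j, code in enumerate(candidate_codes):
        e, d = next_identity()
        add(1, dict(coupon_code=code, email=e, dob=d.isoformat(),
                    screen_used_12mo=True, screen_age_ok=True,
                    screen_resident=True, completed=False, **blank),
            "incomplete", f"C{j + 1:02d}")

    junk_i = 0

    def next_junk() -> tuple[_Person, str]:
        nonlocal junk_i
        slot = junk_slots[junk_i]
        junk_i += 1
        return slot

    consumed_extra: list[tuple[str, str, int, str]] = []  # code, status, day, used_by

    # 20 automatic blocks: reuse of an already-spent invitation code
    sources = [p for p in order if p.wave > 0]
    for j in range(20):
        src = sources[j * 7 % len(sources)]
        e, d = next_identity()
        add(src.day + 2, dict(coupon_code=src.coupon_in, email=e, dob=d.isoformat(),
                              screen_used_12mo=True, screen_age_ok=True,
                              screen_resident=True, completed=False, **blank),
            "duplicate_code_reuse", f"X{j:03d}")

    # 20 automatic blocks: exact repeat of a registered email address
    for j in range(20):
        src = sources[(j * 11 + 3) % len(sources)]
        issuer, code = next_junk()
        day = max(src.day, issuer.day) + 2
        shouting = src.email.upper() if j % 2 else src.email
        _, d = next_identity()
        add(day, dict(coupon_code=code, email=shouting, dob=d.isoformat(),
                      screen_used_12mo=True, screen_age_ok=True,
                      screen_resident=True, completed=False, **blank),
            "duplicate_email_exact", src.pid)
        consumed_extra.append((code, "used", day, src.pid))

    def requestionnaire(src: _Person, email: str, dob: dt.date, code: str, day: int, kind: str) -> None:
        add(day, dict(coupon_code=code, email=email, dob=dob.isoformat(),
                      screen_used_12mo=True, screen_age_ok=True,
                      screen_resident=True, completed=True,
                      **{"device_e-cigarette": True, "device_heated-tobacco": False,
                         "device_vaporizer": False},
                      q1_network=src.q1, q2_network=src.q2,
                      age_group=src.age_group, sex=src.sex, zone=src.zone,
                      ever_cigarette=True),
            kind, src.pid)

    # 13 manual removals: first/last name inversion
    for j in range(13):
        src = sources[(j * 13 + 5) % len(sources)]
        local, _, dom = src.email.partition("@")
        inverted = ".".join(reversed(local.split("."))) + "@" + dom
        issuer, code = next_junk()
        day = max(src.day, issuer.day) + 3
        _, d = next_identity()
        requestionnaire(src, inverted, d, code, day, "duplicate_inversion")
        consumed_extra.append((code, "used", day, src.pid))

    # 13 manual removals: numeric variant of the same username
    for j in range(13):
        src = sources[(j * 17 + 8) % len(sources)]
        local, _, dom = src.email.partition("@")
        variant = f"{local}{j + 2}@{dom}"
        issuer, code = next_junk()
        day = max(src.day, issuer.day) + 3
        _, d = next_identity()
        requestionnaire(src, variant, d, code, day, "duplicate_numeric")
        consumed_extra.append((code, "used", day, src.pid))

    # 12 manual removals: self-recruitment (fresh email, recruiter's DOB)
    for j, (issuer, code) in enumerate(self_recruit_slots):
        day = issuer.day + 3
        fake = f"vapefriend{j + 1:02d}@example.test"
        requestionnaire(issuer, fake, issuer.dob, code, day, "self_recruit")
        consumed_extra.append((code, "used", day, issuer.pid))

    # 78 ineligible attempts (failed screen); their coupons are invalidated
    fail_patterns = [(False, True, True)] * 55 + [(True, False, True)] * 13 + [(True, True, False)] * 10
    for j, screen in enumerate(fail_patterns):
        issuer, code = next_junk()
        day = issuer.day + 2 + (j % 3)
        e, d = next_identity()
        add(day, dict(coupon_code=code, email=e, dob=d.isoformat(),
                      screen_used_12mo=screen[0], screen_age_ok=screen[1],
                      screen_resident=screen[2], completed=False, **blank),
            "ineligible", f"N{j:03d}")
        consumed_extra.append((code, "invalidated", day, f"N{j:03d}"))

    # 19 incomplete questionnaires through participant coupons
    for j in range(19):
        issuer, code = next_junk()
        day = issuer.day + 2 + (j % 2)
        e, d = next_identity()
        add(day, dict(coupon_code=code, email=e, dob=d.isoformat(),
                      screen_used_12mo=True, screen_age_ok=True,
                      screen_resident=True, completed=False, **blank),
            "incomplete", f"C{j + 4:02d}")
        consumed_extra.append((code, "used", day, f"C{j + 4:02d}"))

    assert junk_i == len(junk_slots)

    # --- assemble frames --------------------------------------------------
    rows.sort(key=lambda r: (r[0], r[1]))
    roster_recs, truth_recs = [], []
    for aid, (day, _seq, rec, kind, person) in enumerate(rows, start=1):
        rec["attempt_id"] = aid
        roster_recs.append(rec)
        truth_recs.append(dict(attempt_id=aid, truth_person_id=person, truth_kind=kind))
    roster = pd.DataFrame(roster_recs)[ROSTER_COLUMNS]
    truth = pd.DataFrame(truth_recs, columns=["attempt_id", "truth_person_id", "truth_kind"])

    extra_status = {code: (status, day, used_by) for code, status, day, used_by in consumed_extra}
    for p in order:
        for slot, code in enumerate(p.coupons):
            if slot < len(p.children):
                child = people[p.children[slot]]
                ledger_rows.append(dict(coupon_code=code, issuer_id=p.pid,
                                        status="used", used_by=child.pid,
                                        issued_at=p.day, used_at=child.day))
            elif code in extra_status:
                s, d, u = extra_status[code]
                ledger_rows.append(dict(coupon_code=code, issuer_id=p.pid,
                                        status=s, used_by=u,
                                        issued_at=p.day, used_at=d))
            else:
                ledger_rows.append(dict(coupon_code=code, issuer_id=p.pid,
                                        status="unused", used_by=pd.NA,
                                        issued_at=p.day, used_at=pd.NA))
    ledger = pd.DataFrame(ledger_rows)[LEDGER_COLUMNS]

    parts = pd.DataFrame(
        {
            "person_id": [p.pid for p in order],
            "wave": [p.wave for p in order],
            "seed_id": [p.seed_id for p in order],
            "recruiter_id": pd.array([p.recruiter for p in order], dtype="string"),
            "coupon_code": [p.coupon_in for p in order],
            "day": [p.day for p in order],
        }
    ).set_index("person_id")
    forest = RecruitmentForest(parts)
    forest.validate()

    return SimulationResult(roster=roster, ledger=ledger, forest=forest, truth=truth)
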