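"""Multistep verification and cleaning funnel for raw attempt rosters.

An incentive-driven web survey attracts repeat participation under disguised
identities, self-recruitment, and coupon use by ineligible contacts. This
module turns the raw roster of access attempts into an analysis-ready
participant roster through five ordered stages:

1. automatic blocking — repeated invitation code, registration email, or
   date of birth (first arrival wins);
2. manual-pattern review — near-duplicate email structures (token
   inversions, numeric variants of the same username, small edits combined
   with an identical or adjacent date of birth) and self-recruitment
   (a different email carrying the recruiter's own date of birth);
3. eligibility screening — all three screen answers must be affirmative;
   the spent coupon of an ineligible attempt is invalidated;
4. completeness — attempts that never finished the questionnaire;
5. consistency — eligible completers whose device-use answers contradict
   the affirmative screen are excluded from analysis but retained for the
   recruitment network.

Every removal carries a machine-readable stage and reason code, and the
funnel report recomputes all percentages from the counts (half-up, one
decimal).
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass, field

import edlib
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from ._util import pct
from .population import DEVICES
from .simulator import SEED_ISSUER

DEVICE_COLS = [f"device_{d}" for d in DEVICES]
SCREEN_COLS = ["screen_used_12mo", "screen_age_ok", "screen_resident"]


class IntakeConfig(BaseModel):
    """Cleaning-stage knobs.

    auto_keys selects which registration fields the automatic block matches
    exactly; similarity_threshold is the normalized edit distance (edits
    divided by the longer normalized address) at or below which two emails
    count as implausibly similar when the dates of birth are within
    dob_window_days of each other.
    """

    model_config = ConfigDict(extra="forbid")

    auto_keys: tuple[str, ...] = ("coupon_code", "email", "dob")
    similarity_threshold: float = Field(default=0.2, ge=0, le=1)
    dob_window_days: int = Field(default=1, ge=0)


# --------------------------------------------------------------------------
# email normalization
# --------------------------------------------------------------------------

def normalize_email(email: str) -> str:
    """Canonical form for near-duplicate matching: lowercase, plus-tag and
    separator characters removed, trailing digits stripped."""
    local, _, domain = str(email).strip().lower().partition("@")
    local = local.partition("+")[0]
    local = re.sub(r"[._]", "", local)
    local = re.sub(r"\d+$", "", local)
    return f"{local}@{domain}"


def email_token_key(email: str) -> tuple:
    """Order-insensitive token key: separator-delimited username tokens,
    each with trailing digits stripped, sorted; detects first/last-name
    inversions and numeric variants in one comparison."""
    local, _, domain = str(email).strip().lower().partition("@")
    local = local.partition("+")[0]
    tokens = [re.sub(r"\d+$", "", t) for t in re.split(r"[._]", local) if t]
    return (tuple(sorted(tokens)), domain)


def normalized_edit_distance(a: str, b: str) -> float:
    if a == b:
        return 0.0
    longer = max(len(a), len(b))
    if longer == 0:
        return 0.0
    return edlib.align(a, b, task="distance")["editDistance"] / longer


def _valid_email(email) -> bool:
    s = str(email)
    return "@" in s and s.partition("@")[0] != "" and not pd.isna(email)


def _parse_dob(dob) -> dt.date | None:
    if isinstance(dob, dt.date) and not isinstance(dob, dt.datetime):
        return dob
    try:
        return dt.date.fromisoformat(str(dob))
    except (ValueError, TypeError):
        return None


# --------------------------------------------------------------------------
# stage 1: automatic blocking
# --------------------------------------------------------------------------

def block_automatic(
    roster: pd.DataFrame, config: IntakeConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Replay the live duplicate filter over the roster in arrival order.

    An attempt is removed iff its invitation code was already spent, or its
    registration email (case-folded) or date of birth exactly matches an
    earlier kept attempt, per config.auto_keys. Malformed email/DOB rows go
    to a quarantine frame rather than being dropped silently.

    Returns (kept, removed, quarantined); removed carries a reason column.
    """
    config = config or IntakeConfig()
    seen: dict[str, set] = {k: set() for k in config.auto_keys}
    kept_idx: list[int] = []
    removed: list[tuple[int, str]] = []
    quarantined: list[int] = []
    for idx, row in roster.iterrows():
        email_ok = _valid_email(row["email"])
        dob = _parse_dob(row["dob"])
        if not email_ok or dob is None:
            quarantined.append(idx)
            continue
        keyvals = {
            "coupon_code": str(row["coupon_code"]),
            "email": str(row["email"]).strip().lower(),
            "dob": dob,
        }
        reason = None
        for k in config.auto_keys:
            if keyvals[k] in seen[k]:
                reason = f"repeat_{k.replace('coupon_code', 'code')}"
                break
        if reason is not None:
            removed.append((idx, reason))
            continue
        for k in config.auto_keys:
            seen[k].add(keyvals[k])
        kept_idx.append(idx)
    kept = roster.loc[kept_idx]
    rem = roster.loc[[i for i, _ in removed]].copy()
    rem["reason"] = [r for _, r in removed]
    quar = roster.loc[quarantined]
    return kept, rem, quar


# --------------------------------------------------------------------------
# stage 2: manual-pattern review
# --------------------------------------------------------------------------

def recruiter_dob_map(roster: pd.DataFrame, ledger: pd.DataFrame) -> dict[str, dt.date]:
    """coupon_code -> registration DOB of the coupon's issuer, recovered
    from the observed bundle alone (the issuer enrolled through some earlier
    coupon recorded in the ledger)."""
    code_to_dob = {
        str(r["coupon_code"]): _parse_dob(r["dob"]) for _, r in roster.iterrows()
    }
    enrolled_code: dict[str, str] = {}
    for _, c in ledger.iterrows():
        if c["status"] == "used" and pd.notna(c["used_by"]):
            code = str(c["coupon_code"])
            if code in code_to_dob:
                enrolled_code.setdefault(str(c["used_by"]), code)
    out: dict[str, dt.date] = {}
    for _, c in ledger.iterrows():
        issuer = str(c["issuer_id"])
        if issuer == SEED_ISSUER or issuer not in enrolled_code:
            continue
        dob = code_to_dob.get(enrolled_code[issuer])
        if dob is not None:
            out[str(c["coupon_code"])] = dob
    return out


def flag_manual_patterns(
    roster: pd.DataFrame,
    ledger: pd.DataFrame | None = None,
    config: IntakeConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Manual review pass over automatically kept attempts.

    Removes, in arrival order and against earlier *kept* attempts only:
    token-inversion and numeric-variant addresses (normalized/token-key
    equality), small-edit addresses combined with an identical-or-adjacent
    DOB, and self-recruitment (the attempt's DOB equals its recruiter's
    registration DOB under a different email). Ties between candidate
    matches resolve to the earliest kept attempt.
    """
    config = config or IntakeConfig()
    rec_dob = (
        recruiter_dob_map(roster, ledger) if ledger is not None else {}
    )
    kept_idx: list[int] = []
    kept_info: list[tuple[str, tuple, dt.date | None, str]] = []  # norm, key, dob, raw
    removed: list[tuple[int, str]] = []
    for idx, row in roster.iterrows():
        email = str(row["email"]).strip().lower()
        norm = normalize_email(email)
        key = email_token_key(email)
        dob = _parse_dob(row["dob"])
        reason = None

        r_dob = rec_dob.get(str(row["coupon_code"]))
        if r_dob is not None and dob == r_dob:
            reason = "self_recruit"

        if reason is None:
            for k_norm, k_key, k_dob, k_raw in kept_info:
                if k_raw == email:
                    continue  # exact repeats belong to the automatic stage
                if key == k_key or norm == k_norm:
                    had_digits = bool(re.search(r"\d", email)) or bool(
                        re.search(r"\d", k_raw)
                    )
                    if key == k_key and norm != k_norm:
                        reason = "token_inversion"
                    elif had_digits:
                        reason = "numeric_variant"
                    else:
                        reason = "duplicate_email_structure"
                    break
                if (
                    dob is not None
                    and k_dob is not None
                    and abs((dob - k_dob).days) <= config.dob_window_days
                    and normalized_edit_distance(norm, k_norm) <= config.similarity_threshold
                ):
                    reason = "similar_email_dob"
                    break

        if reason is not None:
            removed.append((idx, reason))
        else:
            kept_idx.append(idx)
            kept_info.append((norm, key, dob, email))
    kept = roster.loc[kept_idx]
    rem = roster.loc[[i for i, _ in removed]].copy()
    rem["reason"] = [r for _, r in removed]
    return kept, rem


# --------------------------------------------------------------------------
# stage 3: eligibility screen
# --------------------------------------------------------------------------

def screen_eligibility(
    roster: pd.DataFrame, ledger: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Keep attempts whose three screen answers are all affirmative.

    A missing answer is conservatively ineligible (reason missing_screen).
    When a ledger is supplied, coupons spent by ineligible attempts are
    marked invalidated (they cannot be reused); the updated ledger is
    returned.
    """
    answers = roster[SCREEN_COLS]
    missing = answers.isna().any(axis=1)
    all_yes = answers.astype("boolean").fillna(False).all(axis=1)
    eligible = roster[all_yes & ~missing]
    inel = roster[~(all_yes & ~missing)].copy()
    inel["reason"] = ["missing_screen" if m else "failed_screen" for m in missing[inel.index]]
    new_ledger = None
    if ledger is not None:
        new_ledger = ledger.copy()
        bad_codes = set(inel["coupon_code"].astype(str))
        mask = new_ledger["coupon_code"].astype(str).isin(bad_codes) & (
            new_ledger["status"] != "unused"
        )
        new_ledger.loc[mask, "status"] = "invalidated"
    return eligible, inel, new_ledger


# --------------------------------------------------------------------------
# stage 4: completeness; stage 5: consistency
# --------------------------------------------------------------------------

def filter_complete(roster: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    done = roster["completed"].astype("boolean").fillna(False)
    inc = roster[~done].copy()
    inc["reason"] = "incomplete"
    return roster[done], inc


def check_consistency(roster: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude eligible completers whose device-use answers are all
    empty/negative despite the affirmative screen. Excluded records remain
    in the recruitment forest; they only leave the analysis roster."""
    dev = roster[DEVICE_COLS].astype("boolean").fillna(False)
    inconsistent = ~dev.any(axis=1)
    excl = roster[inconsistent].copy()
    excl["reason"] = "device_fields_contradict_screen"
    return roster[~inconsistent], excl


# --------------------------------------------------------------------------
# funnel report and pipeline driver
# --------------------------------------------------------------------------

@dataclass
class FunnelReport:
    n_attempts: int
    n_blocked_auto: int
    n_invalid_manual: int
    n_ineligible: int
    n_incomplete: int
    n_valid: int
    n_inconsistent: int
    n_analysis: int
    n_quarantined: int = 0
    percentages: dict[str, float] = field(default_factory=dict)

    @property
    def n_invalid_or_ineligible(self) -> int:
        """Duplicates (automatic + manual) plus screen failures combined —
        the headline removal count."""
        return self.n_blocked_auto + self.n_invalid_manual + self.n_ineligible

    def validate(self) -> None:
        total = (
            self.n_blocked_auto
            + self.n_invalid_manual
            + self.n_ineligible
            + self.n_incomplete
            + self.n_quarantined
            + self.n_valid
        )
        if total != self.n_attempts:
            raise ValueError(
                f"funnel does not conserve attempts: {total} != {self.n_attempts}"
            )
        if self.n_analysis != self.n_valid - self.n_inconsistent:
            raise ValueError("n_analysis must equal n_valid - n_inconsistent")
        expect = self._compute_percentages()
        for k, v in expect.items():
            if self.percentages.get(k) != v:
                raise ValueError(f"percentage {k} does not recompute from counts")

    def _compute_percentages(self) -> dict[str, float]:
        n = self.n_attempts
        return {
            "blocked_auto": pct(self.n_blocked_auto, n),
            "invalid_manual": pct(self.n_invalid_manual, n),
            "ineligible": pct(self.n_ineligible, n),
            "invalid_or_ineligible": pct(self.n_invalid_or_ineligible, n),
            "incomplete": pct(self.n_incomplete, n),
            "valid": pct(self.n_valid, n),
            "inconsistent_of_valid": pct(self.n_inconsistent, self.n_valid),
            "analysis": pct(self.n_analysis, n),
        }

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "n_attempts", "n_blocked_auto", "n_invalid_manual", "n_ineligible",
            "n_incomplete", "n_valid", "n_inconsistent", "n_analysis",
            "n_quarantined",
        )}
        d["n_invalid_or_ineligible"] = self.n_invalid_or_ineligible
        d["percentages"] = self.percentages
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        p = self.percentages
        lines = [
            f"Access attempts recorded           {self.n_attempts}",
            f"  blocked automatically            {self.n_blocked_auto} ({p['blocked_auto']}%)",
            f"  removed in manual review         {self.n_invalid_manual} ({p['invalid_manual']}%)",
            f"  ineligible at screen             {self.n_ineligible} ({p['ineligible']}%)",
            f"  [duplicate or ineligible total   {self.n_invalid_or_ineligible} ({p['invalid_or_ineligible']}%)]",
            f"  incomplete questionnaires        {self.n_incomplete} ({p['incomplete']}%)",
        ]
        if self.n_quarantined:
            lines.append(f"  quarantined (malformed fields)   {self.n_quarantined}")
        lines += [
            f"Valid participants                 {self.n_valid} ({p['valid']}%)",
            f"  device-use inconsistencies       {self.n_inconsistent} ({p['inconsistent_of_valid']}% of valid)",
            f"Analysis roster                    {self.n_analysis}",
        ]
        return "\n".join(lines)


def build_funnel_report(
    n_attempts: int,
    n_blocked_auto: int,
    n_invalid_manual: int,
    n_ineligible: int,
    n_incomplete: int,
    n_valid: int,
    n_inconsistent: int,
    n_quarantined: int = 0,
) -> FunnelReport:
    rep = FunnelReport(
        n_attempts=n_attempts,
        n_blocked_auto=n_blocked_auto,
        n_invalid_manual=n_invalid_manual,
        n_ineligible=n_ineligible,
        n_incomplete=n_incomplete,
        n_valid=n_valid,
        n_inconsistent=n_inconsistent,
        n_analysis=n_valid - n_inconsistent,
        n_quarantined=n_quarantined,
    )
    rep.percentages = rep._compute_percentages()
    rep.validate()
    return rep


@dataclass
class IntakeResult:
    funnel: FunnelReport
    valid_roster: pd.DataFrame
    analysis_roster: pd.DataFrame
    removals: pd.DataFrame  # attempt_id, stage, reason
    ledger: pd.DataFrame | None
    quarantine: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.valid_roster.to_csv(out / "valid_roster.csv", index=False)
        self.analysis_roster.to_csv(out / "analysis_roster.csv", index=False)
        self.removals.to_csv(out / "removals.csv", index=False)
        (out / "funnel.json").write_text(self.funnel.to_json())
        (out / "funnel.txt").write_text(self.funnel.to_text() + "\n")
        if self.ledger is not None:
            self.ledger.to_csv(out / "coupon_ledger.csv", index=False)


def run_intake(
    roster: pd.DataFrame,
    ledger: pd.DataFrame | None = None,
    config: IntakeConfig | None = None,
) -> IntakeResult:
    """Run the five cleaning stages in order and assemble the funnel report."""
    config = config or IntakeConfig()
    removal_frames = []

    kept, rem_auto, quarantine = block_automatic(roster, config)
    removal_frames.append(rem_auto.assign(stage="automatic_block"))

    kept, rem_manual = flag_manual_patterns(kept, ledger, config)
    removal_frames.append(rem_manual.assign(stage="manual_review"))

    kept, rem_inel, new_ledger = screen_eligibility(kept, ledger)
    removal_frames.append(rem_inel.assign(stage="eligibility_screen"))

    valid, rem_inc = filter_complete(kept)
    removal_frames.append(rem_inc.assign(stage="completeness"))

    analysis, rem_incons = check_consistency(valid)
    removal_frames.append(rem_incons.assign(stage="consistency"))

    removals = pd.concat(
        [f[["attempt_id", "stage", "reason"]] for f in removal_frames],
        ignore_index=True,
    )
    funnel = build_funnel_report(
        n_attempts=len(roster),
        n_blocked_auto=len(rem_auto),
        n_invalid_manual=len(rem_manual),
        n_ineligible=len(rem_inel),
        n_incomplete=len(rem_inc),
        n_valid=len(valid),
        n_inconsistent=len(rem_incons),
        n_quarantined=len(quarantine),
    )
    return IntakeResult(
        funnel=funnel,
        valid_roster=valid,
        analysis_roster=analysis,
        removals=removals,
        ledger=new_ledger if new_ledger is not None else ledger,
        quarantine=quarantine,
    )
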