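"""Self-reported network size and deterministic imputation of implausible
reports.

The degree instrument asks two questions: how many ENDS users the
respondent knows in the city (q1) and how many of those are aged >= 15
(q2, the operative degree for weighting). A report is implausible when it
is zero or smaller than the respondent's visible connections in the
recruitment tree (recruiter plus recruits). Implausible q2 values are
replaced by q1 when q1 itself is plausible; otherwise by the rounded mean
of the plausible operative degrees in the sample. Inverse-degree weighting
breaks down on artificially small degrees, which is why the rule never
lets a degree fall below the observed tree connections (or 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import round_half_up
from .simulator import RecruitmentForest

FLAG_NONE = "none"
FLAG_Q1 = "q1_substituted"
FLAG_MEAN = "mean_substituted"

DEGREE_COLUMNS = ["person_id", "q1", "q2", "tree_degree", "degree_final", "imputation_flag"]


@dataclass(frozen=True)
class DegreeRecord:
    person_id: str
    q1: int
    q2: int
    tree_degree: int
    degree_final: int | None = None
    imputation_flag: str = FLAG_NONE


def compute_tree_degree(person_id: str, forest: RecruitmentForest) -> int:
    """Connections visible in the recruitment tree: the recruiter (absent
    for seeds) plus every recruit."""
    if person_id not in forest.participants.index:
        raise KeyError(f"{person_id!r} is not enrolled in the forest")
    has_recruiter = 0 if forest.is_seed(person_id) else 1
    return has_recruiter + len(forest.recruits_of(person_id))


def _plausible(value: int, tree_degree: int) -> bool:
    return value > 0 and value >= tree_degree


def impute_degree(record: DegreeRecord, valid_mean: float) -> DegreeRecord:
    """Apply the deterministic substitution rule to one record.

    Pure in (q1, q2, tree_degree, valid_mean); valid_mean must come from the
    plausible records of the same sample (two-pass evaluation keeps the
    result independent of record order).
    """
    if valid_mean <= 0:
        raise ValueError("valid_mean must be positive (no valid records to anchor it)")
    if _plausible(record.q2, record.tree_degree):
        return replace(record, degree_final=int(record.q2), imputation_flag=FLAG_NONE)
    if _plausible(record.q1, record.tree_degree):
        return replace(record, degree_final=int(record.q1), imputation_flag=FLAG_Q1)
    final = max(int(round_half_up(valid_mean)), record.tree_degree, 1)
    return replace(record, degree_final=final, imputation_flag=FLAG_MEAN)


def build_degree_records(
    analysis_roster: pd.DataFrame, forest: RecruitmentForest
) -> pd.DataFrame:
    """Join the analysis roster to the forest (via enrollment coupon) and
    compute tree degrees. Returns the degrees table before imputation."""
    code_to_pid = {
        str(row["coupon_code"]): pid for pid, row in forest.participants.iterrows()
    }
    rows = []
    for _, r in analysis_roster.iterrows():
        code = str(r["coupon_code"])
        if code not in code_to_pid:
            raise KeyError(f"attempt coupon {code} not found among enrollments")
        pid = code_to_pid[code]
        rows.append(
            {
                "person_id": pid,
                "q1": int(r["q1_network"]),
                "q2": int(r["q2_network"]),
                "tree_degree": compute_tree_degree(pid, forest),
            }
        )
    return pd.DataFrame(rows, columns=["person_id", "q1", "q2", "tree_degree"])


def impute_degrees(records: pd.DataFrame) -> pd.DataFrame:
    """Two-pass imputation over a degrees table.

    Pass 1 freezes the mean of the plausible operative degrees; pass 2
    applies the substitution rule record by record against that frozen
    mean. Raises if no record is plausible.
    """
    plaus = records.apply(lambda r: _plausible(int(r["q2"]), int(r["tree_degree"])), axis=1)
    if not plaus.any():
        raise ValueError("no plausible operative degrees to anchor the valid mean")
    valid_mean = float(records.loc[plaus, "q2"].mean())
    out = records.copy()
    finals, flags = [], []
    for _, r in records.iterrows():
        rec = impute_degree(
            DegreeRecord(
                person_id=str(r["person_id"]),
                q1=int(r["q1"]),
                q2=int(r["q2"]),
                tree_degree=int(r["tree_degree"]),
            ),
            valid_mean,
        )
        finals.append(rec.degree_final)
        flags.append(rec.imputation_flag)
    out["degree_final"] = finals
    out["imputation_flag"] = flags
    return out


def inject_degree_corruptions(
    records: pd.DataFrame,
    n_rule1: int,
    n_rule2: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Corrupt a degrees table so that exactly n_rule1 records trigger the
    q1 substitution and n_rule2 trigger the mean substitution; used to
    exercise the imputation audit trail against known truth."""
    if n_rule1 + n_rule2 > len(records):
        raise ValueError("more corruptions requested than records available")
    out = records.copy().reset_index(drop=True)
    idx = rng.choice(len(out), size=n_rule1 + n_rule2, replace=False)
    for i in idx[:n_rule1]:
        tree = int(out.loc[i, "tree_degree"])
        out.loc[i, "q2"] = 0
        out.loc[i, "q1"] = max(int(out.loc[i, "q1"]), tree + 2, 1)
    for i in idx[n_rule1:]:
        out.loc[i, "q2"] = 0
        out.loc[i, "q1"] = 0
    return out


def degree_summary(records: pd.DataFrame) -> dict:
    """Distribution summary of the operative degree after imputation."""
    if "degree_final" not in records or records["degree_final"].isna().any():
        raise ValueError("records must be imputed before summarizing")
    d = records["degree_final"].astype(int)
    n = len(d)
    n_le5 = int((d <= 5).sum())
    n_gt10 = int((d > 10).sum())
    flags = records["imputation_flag"].value_counts().to_dict()
    n_imputed = n - int(flags.get(FLAG_NONE, 0))
    from ._util import pct

    return {
        "n": n,
        "n_le5": n_le5,
        "pct_le5": pct(n_le5, n),
        "n_gt10": n_gt10,
        "pct_gt10": pct(n_gt10, n),
        "max": int(d.max()) if n else 0,
        "mode": int(d.mode().iloc[0]) if n else None,
        "imputed": {
            FLAG_Q1: int(flags.get(FLAG_Q1, 0)),
            FLAG_MEAN: int(flags.get(FLAG_MEAN, 0)),
        },
        "n_imputed": n_imputed,
        "pct_imputed": pct(n_imputed, n),
    }


def degree_histogram(records: pd.DataFrame) -> pd.DataFrame:
    """Tidy histogram series (degree, count) for plotting."""
    counts = records["degree_final"].astype(int).value_counts().sort_index()
    return counts.rename_axis("degree").reset_index(name="count")


def write_degrees(records: pd.DataFrame, path) -> None:
    records[DEGREE_COLUMNS].to_csv(path, index=False)


def read_degrees(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"person_id": str})
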