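"""Cleaning funnel: automatic blocking against a brute-force oracle,
manual near-duplicate patterns, eligibility/completeness/consistency
stages, funnel arithmetic and detection performance on simulated fraud."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from webrds import (
    IntakeConfig,
    PopulationConfig,
    SimulationConfig,
    block_automatic,
    build_funnel_report,
    check_consistency,
    flag_manual_patterns,
    generate_population,
    normalize_email,
    run_intake,
    run_recruitment,
    screen_eligibility,
)
from webrds.intake import email_token_key

from conftest import NO_FRAUD


def _row(attempt_id, code, email, dob, screen=(True, True, True), completed=True,
         devices=(True, False, False), q=(5, 5)):
    return {
        "attempt_id": attempt_id,
        "coupon_code": code,
        "email": email,
        "dob": dob,
        "day": attempt_id,
        "screen_used_12mo": screen[0],
        "screen_age_ok": screen[1],
        "screen_resident": screen[2],
        "completed": completed,
        "device_e-cigarette": devices[0],
        "device_heated-tobacco": devices[1],
        "device_vaporizer": devices[2],
        "q1_network": q[0],
        "q2_network": q[1],
        "age_group": "25-34",
        "sex": "female",
        "zone": "south",
        "ever_cigarette": True,
    }


class TestNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Ana.Silva@X.test", "anasilva@x.test"),
            ("ana_silva@x.test", "anasilva@x.test"),
            ("ana.silva+promo@x.test", "anasilva@x.test"),
            ("ana.silva77@x.test", "anasilva@x.test"),
        ],
    )
    def test_normalize_email(self, raw, expected):
        assert normalize_email(raw) == expected

    def test_token_key_detects_inversion_and_digits(self):
        assert email_token_key("ana.silva@x") == email_token_key("silva.ana@x")
        assert email_token_key("joao@x") == email_token_key("joao2@x")
        assert email_token_key("ana.silva@x") != email_token_key("ana.souza@x")


class TestAutomaticBlock:
    def test_repeated_code_removed(self):
        roster = pd.DataFrame(
            [_row(1, "A1", "a@x", "2000-01-01"), _row(2, "A1", "b@x", "1999-01-01")]
        )
        kept, removed, _ = block_automatic(roster)
        assert list(kept["attempt_id"]) == [1]
        assert list(removed["reason"]) == ["repeat_code"]

    def test_distinct_attempts_all_kept(self):
        roster = pd.DataFrame(
            [_row(i, f"A{i}", f"u{i}@x", f"199{i}-01-01") for i in range(1, 6)]
        )
        kept, removed, quarantined = block_automatic(roster)
        assert len(kept) == 5 and removed.empty and quarantined.empty

    def test_malformed_rows_quarantined(self):
        roster = pd.DataFrame(
            [
                _row(1, "A1", "a@x", "2000-01-01"),
                _row(2, "A2", "no-at-sign", "2000-02-02"),
                _row(3, "A3", "c@x", "not-a-date"),
            ]
        )
        kept, removed, quarantined = block_automatic(roster)
        assert list(kept["attempt_id"]) == [1]
        assert sorted(quarantined["attempt_id"]) == [2, 3]
        assert removed.empty

    def test_matches_bruteforce_quadratic_scan(self):
        """1,000-row randomized roster: the sequential filter keeps exactly
        the rows a pairwise first-match scan keeps."""
        rng = np.random.default_rng(42)
        rows = []
        for i in range(1, 1001):
            code = f"C{rng.integers(0, 700):04d}"
            email = f"user{rng.integers(0, 700)}@x.test"
            dob = (
                dt.date(1980, 1, 1) + dt.timedelta(days=int(rng.integers(0, 700)))
            ).isoformat()
            rows.append(_row(i, code, email, dob))
        roster = pd.DataFrame(rows)

        kept, removed, _ = block_automatic(roster)

        # oracle: O(n^2) scan; row i removed iff some kept earlier row
        # shares a key
        oracle_kept = []
        for i in range(len(roster)):
            ri = roster.iloc[i]
            dup = any(
                roster.iloc[j]["coupon_code"] == ri["coupon_code"]
                or roster.iloc[j]["email"].lower() == ri["email"].lower()
                or roster.iloc[j]["dob"] == ri["dob"]
                for j in oracle_kept
            )
            if not dup:
                oracle_kept.append(i)
        assert list(kept.index) == oracle_kept

    def test_permuting_rows_preserves_kept_count(self):
        """Shuffling arrival order changes which clone of an identity is
        kept, never how many distinct identities survive."""
        rng = np.random.default_rng(7)
        rows = []
        for i in range(120):
            rows.append(_row(i, f"C{i}", f"u{i}@x", f"19{70 + i % 30}-03-0{1 + i % 9}"))
        # add clones that copy every key of their original
        for j, src in enumerate(rng.integers(0, 120, size=40)):
            clone = dict(rows[src])
            clone["attempt_id"] = 1000 + j
            rows.append(clone)
        roster = pd.DataFrame(rows)
        kept_counts = set()
        for perm_seed in range(5):
            perm = np.random.default_rng(perm_seed).permutation(len(roster))
            shuffled = roster.iloc[perm].reset_index(drop=True)
            shuffled["attempt_id"] = range(len(shuffled))
            kept, _, _ = block_automatic(shuffled)
            kept_counts.add(len(kept))
        assert len(kept_counts) == 1


class TestManualPatterns:
    def test_token_inversion_detected(self):
        roster = pd.DataFrame(
            [
                _row(1, "A1", "ana.silva@x", "2000-01-01"),
                _row(2, "A2", "silva.ana@x", "1995-05-05"),
            ]
        )
        kept, removed = flag_manual_patterns(roster)
        assert list(kept["attempt_id"]) == [1]
        assert list(removed["reason"]) == ["token_inversion"]

    def test_numeric_variant_detected(self):
        roster = pd.DataFrame(
            [
                _row(1, "A1", "joao@x", "2000-01-01"),
                _row(2, "A2", "joao2@x", "2000-01-01"),
            ]
        )
        _, removed = flag_manual_patterns(roster)
        assert list(removed["reason"]) == ["numeric_variant"]

    def test_small_edit_with_close_dob_detected(self):
        roster = pd.DataFrame(
            [
                _row(1, "A1", "carla.gomes@x.test", "2001-07-07"),
                _row(2, "A2", "carla.gomez@x.test", "2001-07-08"),
            ]
        )
        _, removed = flag_manual_patterns(roster)
        assert list(removed["reason"]) == ["similar_email_dob"]

    def test_small_edit_with_distant_dob_kept(self):
        roster = pd.DataFrame(
            [
                _row(1, "A1", "carla.gomes@x.test", "2001-07-07"),
                _row(2, "A2", "carla.gomez@x.test", "1988-01-01"),
            ]
        )
        kept, removed = flag_manual_patterns(roster)
        assert len(kept) == 2 and removed.empty

    def test_self_recruitment_detected_via_ledger(self):
        # P1 enrolled via coupon A1 (dob 2000-01-01) and issued B1; B1 is
        # then used under a fresh email but P1's own date of birth
        roster = pd.DataFrame(
            [
                _row(1, "A1", "ana.silva@x", "2000-01-01"),
                _row(2, "B1", "totally.new@x", "2000-01-01"),
            ]
        )
        ledger = pd.DataFrame(
            [
                ("A1", "STUDY", "used", "P1", 0, 0),
                ("B1", "P1", "used", "P1", 0, 2),
            ],
            columns=["coupon_code", "issuer_id", "status", "used_by", "issued_at", "used_at"],
        )
        _, removed = flag_manual_patterns(roster, ledger)
        assert list(removed["attempt_id"]) == [2]
        assert list(removed["reason"]) == ["self_recruit"]

    def test_tie_resolves_to_earliest_kept(self):
        roster = pd.DataFrame(
            [
                _row(1, "A1", "ana.silva@x", "2000-01-01"),
                _row(2, "A2", "ana.silva@y", "1990-01-01"),  # different domain: kept
                _row(3, "A3", "silva.ana@x", "1980-01-01"),
            ]
        )
        kept, removed = flag_manual_patterns(roster)
        assert list(kept["attempt_id"]) == [1, 2]
        assert list(removed["attempt_id"]) == [3]


class TestScreenAndConsistency:
    def test_all_affirmative_is_eligible(self):
        roster = pd.DataFrame([_row(1, "A1", "a@x", "2000-01-01")])
        eligible, ineligible, _ = screen_eligibility(roster)
        assert len(eligible) == 1 and ineligible.empty

    def test_failed_screen_invalidates_coupon(self):
        roster = pd.DataFrame(
            [_row(1, "A1", "a@x", "2000-01-01", screen=(True, True, False), completed=False)]
        )
        ledger = pd.DataFrame(
            [("A1", "P9", "used", "N1", 0, 1)],
            columns=["coupon_code", "issuer_id", "status", "used_by", "issued_at", "used_at"],
        )
        eligible, ineligible, new_ledger = screen_eligibility(roster, ledger)
        assert eligible.empty
        assert list(ineligible["reason"]) == ["failed_screen"]
        assert new_ledger.loc[0, "status"] == "invalidated"

    def test_missing_screen_answer_is_ineligible(self):
        roster = pd.DataFrame(
            [_row(1, "A1", "a@x", "2000-01-01", screen=(True, None, True))]
        )
        _, ineligible, _ = screen_eligibility(roster)
        assert list(ineligible["reason"]) == ["missing_screen"]

    def test_contradictory_device_fields_excluded(self):
        roster = pd.DataFrame(
            [
                _row(1, "A1", "a@x", "2000-01-01", devices=(False, False, False)),
                _row(2, "A2", "b@x", "1999-01-01", devices=(True, False, False)),
            ]
        )
        kept, excluded = check_consistency(roster)
        assert list(kept["attempt_id"]) == [2]
        assert list(excluded["attempt_id"]) == [1]


class TestFunnelReport:
    def test_counts_must_conserve_attempts(self):
        with pytest.raises(ValueError, match="conserve"):
            build_funnel_report(100, 10, 10, 10, 10, 70, 0)

    def test_empty_roster_all_zero(self):
        result = run_intake(pd.DataFrame(columns=pd.DataFrame([_row(1, "A", "a@x", "2000-01-01")]).columns))
        assert result.funnel.n_attempts == 0
        assert result.funnel.n_analysis == 0

    def test_percentages_recompute_from_counts(self):
        rep = build_funnel_report(508, 40, 38, 78, 22, 330, 6)
        assert rep.percentages["invalid_or_ineligible"] == 30.7
        assert rep.percentages["incomplete"] == 4.3
        assert rep.percentages["inconsistent_of_valid"] == 1.8
        rep.validate()


class TestPipelineProperties:
    def test_idempotent_on_own_output(self, reference_intake):
        again = run_intake(reference_intake.analysis_roster.reset_index(drop=True))
        f = again.funnel
        assert f.n_valid == f.n_attempts == f.n_analysis
        assert f.n_blocked_auto == f.n_invalid_manual == 0
        assert f.n_ineligible == f.n_incomplete == f.n_inconsistent == 0

    def test_zero_fraud_run_passes_untouched(self, clean_sim_result):
        result = run_intake(clean_sim_result.roster, clean_sim_result.ledger)
        assert result.funnel.n_valid == result.funnel.n_attempts
        assert result.funnel.n_analysis == result.funnel.n_attempts
        assert result.removals.empty

    def test_detection_recall_and_precision_on_simulated_fraud(self):
        """Default heuristics: >=95% of injected duplicate/self-recruit
        attempts caught, <=1% of genuine attempts wrongly removed."""
        n_true = n_caught = n_valid = n_fp = 0
        for pop_seed in range(5):
            pop = generate_population(
                PopulationConfig(
                    n_total=10000,
                    prevalence_eligible=0.07,
                    mean_degree=8,
                    rng_seed=pop_seed,
                )
            )
            for sim_seed in range(4):
                res = run_recruitment(
                    pop,
                    SimulationConfig(
                        rng_seed=sim_seed,
                        target_n=300,
                        p_duplicate_attempt=0.15,
                        p_self_recruit=0.04,
                    ),
                )
                cleaned = run_intake(res.roster, res.ledger)
                truth = res.truth.set_index("attempt_id")["truth_kind"]
                rem = cleaned.removals.join(truth, on="attempt_id")
                dup_stage = rem["stage"].isin(["automatic_block", "manual_review"])
                fraud = truth.isin(["duplicate", "self_recruit"])
                n_true += int(fraud.sum())
                n_caught += int((rem.loc[dup_stage, "truth_kind"]
                                 .isin(["duplicate", "self_recruit"])).sum())
                valid_kinds = ["valid", "inconsistent"]
                n_valid += int(truth.isin(valid_kinds).sum())
                n_fp += int(rem.loc[dup_stage, "truth_kind"].isin(valid_kinds).sum())
        assert n_true > 100
        assert n_caught / n_true >= 0.95
        assert n_fp / n_valid <= 0.01
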