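"""Majority-rule conflict resolution and systematic-error triage."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from metaharm.config import AttributeSpec, HarmonizationConfig
from metaharm.conflicts import (
    ConflictGroup,
    InvariantPolicyError,
    apply_resolutions,
    find_conflicts,
    majority_resolve,
    resolve_conflicts,
    restrict_to_invariant,
    systematic_error_report,
)
from metaharm.engine import HarmonizedTable
from metaharm.issues import IssueKind, Severity, ValidationIssue


def _sex_table(rows: list[tuple[str, str, str | None]]) -> HarmonizedTable:
    """rows: (participant, sample, sex value)."""
    return HarmonizedTable(
        pd.DataFrame(
            [
                {
                    "curation_id": f"s:{p}:{smp}",
                    "participant_id": p,
                    "curated_sex": v,
                }
                for p, smp, v in rows
            ]
        )
    )


def _group(values: list[str | None], key: str = "s:p") -> ConflictGroup:
    obs = [(v, f"{key}:S{i}") for i, v in enumerate(values) if v is not None]
    nas = [f"{key}:S{i}" for i, v in enumerate(values) if v is None]
    return ConflictGroup(key, "sex", obs, nas)


class TestFindConflicts:
    def test_two_against_one_is_a_group(self):
        t = _sex_table([("p", "1", "M"), ("p", "2", "M"), ("p", "3", "F")])
        groups = find_conflicts(t, "sex")
        assert len(groups) == 1
        assert Counter(v for v, _ in groups[0].observations) == {"M": 2, "F": 1}

    def test_unanimous_group_excluded(self):
        t = _sex_table([("p", "1", "M"), ("p", "2", "M"), ("p", "3", "M")])
        assert find_conflicts(t, "sex") == []

    def test_value_plus_na_is_inference_candidate(self):
        t = _sex_table([("p", "1", "M"), ("p", "2", None)])
        groups = find_conflicts(t, "sex")
        assert len(groups) == 1 and groups[0].na_count == 1

    def test_multi_valued_attribute_refused(self, toy):
        from metaharm.simulate import CorruptionProfile, make_messy_metadata
        from metaharm.engine import harmonize_table

        b = make_messy_metadata(CorruptionProfile(seed=2, n_participants=5), toy)
        res = harmonize_table(b.messy, b.config, b.maps, toy.graph, timestamp="T")
        with pytest.raises(ValueError, match="single-valued"):
            find_conflicts(res.table, "ancestry")


def _oracle_resolve(values: list[str | None], mode: str = "plurality"):
    """Independent brute-force majority oracle."""
    votes = [v for v in values if v is not None]
    counts = Counter(votes)
    best = max(counts.values())
    winners = [v for v, n in counts.items() if n == best]
    if len(winners) > 1 or (mode == "strict" and best * 2 <= len(votes)):
        return None  # tie -> NA for everyone
    return winners[0]


class TestMajorityResolve:
    def test_two_one_majority_corrects_minority(self):
        r = majority_resolve(_group(["M", "M", "F"]))
        assert r.value == "M" and r.action == "majority-corrected"
        assert r.affected == ["s:p:S2"]

    def test_even_split_sets_all_na(self):
        r = majority_resolve(_group(["M", "F"]))
        assert r.value is None and r.action == "tie-NA"
        assert set(r.affected) == {"s:p:S0", "s:p:S1"}

    def test_nas_filled_by_winner(self):
        r = majority_resolve(_group(["M", None, None]))
        assert r.value == "M" and r.action == "inferred"
        assert set(r.affected) == {"s:p:S1", "s:p:S2"}

    def test_plurality_wins_without_absolute_majority(self):
        r = majority_resolve(_group(["A", "A", "B", "C"]))
        assert r.value == "A"

    def test_strict_mode_requires_over_half(self):
        r = majority_resolve(_group(["A", "A", "B", "C"]), mode="strict")
        assert r.value is None and r.action == "tie-NA"

    @pytest.mark.parametrize("mode", ["plurality", "strict"])
    def test_exhaustive_enumeration_matches_oracle(self, mode):
        """All vote patterns over {M, F, NA} for group sizes 2..5."""
        for k in range(2, 6):
            for pattern in itertools.product(["M", "F", None], repeat=k):
                if all(v is None for v in pattern):
                    continue
                g = _group(list(pattern))
                r = majority_resolve(g, mode=mode)
                want = _oracle_resolve(list(pattern), mode)
                assert r.value == want, (pattern, mode)
                if want is None:
                    assert r.action == "tie-NA"

    def test_monotone_in_agreeing_votes(self):
        """Adding a vote for the current winner never changes the outcome."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            k = int(rng.integers(1, 6))
            values = [str(rng.integers(3)) for _ in range(k)]
            r = majority_resolve(_group(values))
            if r.value is None:
                continue
            r2 = majority_resolve(_group(values + [r.value]))
            assert r2.value == r.value


class TestInvariantPolicy:
    CONFIG = HarmonizationConfig(
        attributes=[
            AttributeSpec(name="sex", structure="single", source_fields=["sex"]),
            AttributeSpec(
                name="disease_stage", structure="single", source_fields=["stage"]
            ),
        ],
        invariant_attributes=["sex", "ancestry"],
    )

    def test_listed_attributes_permitted(self):
        assert restrict_to_invariant(self.CONFIG) == ["sex", "ancestry"]
        t = _sex_table([("p", "1", "M"), ("p", "2", "F")])
        resolved, _ = resolve_conflicts(t, "sex", self.CONFIG)
        assert resolved is not None

    def test_dynamic_attribute_refused(self):
        t = _sex_table([("p", "1", "M")])
        with pytest.raises(InvariantPolicyError, match="disease_stage"):
            resolve_conflicts(t, "disease_stage", self.CONFIG)

    def test_empty_invariant_list_refuses_everything(self):
        cfg = self.CONFIG.model_copy(update={"invariant_attributes": []})
        t = _sex_table([("p", "1", "M")])
        with pytest.raises(InvariantPolicyError):
            resolve_conflicts(t, "sex", cfg)


class TestSystematicErrorReport:
    @staticmethod
    def _issues(spread: dict[str, int]) -> list[ValidationIssue]:
        out = []
        for study, n in spread.items():
            for i in range(n):
                out.append(
                    ValidationIssue(
                        kind=IssueKind.CONFLICT,
                        severity=Severity.WARNING,
                        curation_id=f"{study}:p{i}:s",
                        attribute="sex",
                        observed="F",
                    )
                )
        return out

    def test_single_study_dominates(self):
        others = {f"other_{i}": 2 for i in range(17)}  # 34 spread elsewhere
        rep = systematic_error_report(
            self._issues({"luad_msk_npjpo_2021": 303, **others}), threshold=0.5
        )
        assert rep.total == 337
        assert rep.flagged == ["luad_msk_npjpo_2021"]
        assert rep.shares["luad_msk_npjpo_2021"] == pytest.approx(303 / 337)

    def test_uniform_spread_flags_nothing(self):
        rep = systematic_error_report(
            self._issues({f"s{i}": 5 for i in range(10)}), threshold=0.5
        )
        assert rep.flagged == []

    def test_zero_discrepancies(self):
        rep = systematic_error_report([], threshold=0.5)
        assert rep.total == 0 and rep.counts == {} and rep.flagged == []

    def test_threshold_must_be_a_fraction(self):
        with pytest.raises(ValueError):
            systematic_error_report([], threshold=0)

    def test_conflict_groups_attribute_minority_votes(self):
        g = ConflictGroup(
            "p",
            "sex",
            [("M", "a:p:1"), ("M", "b:p:2"), ("F", "c:p:3")],
        )
        rep = systematic_error_report([g], threshold=0.5)
        assert rep.counts == {"c": 1}


class TestApplyResolutions:
    def test_reapplication_is_identity(self):
        t = _sex_table([("p", "1", "M"), ("p", "2", "M"), ("p", "3", "F")])
        r = majority_resolve(find_conflicts(t, "sex")[0])
        once = apply_resolutions(t, [r])
        twice = apply_resolutions(once, [r])
        assert once.data.equals(twice.data)

    def test_empty_resolution_list_is_noop(self):
        t = _sex_table([("p", "1", "M")])
        assert apply_resolutions(t, []).data.equals(t.data)

    def test_only_affected_cells_change(self):
        t = _sex_table([("p", "1", "M"), ("p", "2", "M"), ("p", "3", "F"),
                        ("q", "1", "F")])
        r = majority_resolve(find_conflicts(t, "sex")[0])
        out = apply_resolutions(t, [r])
        for i, cid in enumerate(t.data["curation_id"]):
            if cid in r.affected:
                assert out.data.at[i, "curated_sex"] == "M"
            else:
                assert out.data.at[i, "curated_sex"] == t.data.at[i, "curated_sex"]

    def test_conflicting_resolutions_rejected(self):
        from metaharm.conflicts import Resolution

        t = _sex_table([("p", "1", "M")])
        r1 = Resolution("s:p", "sex", "M", "majority-corrected", ["s:p:1"])
        r2 = Resolution("s:p", "sex", "F", "majority-corrected", ["s:p:1"])
        with pytest.raises(ValueError, match="conflicting"):
            apply_resolutions(t, [r1, r2])

    def test_provenance_note_records_action_and_old_value(self):
        t = _sex_table([("p", "1", "M"), ("p", "2", "M"), ("p", "3", "F")])
        r = majority_resolve(find_conflicts(t, "sex")[0])
        out = apply_resolutions(t, [r])
        note = out.data.loc[2, "curated_sex_resolution"]
        assert note == "majority-corrected:was=F"


def test_golden_flip_recovery_enumeration():
    """Exhaustive flip patterns for k <= 5: recovery iff flips stay a
    strict minority; realized ties always end as NA."""
    for k in range(2, 6):
        for n_flips in range(k + 1):
            values = ["F"] * n_flips + ["M"] * (k - n_flips)
            g = _group(values)
            if len(set(values)) == 1:
                r = majority_resolve(g)
                assert r.action == "unanimous"
                continue
            r = majority_resolve(g)
            if n_flips < k - n_flips:
                assert r.value == "M"
            elif n_flips == k - n_flips:
                assert r.value is None and r.action == "tie-NA"
            else:
                assert r.value == "F"
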