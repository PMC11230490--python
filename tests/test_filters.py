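"""Exclusion rules on hand-built fixtures and on planted aberrant agents."""

import pandas as pd
import pytest

from riskamb.filters import (
    apply_exclusions,
    filter_age_gap,
    filter_catch_trials,
    filter_duplicate_ids,
    filter_never_uncertain,
)
from conftest import make_choices


def roster(rows):
    return pd.DataFrame(rows, columns=["participant_id", "phase", "age",
                                       "mturk_like_id"])


class TestDuplicateIds:
    def test_two_of_three_sharing_an_id_are_both_excluded(self):
        r = roster([("A", 1, 30, "W1"), ("B", 1, 40, "W2"), ("C", 1, 50, "W1")])
        out = filter_duplicate_ids(r)
        assert set(out["participant_id"]) == {"A", "C"}
        assert len(out) == 2

    def test_all_unique_ids_fire_nothing(self):
        r = roster([("A", 1, 30, "W1"), ("B", 1, 40, "W2")])
        assert filter_duplicate_ids(r).empty

    def test_planted_duplicates_are_flagged(self, aberrant_cohort):
        out = filter_duplicate_ids(aberrant_cohort["participants"])
        # 2 duplicate agents each drag in their id-sharing partner
        assert len(out) >= 2 * 2


class TestAgeGap:
    @pytest.mark.parametrize(
        "age1,age2,excluded",
        [(50, 53, True), (50, 52, False), (50, 50, False), (53, 50, True)],
        ids=["gap3", "gap2-boundary", "gap0", "gap3-reversed"],
    )
    def test_strict_two_year_threshold(self, age1, age2, excluded):
        r = roster([("A", 1, age1, "W1"), ("A", 2, age2, "W1")])
        out = filter_age_gap(r)
        assert (len(out) == 1) is excluded
        if excluded:
            assert out.iloc[0]["phase"] == 2  # only the follow-up is dropped

    def test_phase_one_only_participants_are_untouched(self):
        r = roster([("A", 1, 50, "W1")])
        assert filter_age_gap(r).empty


class TestCatchTrials:
    def _choices(self, trialset, n_uncertain):
        mon = trialset.domain("monetary")
        chose = [t.is_reference_equal and n_uncertain > 0 for t in mon]
        # flip exactly n_uncertain catch trials to lottery
        out, fired = [], 0
        for t in mon:
            if t.is_reference_equal and fired < n_uncertain:
                out.append(True)
                fired += 1
            else:
                out.append(False)
        return make_choices(mon, out)

    def test_four_of_seven_fires(self, trialset):
        out = filter_catch_trials(self._choices(trialset, 4), trialset)
        assert len(out) == 1
        assert out.iloc[0]["domain"] == "monetary"

    def test_three_of_seven_does_not_fire(self, trialset):
        assert filter_catch_trials(self._choices(trialset, 3), trialset).empty

    def test_zero_of_seven_retained(self, trialset):
        assert filter_catch_trials(self._choices(trialset, 0), trialset).empty

    def test_no_catch_trials_is_an_error(self, trialset):
        mon = [t for t in trialset.domain("monetary") if not t.is_reference_equal]
        with pytest.raises(ValueError):
            filter_catch_trials(make_choices(mon, [False] * len(mon)), trialset)


class TestNeverUncertain:
    def test_all_reference_chooser_is_flagged(self, trialset):
        mon = trialset.domain("monetary")
        out = filter_never_uncertain(make_choices(mon, [False] * 49), trialset)
        assert len(out) == 1

    def test_single_lottery_choice_is_retained(self, trialset):
        mon = trialset.domain("monetary")
        value_idx = next(
            i for i, t in enumerate(mon) if not t.is_reference_equal
        )
        chose = [i == value_idx for i in range(49)]
        assert filter_never_uncertain(make_choices(mon, chose), trialset).empty


class TestApplyExclusions:
    def test_planted_aberrants_fire_their_rules(self, aberrant_cohort, trialset):
        out = apply_exclusions(
            aberrant_cohort["choices"],
            aberrant_cohort["participants"],
            trialset,
        )
        counts = out.counts()
        # 40 agents: 4 catch_failers, 4 never_uncertain, 2 duplicate pairs, 2 age_gap
        assert counts["duplicate_id"] >= 4
        assert counts["age_gap"] >= 2
        # catch failers fire per phase x domain: 4 agents x 2 x 2
        assert counts["catch_trial"] >= 16
        assert counts["never_uncertain"] >= 16

    def test_never_uncertain_units_stay_in_analysis_set(self, aberrant_cohort,
                                                        trialset):
        out = apply_exclusions(
            aberrant_cohort["choices"],
            aberrant_cohort["participants"],
            trialset,
        )
        never = set(
            out.report[out.report["rule"] == "never_uncertain"]["participant_id"]
        )
        assert never
        assert never <= set(out.analysis_choices["participant_id"])
        assert never.isdisjoint(set(out.modeling_choices["participant_id"]))

    def test_cohort_without_aberrants_fires_only_behavioural_rules(
        self, small_cohort, trialset
    ):
        """No planted aberrants: the roster rules stay silent, and any
        catch-rule firings (softmax agents do sometimes pick the dominated
        catch lottery) exactly match a direct application of the rule."""
        out = apply_exclusions(
            small_cohort["choices"], small_cohort["participants"], trialset
        )
        assert set(out.report["rule"]) <= {"catch_trial", "never_uncertain"}
        direct = filter_catch_trials(small_cohort["choices"], trialset)
        fired = out.report[out.report["rule"] == "catch_trial"]
        assert len(fired) == len(direct)
        kept_units = set(
            map(tuple, out.analysis_choices[["participant_id", "phase"]]
                .drop_duplicates().to_numpy())
        )
        for _, row in direct.iterrows():
            unit_choices = out.analysis_choices[
                (out.analysis_choices["participant_id"] == row["participant_id"])
                & (out.analysis_choices["phase"] == row["phase"])
            ]
            domain_prefix = row["domain"][:3]
            assert not unit_choices["trial_id"].str.startswith(domain_prefix).any()
        assert kept_units  # most units survive

    def test_filters_idempotent(self, aberrant_cohort, trialset):
        first = apply_exclusions(
            aberrant_cohort["choices"],
            aberrant_cohort["participants"],
            trialset,
        )
        second = apply_exclusions(
            first.analysis_choices, aberrant_cohort["participants"], trialset
        )
        assert second.counts().get("catch_trial", 0) == 0
        pd.testing.assert_frame_equal(
            first.modeling_choices.reset_index(drop=True),
            second.modeling_choices.reset_index(drop=True),
        )
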