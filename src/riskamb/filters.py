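"""Participant exclusion rules.

Four rules, applied before analysis:

* duplicate_id — participants sharing an MTurk-like worker id are removed
  entirely (all phases, both domains).
* age_gap — phase-2 data are removed when the self-reported age differs
  from phase 1 by strictly more than the threshold (2 years by default;
  the study interval is only 9 months).
* catch_trial — within a participant x phase x domain, the domain's data
  are removed when the reference-equal (catch) lottery was chosen on
  strictly more than 50% of catch trials.
* never_uncertain — within a participant x phase x domain, the unit is
  excluded from model *fitting* (not from model-free summaries) when the
  lottery was never chosen: such data carry no likelihood information.

Each rule returns tidy exclusion rows; `apply_exclusions` combines them and
derives the retained analysis / modelling sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .trials import TrialSet

EXCLUSION_COLUMNS = ["rule", "participant_id", "phase", "domain", "detail"]

AGE_GAP_THRESHOLD_YEARS = 2
CATCH_CHOICE_LIMIT = 0.5


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(columns=EXCLUSION_COLUMNS)


def filter_duplicate_ids(participants: pd.DataFrame) -> pd.DataFrame:
    """Exclude every participant whose worker id is shared with another."""
    phase1 = participants[participants["phase"] == 1]
    counts = phase1.groupby("mturk_like_id")["participant_id"].nunique()
    dup_workers = set(counts[counts > 1].index)
    rows = [
        {
            "rule": "duplicate_id",
            "participant_id": pid,
            "phase": "all",
            "domain": "all",
            "detail": f"shared worker id {wid}",
        }
        for pid, wid in phase1[["participant_id", "mturk_like_id"]]
        .drop_duplicates()
        .itertuples(index=False)
        if wid in dup_workers
    ]
    return pd.DataFrame(rows, columns=EXCLUSION_COLUMNS) if rows else _empty_report()


def filter_age_gap(
    participants: pd.DataFrame, threshold_years: int = AGE_GAP_THRESHOLD_YEARS
) -> pd.DataFrame:
    """Exclude phase-2 data when |age2 - age1| strictly exceeds the threshold."""
    wide = participants.pivot_table(
        index="participant_id", columns="phase", values="age", aggfunc="first"
    )
    if 1 not in wide.columns or 2 not in wide.columns:
        return _empty_report()
    both = wide.dropna(subset=[1, 2])
    gaps = (both[2] - both[1]).abs()
    rows = [
        {
            "rule": "age_gap",
            "participant_id": pid,
            "phase": 2,
            "domain": "all",
            "detail": f"age gap {int(gap)} > {threshold_years}",
        }
        for pid, gap in gaps[gaps > threshold_years].items()
    ]
    return pd.DataFrame(rows, columns=EXCLUSION_COLUMNS) if rows else _empty_report()


def _merged(choices: pd.DataFrame, trials: TrialSet | pd.DataFrame) -> pd.DataFrame:
    tf = trials.to_frame() if isinstance(trials, TrialSet) else trials
    return choices.merge(
        tf[["trial_id", "domain", "is_reference_equal"]], on="trial_id", how="left"
    )


def filter_catch_trials(
    choices: pd.DataFrame, trials: TrialSet | pd.DataFrame
) -> pd.DataFrame:
    """Exclude a participant x phase x domain with > 50% uncertain catch choices."""
    merged = _merged(choices, trials)
    catch = merged[merged["is_reference_equal"]]
    if catch.empty:
        raise ValueError("no reference-equal catch trials found in any domain")
    grouped = catch.groupby(["participant_id", "phase", "domain"])["chose_lottery"]
    stats = grouped.agg(["sum", "count"])
    if (stats["count"] == 0).any():
        raise ValueError("a participant/domain cell has zero catch trials")
    bad = stats[stats["sum"] / stats["count"] > CATCH_CHOICE_LIMIT]
    rows = [
        {
            "rule": "catch_trial",
            "participant_id": pid,
            "phase": phase,
            "domain": domain,
            "detail": f"chose uncertain catch {int(s)}/{int(c)}",
        }
        for (pid, phase, domain), (s, c) in bad.iterrows()
    ]
    return pd.DataFrame(rows, columns=EXCLUSION_COLUMNS) if rows else _empty_report()


def filter_never_uncertain(
    choices: pd.DataFrame, trials: TrialSet | pd.DataFrame
) -> pd.DataFrame:
    """Flag participant x phase x domain cells with zero lottery choices.

    These units cannot be fitted (the likelihood is maximized at a
    degenerate boundary) but remain valid for model-free summaries.
    """
    merged = _merged(choices, trials)
    value = merged[~merged["is_reference_equal"]]
    grouped = value.groupby(["participant_id", "phase", "domain"])["chose_lottery"]
    totals = grouped.sum()
    rows = [
        {
            "rule": "never_uncertain",
            "participant_id": pid,
            "phase": phase,
            "domain": domain,
            "detail": "never chose the uncertain option",
        }
        for (pid, phase, domain), s in totals.items()
        if s == 0
    ]
    return pd.DataFrame(rows, columns=EXCLUSION_COLUMNS) if rows else _empty_report()


@dataclass
class ExclusionOutcome:
    """Exclusion rows plus the derived retained sets.

    ``analysis_choices`` feed model-free summaries (duplicate-id, age-gap
    and catch-trial rules applied); ``modeling_choices`` additionally drop
    never-uncertain units.
    """

    report: pd.DataFrame
    analysis_choices: pd.DataFrame
    modeling_choices: pd.DataFrame

    def counts(self) -> pd.Series:
        return self.report.groupby("rule").size()


def apply_exclusions(
    choices: pd.DataFrame,
    participants: pd.DataFrame,
    trials: TrialSet | pd.DataFrame,
) -> ExclusionOutcome:
    """Run all four rules and materialize the retained choice sets.

    The final retained sets are order-insensitive: participant-scoped rules
    (duplicate id, age gap) are applied first, then the domain-scoped rules
    are evaluated on what remains — but since catch/never-uncertain firing
    depends only on a unit's own rows, any order yields the same result.
    """
    dup = filter_duplicate_ids(participants)
    age = filter_age_gap(participants)

    keep = choices.copy()
    keep = keep[~keep["participant_id"].isin(set(dup["participant_id"]))]
    age_excluded = set(age["participant_id"])
    keep = keep[~((keep["phase"] == 2) & keep["participant_id"].isin(age_excluded))]

    cols = list(choices.columns)
    catch = filter_catch_trials(keep, trials) if not keep.empty else _empty_report()
    merged = _merged(keep[cols], trials)
    bad_units = set(
        map(tuple, catch[["participant_id", "phase", "domain"]].to_numpy())
    )
    unit = list(zip(merged["participant_id"], merged["phase"], merged["domain"]))
    analysis = merged[[u not in bad_units for u in unit]]

    never = (
        filter_never_uncertain(analysis[cols], trials)
        if not analysis.empty
        else _empty_report()
    )
    never_units = set(
        map(tuple, never[["participant_id", "phase", "domain"]].to_numpy())
    )
    unit = list(zip(analysis["participant_id"], analysis["phase"], analysis["domain"]))
    modeling = analysis[[u not in never_units for u in unit]]

    report = pd.concat([dup, age, catch, never], ignore_index=True)
    return ExclusionOutcome(
        report=report,
        analysis_choices=analysis[cols].reset_index(drop=True),
        modeling_choices=modeling[cols].reset_index(drop=True),
    )
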