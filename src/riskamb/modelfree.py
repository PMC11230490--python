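"""Model-free attitude summaries from raw choice proportions.

Per participant x phase x domain:

* proportion of lottery choices grouped by outcome level (collapsing
  uncertainty levels) and by uncertainty level (collapsing outcomes);
* risk attitude = unweighted mean proportion over the three risk levels;
* corrected ambiguity proportion = proportion at each ambiguity level
  minus the proportion at 50% risk.  An ambiguity-neutral decision-maker
  treats every ambiguous lottery as a 50% risky one, so 0 marks
  neutrality and negative values mark aversion;
* ambiguity attitude = mean corrected proportion over the three levels.

Catch (reference-equal) trials are manipulation checks and are excluded
from every proportion.  Empty cells propagate as missing (NaN), never as 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trials import AMBIGUITY_LEVELS, NON_REFERENCE_ORDINALS, RISK_LEVELS, TrialSet

MODELFREE_COLUMNS = (
    ["participant_id", "phase", "domain"]
    + [f"prop_outcome_{o}" for o in NON_REFERENCE_ORDINALS]
    + [f"prop_risk_{int(p * 100)}" for p in RISK_LEVELS]
    + [f"prop_amb_{int(a * 100)}" for a in AMBIGUITY_LEVELS]
    + [f"corrected_amb_{int(a * 100)}" for a in AMBIGUITY_LEVELS]
    + ["risk_attitude", "ambiguity_attitude"]
)


def _value_trials(choices: pd.DataFrame, trials: TrialSet | pd.DataFrame) -> pd.DataFrame:
    tf = trials.to_frame() if isinstance(trials, TrialSet) else trials
    merged = choices.merge(
        tf[
            [
                "trial_id",
                "domain",
                "uncertainty_type",
                "win_probability",
                "ambiguity_level",
                "outcome_ordinal",
                "is_reference_equal",
            ]
        ],
        on="trial_id",
        how="left",
    )
    if merged["domain"].isna().any():
        raise ValueError("choices reference trials missing from the trial set")
    return merged[~merged["is_reference_equal"]]


def _prop(df: pd.DataFrame) -> float:
    return float(df["chose_lottery"].mean()) if len(df) else np.nan


def choice_proportions(
    choices: pd.DataFrame, trials: TrialSet | pd.DataFrame
) -> pd.DataFrame:
    """One summary row per participant x phase x domain (see module doc)."""
    value = _value_trials(choices, trials)
    rows = []
    for (pid, phase, domain), g in value.groupby(
        ["participant_id", "phase", "domain"], sort=True
    ):
        row: dict = {"participant_id": pid, "phase": phase, "domain": domain}
        for o in NON_REFERENCE_ORDINALS:
            row[f"prop_outcome_{o}"] = _prop(g[g["outcome_ordinal"] == o])
        risk = g[g["uncertainty_type"] == "risk"]
        for p in RISK_LEVELS:
            row[f"prop_risk_{int(p * 100)}"] = _prop(
                risk[risk["win_probability"] == p]
            )
        amb = g[g["uncertainty_type"] == "ambiguity"]
        for a in AMBIGUITY_LEVELS:
            row[f"prop_amb_{int(a * 100)}"] = _prop(amb[amb["ambiguity_level"] == a])
        risk_props = [row[f"prop_risk_{int(p * 100)}"] for p in RISK_LEVELS]
        row["risk_attitude"] = (
            float(np.mean(risk_props)) if not np.isnan(risk_props).any() else np.nan
        )
        rows.append(row)
    summary = pd.DataFrame(rows)
    return corrected_ambiguity_proportion(summary)


def corrected_ambiguity_proportion(summary: pd.DataFrame) -> pd.DataFrame:
    """Add corrected ambiguity columns and the mean ambiguity attitude.

    corrected(a) = prop_ambiguity(a) - prop_risk(50%).  A missing 50%-risk
    cell makes the whole correction incomputable (NaN) for that unit.
    """
    summary = summary.copy()
    ref = summary["prop_risk_50"]
    for a in AMBIGUITY_LEVELS:
        lvl = int(a * 100)
        summary[f"corrected_amb_{lvl}"] = summary[f"prop_amb_{lvl}"] - ref
    corrected = summary[[f"corrected_amb_{int(a * 100)}" for a in AMBIGUITY_LEVELS]]
    summary["ambiguity_attitude"] = corrected.mean(axis=1, skipna=False)
    return summary[[c for c in MODELFREE_COLUMNS if c in summary.columns]]
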