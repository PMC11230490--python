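"""Reading, validating and writing the study tables.

The canonical on-disk form is four UTF-8 CSV files with mandatory headers:
trials.csv, choices.csv, ratings.csv, participants.csv (truth.csv is an
optional fifth, present only for synthetic cohorts).  Booleans are the
literals ``true``/``false``; probabilities are decimals in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import (
    CHOICES_CSV_COLUMNS,
    PARTICIPANTS_CSV_COLUMNS,
    RATINGS_CSV_COLUMNS,
)
from .trials import TRIAL_CSV_COLUMNS, TrialSet, trialset_from_frame

log = logging.getLogger(__name__)

_SCHEMAS = {
    "trials": TRIAL_CSV_COLUMNS,
    "choices": CHOICES_CSV_COLUMNS,
    "ratings": RATINGS_CSV_COLUMNS,
    "participants": PARTICIPANTS_CSV_COLUMNS,
}

_BOOL_MAP = {"true": True, "false": False, "True": True, "False": False,
             True: True, False: False}


@dataclass
class StudyDataset:
    """Validated, analysis-ready bundle of the study tables."""

    trials: TrialSet
    choices: pd.DataFrame
    ratings: pd.DataFrame
    participants: pd.DataFrame
    truth: pd.DataFrame | None = None
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def trials_frame(self) -> pd.DataFrame:
        return self.trials.to_frame()


def _parse_bool(series: pd.Series, table: str, column: str) -> pd.Series:
    try:
        return series.map(_BOOL_MAP).astype(bool)
    except Exception as exc:  # unmappable literal
        raise ValueError(f"{table}.{column}: unparseable boolean value") from exc


def _check_columns(df: pd.DataFrame, table: str) -> None:
    missing = set(_SCHEMAS[table]) - set(df.columns)
    if missing:
        raise ValueError(f"{table}: missing columns {sorted(missing)}")


def load_dataset(
    paths: dict[str, str | Path], strict: bool = True
) -> StudyDataset:
    """Load and cross-validate the study tables.

    ``paths`` maps table name (trials, choices, ratings, participants and
    optionally truth) to a CSV path.  In strict mode any choice/rating row
    referencing an unknown trial or participant raises with the offending
    row index; in lax mode such rows are dropped and counted.
    """
    for key in ("trials", "choices", "ratings", "participants"):
        if key not in paths:
            raise ValueError(f"missing path for table {key!r}")

    frames = {}
    for key in _SCHEMAS:
        df = pd.read_csv(paths[key], float_precision="round_trip")
        _check_columns(df, key)
        frames[key] = df
    frames["trials"]["is_reference_equal"] = _parse_bool(
        frames["trials"]["is_reference_equal"], "trials", "is_reference_equal"
    )
    frames["choices"]["chose_lottery"] = _parse_bool(
        frames["choices"]["chose_lottery"], "choices", "chose_lottery"
    )

    bad_phase = ~frames["choices"]["phase"].isin([1, 2])
    if bad_phase.any():
        raise ValueError(
            f"choices: phase outside {{1,2}} at rows {list(frames['choices'].index[bad_phase][:5])}"
        )

    trialset = trialset_from_frame(frames["trials"])
    known_trials = set(t.trial_id for t in trialset)
    known_participants = set(frames["participants"]["participant_id"].astype(str))

    dropped: dict[str, int] = {}

    def referential(df: pd.DataFrame, table: str, column: str, known: set) -> pd.DataFrame:
        orphan = ~df[column].astype(str).isin(known)
        if orphan.any():
            if strict:
                row = int(df.index[orphan][0])
                raise ValueError(
                    f"{table}: unknown {column} {df.loc[row, column]!r} at row {row}"
                )
            dropped[f"{table}.{column}"] = int(orphan.sum())
            log.warning(
                "%s: dropped %d rows with unknown %s", table, orphan.sum(), column
            )
            df = df.loc[~orphan].reset_index(drop=True)
        return df

    choices = referential(frames["choices"], "choices", "trial_id", known_trials)
    choices = referential(choices, "choices", "participant_id", known_participants)
    ratings = referential(
        frames["ratings"], "ratings", "participant_id", known_participants
    )

    truth = None
    if "truth" in paths and paths["truth"] is not None:
        truth = pd.read_csv(paths["truth"])

    return StudyDataset(
        trials=trialset,
        choices=choices,
        ratings=ratings,
        participants=frames["participants"],
        truth=truth,
        dropped=dropped,
    )


def write_dataset(dataset: StudyDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the canonical CSV files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    tables = {
        "trials": dataset.trials_frame,
        "choices": dataset.choices,
        "ratings": dataset.ratings,
        "participants": dataset.participants,
    }
    if dataset.truth is not None:
        tables["truth"] = dataset.truth
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        write_table(df, path)
        written[name] = path
    return written


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV writer with the canonical boolean/encoding conventions."""
    df = df.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].map({True: "true", False: "false"})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    return path
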