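"""Two-domain lottery task design.

Participants choose, on every trial, between a certain reference outcome
(ordinal value 1: $500 / "slight improvement") and a lottery that pays a
higher-ranked outcome with some probability and the null outcome (ordinal 0)
otherwise.  Uncertainty comes in two flavours:

* risk — the winning probability is fully known (25%, 50% or 75%);
* ambiguity — the probability display is partly occluded; the occluded
  fraction A is 24%, 50% or 74% and the midpoint probability is 50%.

The default set has 98 trials, 49 per domain, of which 7 per domain are
reference-equal "catch" trials (the lottery pays exactly the reference
outcome, so choosing it is never advantageous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DOMAINS = ("monetary", "medical")
RISK_LEVELS = (0.25, 0.50, 0.75)
AMBIGUITY_LEVELS = (0.24, 0.50, 0.74)
AMBIGUOUS_WIN_PROBABILITY = 0.50
COLORS = ("red", "blue")

#: ordinal -> label, per domain; ordinal 0 is the null outcome, ordinal 1 the
#: certain reference option.
OUTCOME_LABELS: dict[str, tuple[str, ...]] = {
    "monetary": ("$0", "$500", "$800", "$1200", "$2500"),
    "medical": (
        "no effect",
        "slight improvement",
        "moderate improvement",
        "major improvement",
        "recovery",
    ),
}

REFERENCE_ORDINAL = 1
NON_REFERENCE_ORDINALS = (2, 3, 4)

TRIAL_CSV_COLUMNS = [
    "trial_id",
    "domain",
    "uncertainty_type",
    "win_probability",
    "ambiguity_level",
    "outcome_ordinal",
    "outcome_label",
    "win_color",
    "is_reference_equal",
]


@dataclass(frozen=True)
class OutcomeLevel:
    """One rung of a domain's ordered outcome ladder."""

    domain: str
    ordinal_value: int
    label: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if not 0 <= self.ordinal_value <= 4:
            raise ValueError("ordinal_value must be in 0..4")


@dataclass(frozen=True)
class Trial:
    """One lottery-vs-reference decision problem."""

    trial_id: str
    domain: str
    uncertainty_type: str  # "risk" | "ambiguity"
    win_probability: float
    ambiguity_level: float
    lottery_outcome: OutcomeLevel
    win_color: str

    def __post_init__(self) -> None:
        if self.uncertainty_type == "risk":
            if self.ambiguity_level != 0.0:
                raise ValueError("risk trials have ambiguity_level 0")
            if self.win_probability not in RISK_LEVELS:
                raise ValueError(f"bad risk level {self.win_probability}")
        elif self.uncertainty_type == "ambiguity":
            if self.win_probability != AMBIGUOUS_WIN_PROBABILITY:
                raise ValueError("ambiguous trials have win_probability 0.5")
            if self.ambiguity_level not in AMBIGUITY_LEVELS:
                raise ValueError(f"bad ambiguity level {self.ambiguity_level}")
        else:
            raise ValueError(f"unknown uncertainty_type {self.uncertainty_type!r}")
        if self.lottery_outcome.ordinal_value < 1:
            raise ValueError("lottery winning outcome must have ordinal >= 1")
        if self.win_color not in COLORS:
            raise ValueError(f"unknown color {self.win_color!r}")

    @property
    def is_reference_equal(self) -> bool:
        return self.lottery_outcome.ordinal_value == REFERENCE_ORDINAL

    @property
    def uncertainty_level(self) -> float:
        """The manipulated level: P for risk, A for ambiguity."""
        return (
            self.win_probability
            if self.uncertainty_type == "risk"
            else self.ambiguity_level
        )


def outcome_levels(domain: str) -> tuple[OutcomeLevel, ...]:
    """All five ordered outcome levels of a domain."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    return tuple(
        OutcomeLevel(domain, i, lab) for i, lab in enumerate(OUTCOME_LABELS[domain])
    )


def reference_option(domain: str) -> OutcomeLevel:
    """The certain option: ordinal 1 ($500 / slight improvement)."""
    return outcome_levels(domain)[REFERENCE_ORDINAL]


@dataclass(frozen=True)
class TrialSet:
    """An ordered, immutable collection of trials plus the seed that built it."""

    trials: tuple[Trial, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def domain(self, domain: str) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.domain == domain)

    def by_id(self) -> dict[str, Trial]:
        return {t.trial_id: t for t in self.trials}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trial_id": t.trial_id,
                "domain": t.domain,
                "uncertainty_type": t.uncertainty_type,
                "win_probability": t.win_probability,
                "ambiguity_level": t.ambiguity_level,
                "outcome_ordinal": t.lottery_outcome.ordinal_value,
                "outcome_label": t.lottery_outcome.label,
                "win_color": t.win_color,
                "is_reference_equal": t.is_reference_equal,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS)


def _uncertainty_grid() -> list[tuple[str, float, float]]:
    """(uncertainty_type, win_probability, ambiguity_level) for the 6 levels."""
    grid = [("risk", p, 0.0) for p in RISK_LEVELS]
    grid += [("ambiguity", AMBIGUOUS_WIN_PROBABILITY, a) for a in AMBIGUITY_LEVELS]
    return grid


def build_default_trialset(seed: int) -> TrialSet:
    """Construct the full 98-trial task (49 per domain, 7 catch each).

    Per domain the layout is: the complete crossing of the 6 uncertainty
    levels with the 3 non-reference outcomes and both winning colors
    (36 trials), 6 further value trials (one per uncertainty level, outcome
    cycling through the non-reference ordinals, color drawn from the seed),
    and 7 reference-equal catch trials (one per uncertainty level plus an
    extra at 50% risk carrying the opposite color).  Deterministic given
    ``seed``; the (uncertainty, outcome) composition is seed-invariant and
    only the colors of the non-crossed trials move.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for domain in DOMAINS:
        levels = outcome_levels(domain)
        grid = _uncertainty_grid()
        counter = 0

        def add(utype, p, a, ordinal, color):
            nonlocal counter
            counter += 1
            trials.append(
                Trial(
                    trial_id=f"{domain[:3]}-{counter:03d}",
                    domain=domain,
                    uncertainty_type=utype,
                    win_probability=p,
                    ambiguity_level=a,
                    lottery_outcome=levels[ordinal],
                    win_color=color,
                )
            )

        # 36 fully crossed value trials
        for utype, p, a in grid:
            for ordinal in NON_REFERENCE_ORDINALS:
                for color in COLORS:
                    add(utype, p, a, ordinal, color)
        # 6 extra value trials, one per uncertainty level; colors seeded but
        # balanced (3 red / 3 blue per domain)
        extra_colors = rng.permutation([0, 0, 0, 1, 1, 1])
        for i, (utype, p, a) in enumerate(grid):
            ordinal = NON_REFERENCE_ORDINALS[i % len(NON_REFERENCE_ORDINALS)]
            add(utype, p, a, ordinal, COLORS[extra_colors[i]])
        # 7 catch trials: one per level + one extra at 50% risk
        catch_colors = rng.permutation([0, 0, 0, 1, 1, 1])
        for i, (utype, p, a) in enumerate(grid):
            add(utype, p, a, REFERENCE_ORDINAL, COLORS[catch_colors[i]])
        extra_idx = grid.index(("risk", 0.50, 0.0))
        add("risk", 0.50, 0.0, REFERENCE_ORDINAL, COLORS[1 - catch_colors[extra_idx]])
    return TrialSet(trials=tuple(trials), seed=int(seed))


def trialset_from_frame(df: pd.DataFrame, seed: int = 0) -> TrialSet:
    """Rebuild a :class:`TrialSet` from its CSV representation."""
    missing = set(TRIAL_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    trials = []
    for row in df.itertuples(index=False):
        trials.append(
            Trial(
                trial_id=str(row.trial_id),
                domain=row.domain,
                uncertainty_type=row.uncertainty_type,
                win_probability=float(row.win_probability),
                ambiguity_level=float(row.ambiguity_level),
                lottery_outcome=OutcomeLevel(
                    row.domain, int(row.outcome_ordinal), str(row.outcome_label)
                ),
                win_color=row.win_color,
            )
        )
    return TrialSet(trials=tuple(trials), seed=int(seed))
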