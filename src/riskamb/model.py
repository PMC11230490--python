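"""Subjective-value models and the softmax choice rule.

The valuation step discounts the lottery's winning probability linearly by
the ambiguity level and raises the outcome value to a power:

    SV = (P - beta * A / 2) * value**alpha

where P is the winning probability (0.25/0.5/0.75 risky, 0.5 ambiguous,
1 for the certain option), A the ambiguity level (0 unless ambiguous),
alpha > 0 the utility curvature (smaller alpha = more risk averse) and
beta the ambiguity attitude (beta > 0 = ambiguity averse; under beta = 0
every ambiguous lottery is treated exactly as a 50% risky one).

Two variants differ only in ``value``: the *ordinal* model uses the
outcome's rank (0..4, null outcome worth 0), the *rating* model uses the
participant's own 0-10 pleasantness rating of that outcome.

The choice step is a logistic (softmax) rule on the subjective-value
difference with an individual inverse-temperature gamma > 0:

    P_choose_lottery = 1 / (1 + exp(-gamma * (SV_lottery - SV_certain)))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .trials import REFERENCE_ORDINAL, Trial

#: probability clip for the likelihood, avoids -inf at saturation
LIKELIHOOD_EPS = 1e-9

MODEL_VARIANTS = ("ordinal", "rating")


@dataclass(frozen=True)
class AgentParams:
    """(alpha, beta, gamma) for one participant x domain x phase."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError("alpha must be positive and finite")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be positive and finite")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass(frozen=True)
class ModelSpec:
    """Which value source feeds the power utility.

    ``ratings`` maps outcome ordinal -> value and is required for the
    rating variant (a complete map over the domain's outcome levels, from
    the participant being modelled).  The ordinal variant ignores it.
    """

    variant: str = "ordinal"
    ratings: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")

    def value_of(self, ordinal: int) -> float:
        if self.variant == "ordinal":
            return float(ordinal)
        if self.ratings is None or ordinal not in self.ratings:
            raise ValueError(
                f"rating variant needs a rating for ordinal {ordinal}"
            )
        return float(self.ratings[ordinal])


def subjective_value(
    win_probability, ambiguity_level, value, alpha: float, beta: float
):
    """SV = (P - beta*A/2) * value**alpha.  Vectorized over trials.

    The effective weight P - beta*A/2 is used as-is (it may leave [0, 1]
    for extreme beta); 0**alpha is 0 for alpha > 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("outcome value must be non-negative")
    weight = np.asarray(win_probability, dtype=float) - beta * np.asarray(
        ambiguity_level, dtype=float
    ) / 2.0
    return weight * np.power(value, alpha)


def choice_probability(sv_lottery, sv_certain, gamma: float):
    """Softmax probability of choosing the lottery; overflow-safe."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    diff = np.asarray(sv_lottery, dtype=float) - np.asarray(sv_certain, dtype=float)
    if not np.all(np.isfinite(diff)):
        raise ValueError("subjective values must be finite")
    return expit(gamma * diff)


@dataclass(frozen=True)
class TrialArrays:
    """Design arrays for a block of same-domain trials, for fast likelihoods."""

    win_probability: np.ndarray
    ambiguity_level: np.ndarray
    value: np.ndarray  # lottery winning-outcome value (V or R)
    value_certain: float  # reference value (V or R of ordinal 1)

    @property
    def n_trials(self) -> int:
        return int(self.win_probability.shape[0])


def trial_arrays(trials, model: ModelSpec) -> TrialArrays:
    """Extract (P, A, value) arrays from Trial objects or a trials frame."""
    if isinstance(trials, pd.DataFrame):
        p = trials["win_probability"].to_numpy(dtype=float)
        a = trials["ambiguity_level"].to_numpy(dtype=float)
        ordinals = trials["outcome_ordinal"].to_numpy(dtype=int)
    else:
        trials = list(trials)
        p = np.array([t.win_probability for t in trials], dtype=float)
        a = np.array([t.ambiguity_level for t in trials], dtype=float)
        ordinals = np.array(
            [t.lottery_outcome.ordinal_value for t in trials], dtype=int
        )
    if p.shape[0] == 0:
        raise ValueError("empty trial set")
    value = np.array([model.value_of(o) for o in ordinals], dtype=float)
    return TrialArrays(
        win_probability=p,
        ambiguity_level=a,
        value=value,
        value_certain=model.value_of(REFERENCE_ORDINAL),
    )


def lottery_choice_probabilities(
    arrays: TrialArrays, params: AgentParams | tuple
) -> np.ndarray:
    """P(choose lottery) for every trial in ``arrays``.

    Robust to float overflow at degenerate boundary fits (alpha so large
    that value**alpha is inf): an infinite SV difference saturates the
    logistic, and the inf - inf case is resolved on the log scale, where
    the comparison (P - beta*A/2) * V^alpha vs V_c^alpha is still
    well defined.
    """
    alpha, beta, gamma = (
        (params.alpha, params.beta, params.gamma)
        if isinstance(params, AgentParams)
        else params
    )
    if alpha <= 0 or gamma <= 0:
        raise ValueError("alpha and gamma must be positive")
    with np.errstate(over="ignore", invalid="ignore"):
        sv_l = subjective_value(
            arrays.win_probability, arrays.ambiguity_level, arrays.value, alpha, beta
        )
        sv_c = (1.0) * np.power(arrays.value_certain, alpha)
        z = gamma * (sv_l - sv_c)
        p = expit(z)
    bad = ~np.isfinite(z)
    if np.any(bad):
        weight = (
            arrays.win_probability - beta * arrays.ambiguity_level / 2.0
        )[bad]
        with np.errstate(divide="ignore"):
            log_l = np.log(np.maximum(weight, 0.0)) + alpha * np.log(
                np.maximum(arrays.value[bad], 0.0)
            )
            log_c = alpha * np.log(arrays.value_certain)
        p_bad = np.where(log_l > log_c, 1.0, np.where(log_l < log_c, 0.0, 0.5))
        p_bad = np.where(weight < 0, 0.0, p_bad)  # negative weight: SV_L = -inf
        p = np.asarray(p, dtype=float)
        p[bad] = p_bad
    return p


def negative_log_likelihood(
    params: AgentParams | tuple,
    chose_lottery: np.ndarray,
    arrays: TrialArrays,
) -> float:
    """Bernoulli NLL of the observed choices under the model.

    Probabilities are clipped to [eps, 1-eps] so saturated fits stay finite.
    """
    c = np.asarray(chose_lottery, dtype=float)
    if c.shape[0] == 0:
        raise ValueError("empty choice set")
    if c.shape[0] != arrays.n_trials:
        raise ValueError("choices and trials length mismatch")
    p = lottery_choice_probabilities(arrays, params)
    p = np.clip(p, LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)
    return float(-np.sum(c * np.log(p) + (1.0 - c) * np.log(1.0 - p)))


def nll_closure(chose_lottery: np.ndarray, arrays: TrialArrays):
    """Precompiled NLL as a function of (alpha, beta, gamma).

    Identical arithmetic to :func:`negative_log_likelihood` (same clipping,
    same log calls) with the per-call validation and dispatch hoisted out —
    this is the optimizer's inner loop.
    """
    c = np.asarray(chose_lottery, dtype=float)
    if c.shape[0] != arrays.n_trials or c.shape[0] == 0:
        raise ValueError("choices and trials length mismatch")
    one_minus_c = 1.0 - c
    p_win = arrays.win_probability
    a_level = arrays.ambiguity_level
    value = arrays.value
    v_certain = arrays.value_certain
    lo, hi = LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS

    def nll(alpha: float, beta: float, gamma: float) -> float:
        # overflow at extreme optimizer excursions saturates the logistic
        # and is absorbed by the clip; a NaN objective marks a failed start
        with np.errstate(over="ignore", invalid="ignore"):
            sv_l = (p_win - beta * a_level / 2.0) * np.power(value, alpha)
            sv_c = np.power(v_certain, alpha)
            p = expit(gamma * (sv_l - sv_c))
            p = np.clip(p, lo, hi)
            return float(-np.sum(c * np.log(p) + one_minus_c * np.log(1.0 - p)))

    return nll


def nll_for_trials(
    params: AgentParams | tuple,
    choices: dict[str, bool] | pd.DataFrame,
    trials: list[Trial] | pd.DataFrame,
    model: ModelSpec,
) -> float:
    """Convenience wrapper: align choices to trials by trial_id, then NLL."""
    if isinstance(choices, pd.DataFrame):
        chosen = dict(
            zip(choices["trial_id"].astype(str), choices["chose_lottery"])
        )
    else:
        chosen = choices
    if isinstance(trials, pd.DataFrame):
        ids = trials["trial_id"].astype(str).tolist()
    else:
        ids = [t.trial_id for t in trials]
    c = np.array([bool(chosen[i]) for i in ids])
    return negative_log_likelihood(params, c, trial_arrays(trials, model))
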