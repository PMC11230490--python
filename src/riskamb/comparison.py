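"""Arbitrating the ordinal vs rating valuation models.

Two criteria, both computed per participant x domain x phase and averaged
over participants:

* BIC = 2*NLL + k*ln(n_trials) with k = 3 fitted parameters (natural log);
* 5-fold cross-validated mean squared error: the unit's trials are
  randomly partitioned into folds of 9-10 trials; for each fold the model
  is refitted on the other four and the Brier-style residual
  mean((P_V - c)^2) is taken on the left-out fold, c the binary choice.

The winner must take both criteria; a split verdict is flagged discordant.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import COARSE_GRID, fit_unit, ratings_map
from .model import ModelSpec, lottery_choice_probabilities, trial_arrays
from .trials import TrialSet

log = logging.getLogger(__name__)

N_PARAMS = 3

COMPARISON_COLUMNS = [
    "variant",
    "domain",
    "phase",
    "mean_bic",
    "mean_cv_mse",
    "n_participants",
]


def bic(nll: float, n_trials: int, k: int = N_PARAMS) -> float:
    """Bayesian information criterion, lower is better."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return 2.0 * float(nll) + k * np.log(n_trials)


def make_folds(n_trials: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into k folds with sizes as equal as possible.

    49 trials at k=5 gives fold sizes {9, 10, 10, 10, 10}.
    """
    if n_trials < k:
        raise ValueError("need at least k trials")
    perm = rng.permutation(n_trials)
    return [np.sort(part) for part in np.array_split(perm, k)]


def cross_validate(
    choices: pd.DataFrame,
    trials: pd.DataFrame,
    model: ModelSpec,
    k: int = 5,
    seed: int = 0,
    grid=None,
) -> float:
    """Mean out-of-fold MSE between predicted P_V and the binary choice.

    Folds where the training set cannot be fitted (e.g. all-certain after
    the split) are skipped with a log entry and the mean runs over the
    remaining folds.
    """
    grid = grid if grid is not None else COARSE_GRID
    trials = trials.reset_index(drop=True)
    order = dict(zip(choices["trial_id"].astype(str), choices["chose_lottery"]))
    c = np.array([bool(order[t]) for t in trials["trial_id"].astype(str)])
    rng = np.random.default_rng(seed)
    folds = make_folds(len(trials), k, rng)
    mses = []
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(len(trials), dtype=bool)
        train_mask[test_idx] = False
        train_trials = trials[train_mask]
        train_choices = choices[
            choices["trial_id"].isin(set(train_trials["trial_id"]))
        ]
        try:
            fit = fit_unit(train_choices, train_trials, model, grid)
        except (ValueError, RuntimeError) as exc:
            log.warning("cv fold %d skipped: %s", i, exc)
            continue
        test_arrays = trial_arrays(trials.iloc[test_idx], model)
        p = lottery_choice_probabilities(
            test_arrays, (fit.alpha_hat, fit.beta_hat, fit.gamma_hat)
        )
        mses.append(float(np.mean((p - c[test_idx]) ** 2)))
    if not mses:
        raise RuntimeError("no cross-validation fold could be fitted")
    return float(np.mean(mses))


def _unit_seed(seed: int, participant_id: str, phase, domain: str) -> int:
    return int(
        np.random.default_rng(
            [int(seed) % (2**31), zlib.crc32(f"{participant_id}|{phase}|{domain}".encode())]
        ).integers(0, 2**31)
    )


@dataclass
class ModelSelection:
    table: pd.DataFrame
    selected: str | None  # None when the criteria disagree
    discordant: bool


def compare_models(
    choices: pd.DataFrame,
    trials: TrialSet | pd.DataFrame,
    ratings: pd.DataFrame,
    variants: tuple[str, ...] = ("ordinal", "rating"),
    k: int = 5,
    seed: int = 0,
    grid=None,
    cv_grid=None,
) -> ModelSelection:
    """Mean BIC and mean CV-MSE per variant x domain x phase, plus verdict.

    The overall verdict pools all domain x phase cells: the variant with
    the lower grand-mean BIC must also hold the lower grand-mean CV-MSE,
    otherwise the selection is flagged discordant.
    """
    tf = trials.to_frame() if isinstance(trials, TrialSet) else trials
    merged = choices.merge(tf[["trial_id", "domain"]], on="trial_id", how="left")
    rows = []
    for variant in variants:
        for (pid, phase, domain), g in merged.groupby(
            ["participant_id", "phase", "domain"], sort=True
        ):
            unit_trials = tf[tf["trial_id"].isin(set(g["trial_id"]))]
            model = (
                ModelSpec("rating", ratings_map(ratings, pid, phase, domain))
                if variant == "rating"
                else ModelSpec("ordinal")
            )
            try:
                fit = fit_unit(g, unit_trials, model, grid,
                               participant_id=pid, phase=phase, domain=domain)
                mse = cross_validate(
                    g, unit_trials, model, k=k,
                    seed=_unit_seed(seed, pid, phase, domain),
                    grid=cv_grid,
                )
            except (ValueError, RuntimeError) as exc:
                log.warning("comparison unit %s/%s/%s (%s) failed: %s",
                            pid, phase, domain, variant, exc)
                continue
            rows.append(
                {
                    "variant": variant,
                    "domain": domain,
                    "phase": phase,
                    "participant_id": pid,
                    "bic": bic(fit.nll, fit.n_trials),
                    "cv_mse": mse,
                }
            )
    per_unit = pd.DataFrame(rows)
    if per_unit.empty:
        raise RuntimeError("no unit could be compared")
    table = (
        per_unit.groupby(["variant", "domain", "phase"])
        .agg(mean_bic=("bic", "mean"), mean_cv_mse=("cv_mse", "mean"),
             n_participants=("participant_id", "nunique"))
        .reset_index()[COMPARISON_COLUMNS]
    )
    grand = per_unit.groupby("variant").agg(
        bic=("bic", "mean"), mse=("cv_mse", "mean")
    )
    by_bic = grand["bic"].idxmin()
    by_mse = grand["mse"].idxmin()
    discordant = by_bic != by_mse
    return ModelSelection(
        table=table, selected=None if discordant else by_bic, discordant=discordant
    )
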