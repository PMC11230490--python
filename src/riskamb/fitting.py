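"""Per-participant maximum-likelihood fitting.

Each participant x domain x phase unit is fitted separately by minimizing
the Bernoulli negative log-likelihood with the Nelder-Mead simplex, started
from every point of a parameter grid.  Positivity of alpha and gamma is
enforced by optimizing on (log alpha, beta, log gamma); beta is
unconstrained.  The reported ambiguity attitude is -beta, so negative
values indicate aversion.

The default grid follows the task's fitting conventions: alpha starts
[0.01, 4] step 0.5 (8 values), beta starts [-2, 2] step 0.5 (9 values),
gamma start magnitudes [0.01, 1] step 0.5 (2 values) — 144 starts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import ModelSpec, nll_closure, trial_arrays
from .trials import TrialSet

log = logging.getLogger(__name__)

DEFAULT_RANGES = {"alpha": (0.01, 4.0), "beta": (-2.0, 2.0), "gamma": (0.01, 1.0)}
DEFAULT_STEP = 0.5

#: sanity-reporting bounds; fits beyond these are flagged, not clamped
BOUNDARY_LIMITS = {"alpha": 10.0, "beta": 4.0, "gamma": 100.0}

XATOL = FATOL = 1e-6
MAXFEV = 2000

FITS_CSV_COLUMNS = [
    "participant_id",
    "phase",
    "domain",
    "variant",
    "alpha_hat",
    "beta_hat",
    "gamma_hat",
    "reported_ambiguity_attitude",
    "nll",
    "n_trials",
    "start_alpha",
    "start_beta",
    "start_gamma",
    "converged",
    "n_starts",
    "boundary_flag",
]


@dataclass(frozen=True)
class FitResult:
    participant_id: str
    phase: int
    domain: str
    variant: str
    alpha_hat: float
    beta_hat: float
    gamma_hat: float
    nll: float
    n_trials: int
    start_point: tuple[float, float, float]
    converged: bool
    n_starts: int

    @property
    def reported_ambiguity_attitude(self) -> float:
        """-beta: positive = ambiguity seeking, negative = averse."""
        return -self.beta_hat

    @property
    def boundary_flag(self) -> bool:
        return (
            self.alpha_hat > BOUNDARY_LIMITS["alpha"]
            or abs(self.beta_hat) > BOUNDARY_LIMITS["beta"]
            or self.gamma_hat > BOUNDARY_LIMITS["gamma"]
        )

    def as_row(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "phase": self.phase,
            "domain": self.domain,
            "variant": self.variant,
            "alpha_hat": self.alpha_hat,
            "beta_hat": self.beta_hat,
            "gamma_hat": self.gamma_hat,
            "reported_ambiguity_attitude": self.reported_ambiguity_attitude,
            "nll": self.nll,
            "n_trials": self.n_trials,
            "start_alpha": self.start_point[0],
            "start_beta": self.start_point[1],
            "start_gamma": self.start_point[2],
            "converged": self.converged,
            "n_starts": self.n_starts,
            "boundary_flag": self.boundary_flag,
        }


def _sequence(lo: float, hi: float, step: float) -> list[float]:
    if step <= 0:
        raise ValueError("step must be positive")
    if hi < lo:
        raise ValueError("empty range")
    out, x = [], lo
    while x <= hi + 1e-12:
        out.append(round(x, 10))
        x += step
    return out


def make_start_grid(
    ranges: dict[str, tuple[float, float]] | None = None,
    step: float = DEFAULT_STEP,
) -> list[tuple[float, float, float]]:
    """Cartesian product of per-parameter start sequences (alpha, beta, gamma)."""
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    alphas = _sequence(*ranges["alpha"], step)
    betas = _sequence(*ranges["beta"], step)
    gammas = _sequence(*ranges["gamma"], step)
    return list(itertools.product(alphas, betas, gammas))


#: small grid for inner loops (cross-validation folds, large sweeps); the
#: objective is smooth in 3 parameters so a few well-spread starts suffice
COARSE_GRID = make_start_grid(
    {"alpha": (0.51, 3.51), "beta": (-1.5, 1.5), "gamma": (0.51, 0.51)},
    step=1.5,
)

#: minimal 4-start grid for the innermost loops (per-fold refits inside
#: cross-validation, where each unit is refitted k times per variant)
CV_GRID = make_start_grid(
    {"alpha": (0.51, 2.01), "beta": (-0.5, 1.0), "gamma": (0.51, 0.51)},
    step=1.5,
)


def _align(choices: pd.DataFrame, trials) -> np.ndarray:
    chosen = dict(zip(choices["trial_id"].astype(str), choices["chose_lottery"]))
    tf = trials if isinstance(trials, pd.DataFrame) else None
    ids = (
        tf["trial_id"].astype(str).tolist()
        if tf is not None
        else [t.trial_id for t in trials]
    )
    return np.array([bool(chosen[i]) for i in ids])


def fit_unit(
    choices: pd.DataFrame,
    trials,
    model: ModelSpec,
    grid: list[tuple[float, float, float]] | None = None,
    participant_id: str = "",
    phase: int = 0,
    domain: str = "",
) -> FitResult:
    """Fit one participant x domain x phase block of same-domain trials.

    Returns the lowest-NLL solution over all grid starts; ties break toward
    the earliest start in grid order, so the result is deterministic.
    """
    grid = grid if grid is not None else make_start_grid()
    if not grid:
        raise ValueError("empty start grid")
    arrays = trial_arrays(trials, model)
    if arrays.n_trials < 10:
        raise ValueError("need at least 10 trials to fit")
    c = _align(choices, trials)
    if c.sum() == 0:
        raise ValueError(
            "participant never chose the lottery; unit is not fittable "
            "(apply the never-uncertain filter first)"
        )

    fast_nll = nll_closure(c, arrays)

    def objective(x: np.ndarray) -> float:
        return fast_nll(np.exp(x[0]), x[1], np.exp(x[2]))

    best = None
    failures = []
    for start in grid:
        x0 = np.array([np.log(start[0]), start[1], np.log(start[2])])
        try:
            res = minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={
                    "xatol": XATOL,
                    "fatol": FATOL,
                    "maxfev": MAXFEV,
                },
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append((start, str(exc)))
            continue
        if not np.isfinite(res.fun):
            failures.append((start, "non-finite objective"))
            continue
        if best is None or res.fun < best[0] - 1e-12:
            best = (float(res.fun), res, start)
    if best is None:
        raise RuntimeError(
            f"all {len(grid)} starts failed for {participant_id}/{phase}/{domain}: "
            f"{failures[:3]}"
        )
    nll, res, start = best
    return FitResult(
        participant_id=str(participant_id),
        phase=int(phase),
        domain=str(domain),
        variant=model.variant,
        # exp can underflow to 0.0 when a saturated fit runs off to -inf in
        # log space; floor at the smallest normal float to keep alpha, gamma
        # in the model's open domain
        alpha_hat=float(max(np.exp(res.x[0]), np.finfo(float).tiny)),
        beta_hat=float(res.x[1]),
        gamma_hat=float(max(np.exp(res.x[2]), np.finfo(float).tiny)),
        nll=nll,
        n_trials=arrays.n_trials,
        start_point=tuple(start),
        converged=bool(res.success),
        n_starts=len(grid),
    )


def ratings_map(
    ratings: pd.DataFrame, participant_id: str, phase: int, domain: str
) -> dict[int, float]:
    sub = ratings[
        (ratings["participant_id"] == participant_id)
        & (ratings["phase"] == phase)
        & (ratings["domain"] == domain)
    ]
    return dict(zip(sub["outcome_ordinal"].astype(int), sub["rating"].astype(float)))


def fit_cohort(
    choices: pd.DataFrame,
    trials: TrialSet | pd.DataFrame,
    variant: str = "ordinal",
    ratings: pd.DataFrame | None = None,
    grid: list[tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Fit every participant x phase x domain unit in ``choices``.

    ``choices`` should already be the modelling set (exclusions applied).
    Per-unit failures are logged and recorded, not fatal.
    """
    tf = trials.to_frame() if isinstance(trials, TrialSet) else trials
    merged = choices.merge(tf[["trial_id", "domain"]], on="trial_id", how="left")
    rows = []
    for (pid, phase, domain), g in merged.groupby(
        ["participant_id", "phase", "domain"], sort=True
    ):
        unit_trials = tf[tf["trial_id"].isin(set(g["trial_id"]))]
        if variant == "rating":
            if ratings is None:
                raise ValueError("rating variant requires a ratings table")
            model = ModelSpec("rating", ratings_map(ratings, pid, phase, domain))
        else:
            model = ModelSpec("ordinal")
        try:
            fit = fit_unit(
                g, unit_trials, model, grid,
                participant_id=pid, phase=phase, domain=domain,
            )
        except (ValueError, RuntimeError) as exc:
            log.warning("fit failed for %s/%s/%s: %s", pid, phase, domain, exc)
            continue
        rows.append(fit.as_row())
    return pd.DataFrame(rows, columns=FITS_CSV_COLUMNS)
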