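"""Synthetic two-phase cohort generator.

Generates agents with known (alpha, beta, gamma) parameters per domain and
phase, simulates their lottery choices through the valuation + softmax model,
produces monotone noisy outcome-pleasantness ratings on the 0-10 scale, and
plants designated "aberrant" agents whose behaviour fires each downstream
exclusion rule.  Every draw is a pure function of (spec, trialset, seed), so
all downstream stages are testable against the recorded ground truth.

Cross-domain and cross-phase persistence of the parameters is induced with a
Gaussian copula on a Kronecker (domain x phase) latent correlation, so the
planted *Spearman* targets hold exactly in expectation regardless of the
marginal distributions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import AgentParams, ModelSpec, lottery_choice_probabilities, trial_arrays
from .trials import DOMAINS, TrialSet

PHASES = (1, 2)

CHOICES_CSV_COLUMNS = ["participant_id", "phase", "trial_id", "chose_lottery"]
RATINGS_CSV_COLUMNS = [
    "participant_id",
    "phase",
    "domain",
    "outcome_ordinal",
    "rating",
]
PARTICIPANTS_CSV_COLUMNS = ["participant_id", "phase", "age", "mturk_like_id"]
TRUTH_CSV_COLUMNS = [
    "participant_id",
    "phase",
    "domain",
    "alpha",
    "beta",
    "gamma",
    "role",
]

#: aberrant roles a cohort spec can allocate
ROLES = ("typical", "catch_failer", "never_uncertain", "duplicate_id", "age_gap")


@dataclass(frozen=True)
class Marginal:
    """A named 1-D parameter distribution (lognormal or normal)."""

    name: str  # "lognormal" | "normal"
    loc: float  # lognormal: median; normal: mean
    scale: float  # lognormal: sigma of log; normal: sd

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.name == "lognormal":
            return stats.lognorm.ppf(u, s=self.scale, scale=self.loc)
        if self.name == "normal":
            return stats.norm.ppf(u, loc=self.loc, scale=self.scale)
        raise ValueError(f"unknown marginal {self.name!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for the synthetic cohort.

    Defaults emulate a generally risk- and ambiguity-averse population with
    moderate cross-domain and cross-phase persistence of attitudes.  Ratings
    default to a linear-in-ordinal noisy map spanning the 0-10 scale;
    ``rating_exponent`` < 1 produces a concave (nonlinearly distorted)
    rating map instead.
    """

    n_agents: int = 100
    alpha_dist: Marginal = field(default=Marginal("lognormal", 0.7, 0.5))
    beta_dist: Marginal = field(default=Marginal("normal", 0.3, 0.5))
    gamma_dist: Marginal = field(default=Marginal("lognormal", 1.5, 0.5))
    cross_domain_rho: float = 0.4
    cross_phase_rho: float = 0.5
    catch_failer_fraction: float = 0.0
    never_uncertain_fraction: float = 0.0
    duplicate_id_fraction: float = 0.0
    age_gap_fraction: float = 0.0
    rating_exponent: float = 1.0
    rating_noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        fracs = (
            self.catch_failer_fraction,
            self.never_uncertain_fraction,
            self.duplicate_id_fraction,
            self.age_gap_fraction,
        )
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("aberrant fractions must lie in [0,1] and sum < 1")
        for rho in (self.cross_domain_rho, self.cross_phase_rho):
            if abs(rho) > 0.99:
                raise ValueError("correlation targets must satisfy |rho| <= 0.99")
        if self.rating_exponent <= 0:
            raise ValueError("rating_exponent must be positive")


def _stage_rng(seed: int, label: str, *extra: int) -> np.random.Generator:
    """Stable sub-seeding: adding a stage never perturbs another's stream."""
    return np.random.default_rng(
        [int(seed) % (2**31), zlib.crc32(label.encode()), *map(int, extra)]
    )


def _latent_correlation(spec: CohortSpec) -> np.ndarray:
    """4x4 latent Gaussian correlation over (domain, phase) cells.

    Spearman targets are mapped to latent Pearson via r = 2 sin(pi*rho/6);
    the Kronecker structure R_domain (x) R_phase is positive semi-definite
    by construction.
    """

    def latent(rho_s: float) -> float:
        return 2.0 * np.sin(np.pi * rho_s / 6.0)

    rd, rp = latent(spec.cross_domain_rho), latent(spec.cross_phase_rho)
    r_domain = np.array([[1.0, rd], [rd, 1.0]])
    r_phase = np.array([[1.0, rp], [rp, 1.0]])
    return np.kron(r_domain, r_phase)


def sample_agent_params(spec: CohortSpec) -> pd.DataFrame:
    """Ground-truth (alpha, beta, gamma) per agent x domain x phase.

    Rows are ordered (agent, domain, phase); agent ids are assigned later.
    """
    rng = _stage_rng(spec.seed, "params")
    cov = _latent_correlation(spec)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(4))
    rows = []
    values = {}
    for pname, marg in (
        ("alpha", spec.alpha_dist),
        ("beta", spec.beta_dist),
        ("gamma", spec.gamma_dist),
    ):
        z = rng.standard_normal((spec.n_agents, 4)) @ chol.T
        u = stats.norm.cdf(z)
        values[pname] = marg.ppf(u)  # columns: (mon,p1) (mon,p2) (med,p1) (med,p2)
    for i in range(spec.n_agents):
        for d, domain in enumerate(DOMAINS):
            for p, phase in enumerate(PHASES):
                col = 2 * d + p
                rows.append(
                    {
                        "agent_index": i,
                        "domain": domain,
                        "phase": phase,
                        "alpha": float(values["alpha"][i, col]),
                        "beta": float(values["beta"][i, col]),
                        "gamma": float(values["gamma"][i, col]),
                    }
                )
    df = pd.DataFrame(rows)
    # keep parameters inside the model's admissible open domain
    df["alpha"] = df["alpha"].clip(lower=1e-3)
    df["gamma"] = df["gamma"].clip(lower=1e-3)
    return df


def simulate_agent_choices(
    params: AgentParams,
    trials,
    seed: int,
) -> pd.DataFrame:
    """Simulate one agent's choices on a block of same-domain trials.

    Each trial's lottery is chosen with the model's softmax probability;
    deterministic given ``seed``.  Returns a frame with trial_id and
    chose_lottery (participant/phase columns are attached by the caller).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("empty trial set")
    domains = {t.domain for t in trials}
    if len(domains) != 1:
        raise ValueError("trials must come from a single domain")
    arrays = trial_arrays(trials, ModelSpec("ordinal"))
    p = lottery_choice_probabilities(arrays, params)
    rng = np.random.default_rng(seed)
    chose = rng.random(len(trials)) < p
    return pd.DataFrame(
        {"trial_id": [t.trial_id for t in trials], "chose_lottery": chose}
    )


def _assign_roles(spec: CohortSpec) -> list[str]:
    """Deterministic role assignment: aberrant agents occupy the tail."""
    n = spec.n_agents
    counts = {
        "catch_failer": int(round(spec.catch_failer_fraction * n)),
        "never_uncertain": int(round(spec.never_uncertain_fraction * n)),
        "duplicate_id": int(round(spec.duplicate_id_fraction * n)),
        "age_gap": int(round(spec.age_gap_fraction * n)),
    }
    roles = ["typical"] * n
    cursor = n
    for role in ("age_gap", "duplicate_id", "never_uncertain", "catch_failer"):
        for _ in range(counts[role]):
            cursor -= 1
            roles[cursor] = role
    if cursor < 1 and any(counts.values()):
        raise ValueError("aberrant fractions leave no typical agent")
    return roles


def simulate_cohort(spec: CohortSpec, trialset: TrialSet) -> dict[str, pd.DataFrame]:
    """Full cohort simulation.

    Returns dict with keys ``choices``, ``ratings``, ``participants``,
    ``truth`` — the four study tables.  duplicate_id agents share an
    MTurk-like worker id with the preceding typical agent; catch_failers
    choose the lottery on every reference-equal trial; never_uncertain
    agents always take the certain option; age_gap agents report a phase-2
    age more than 2 years away from phase 1.
    """
    truth = sample_agent_params(spec)
    roles = _assign_roles(spec)
    n = spec.n_agents

    ids = [f"P{i:04d}" for i in range(n)]
    worker = [f"W{i:04d}" for i in range(n)]
    typical_pool = [i for i, r in enumerate(roles) if r == "typical"]
    for j, i in enumerate(i for i, r in enumerate(roles) if r == "duplicate_id"):
        worker[i] = worker[typical_pool[j % len(typical_pool)]]

    age_rng = _stage_rng(spec.seed, "ages")
    age1 = age_rng.integers(20, 81, size=n)
    age2 = age1 + age_rng.integers(0, 2, size=n)
    for i, r in enumerate(roles):
        if r == "age_gap":
            age2[i] = age1[i] + 3 + age_rng.integers(0, 5)

    participants = pd.DataFrame(
        [
            {"participant_id": ids[i], "phase": ph, "age": int(a[i]),
             "mturk_like_id": worker[i]}
            for ph, a in ((1, age1), (2, age2))
            for i in range(n)
        ],
        columns=PARTICIPANTS_CSV_COLUMNS,
    )

    domain_trials = {d: trialset.domain(d) for d in DOMAINS}
    truth = truth.copy()
    truth["participant_id"] = [ids[i] for i in truth["agent_index"]]
    truth["role"] = [roles[i] for i in truth["agent_index"]]

    choice_frames = []
    for row in truth.itertuples(index=False):
        i = row.agent_index
        d_idx = DOMAINS.index(row.domain)
        sub_seed = _stage_rng(spec.seed, "choices", i, row.phase, d_idx).integers(
            0, 2**31
        )
        block = simulate_agent_choices(
            AgentParams(row.alpha, row.beta, row.gamma),
            domain_trials[row.domain],
            int(sub_seed),
        )
        if roles[i] == "catch_failer":
            catch_ids = {
                t.trial_id for t in domain_trials[row.domain] if t.is_reference_equal
            }
            block.loc[block["trial_id"].isin(catch_ids), "chose_lottery"] = True
        elif roles[i] == "never_uncertain":
            block["chose_lottery"] = False
        block.insert(0, "phase", row.phase)
        block.insert(0, "participant_id", ids[i])
        choice_frames.append(block)
    choices = pd.concat(choice_frames, ignore_index=True)[CHOICES_CSV_COLUMNS]

    rate_rng = _stage_rng(spec.seed, "ratings")
    ordinals = np.arange(5)
    base = 10.0 * (ordinals / 4.0) ** spec.rating_exponent
    rating_rows = []
    for i in range(n):
        for ph in PHASES:
            for domain in DOMAINS:
                noise = rate_rng.normal(0.0, spec.rating_noise_sd, size=5)
                vals = np.clip(base + noise, 0.0, 10.0)
                for o in ordinals:
                    rating_rows.append(
                        {
                            "participant_id": ids[i],
                            "phase": ph,
                            "domain": domain,
                            "outcome_ordinal": int(o),
                            "rating": float(vals[o]),
                        }
                    )
    ratings = pd.DataFrame(rating_rows, columns=RATINGS_CSV_COLUMNS)

    truth_out = truth[TRUTH_CSV_COLUMNS]
    return {
        "choices": choices,
        "ratings": ratings,
        "participants": participants,
        "truth": truth_out,
    }
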