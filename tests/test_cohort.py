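"""Synthetic cohort generator: choice simulation against closed forms,
copula-planted correlations, aberrant-role construction, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from riskamb.cohort import (
    CohortSpec,
    Marginal,
    sample_agent_params,
    simulate_agent_choices,
    simulate_cohort,
)
from riskamb.model import AgentParams
from riskamb.trials import Trial, outcome_levels


def _risky_trials(n, p=0.5, ordinal=4, domain="monetary"):
    level = outcome_levels(domain)[ordinal]
    return [
        Trial(f"t{i:05d}", domain, "risk", p, 0.0, level, "red") for i in range(n)
    ]


class TestAgentChoices:
    def test_noiseless_agent_takes_dominant_lottery(self):
        params = AgentParams(alpha=1.0, beta=0.0, gamma=1e4)
        trials = _risky_trials(50, p=0.75)  # SV_L = 3 > SV_C = 1
        out = simulate_agent_choices(params, trials, seed=3)
        assert out["chose_lottery"].all()

    def test_empirical_rate_matches_logistic_closed_form(self):
        """alpha=1, beta=0, gamma=5, 50% risk at V=4: P_V = expit(5*(2-1))."""
        params = AgentParams(alpha=1.0, beta=0.0, gamma=5.0)
        n = 10_000
        out = simulate_agent_choices(params, _risky_trials(n), seed=5)
        p_true = float(expit(5.0 * (2.0 - 1.0)))  # ~0.9933
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(out["chose_lottery"].mean() - p_true) < 3 * se

    def test_equal_subjective_values_give_fifty_fifty(self):
        # P=0.25 at V=4 with alpha=1: SV_L = 1 = SV_C
        params = AgentParams(alpha=1.0, beta=0.0, gamma=3.0)
        out = simulate_agent_choices(params, _risky_trials(8000, p=0.25), seed=6)
        assert abs(out["chose_lottery"].mean() - 0.5) < 3 * np.sqrt(0.25 / 8000)

    def test_deterministic_given_seed_and_mixed_domains_rejected(self, trialset):
        params = AgentParams(1.0, 0.3, 2.0)
        mon = trialset.domain("monetary")
        a = simulate_agent_choices(params, mon, seed=9)
        b = simulate_agent_choices(params, mon, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            simulate_agent_choices(params, trialset.trials, seed=9)
        with pytest.raises(ValueError):
            simulate_agent_choices(params, [], seed=9)


class TestCohortStructure:
    def test_bookkeeping_shapes(self, trialset):
        tables = simulate_cohort(CohortSpec(n_agents=100, seed=2), trialset)
        assert len(tables["choices"]) == 100 * 2 * 98
        assert len(tables["participants"]) == 100 * 2
        assert len(tables["truth"]) == 100 * 2 * 2
        assert len(tables["ratings"]) == 100 * 2 * 2 * 5
        per_unit = tables["choices"].groupby(["participant_id", "phase"]).size()
        assert (per_unit == 98).all()

    def test_reproducible(self, trialset):
        spec = CohortSpec(n_agents=10, seed=21)
        a = simulate_cohort(spec, trialset)
        b = simulate_cohort(spec, trialset)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_ratings_bounded_and_monotone_in_expectation(self, trialset):
        tables = simulate_cohort(CohortSpec(n_agents=60, seed=3), trialset)
        r = tables["ratings"]
        assert r["rating"].between(0, 10).all()
        means = r.groupby("outcome_ordinal")["rating"].mean()
        assert (means.diff().dropna() > 0).all()

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_agents=10, cross_phase_rho=0.999)

    def test_aberrant_fraction_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_agents=10, catch_failer_fraction=0.6,
                       never_uncertain_fraction=0.5)


class TestPlantedCorrelations:
    def test_cross_phase_spearman_recovered(self):
        spec = CohortSpec(n_agents=2000, cross_phase_rho=0.6,
                          cross_domain_rho=0.2, seed=17)
        truth = sample_agent_params(spec)
        wide = truth[truth["domain"] == "monetary"].pivot(
            index="agent_index", columns="phase", values="alpha"
        )
        rho = spearmanr(wide[1], wide[2]).statistic
        assert rho == pytest.approx(0.6, abs=0.05)

    def test_independent_domains_when_rho_zero(self):
        spec = CohortSpec(n_agents=2000, cross_domain_rho=0.0, seed=23)
        truth = sample_agent_params(spec)
        wide = truth[truth["phase"] == 1].pivot(
            index="agent_index", columns="domain", values="beta"
        )
        rho = spearmanr(wide["monetary"], wide["medical"]).statistic
        assert abs(rho) < 0.06

    def test_marginals_follow_named_distributions(self):
        spec = CohortSpec(
            n_agents=4000,
            alpha_dist=Marginal("lognormal", 0.7, 0.5),
            beta_dist=Marginal("normal", 0.3, 0.5),
            seed=31,
        )
        truth = sample_agent_params(spec)
        cell = truth[(truth["phase"] == 1) & (truth["domain"] == "monetary")]
        assert np.median(cell["alpha"]) == pytest.approx(0.7, rel=0.07)
        assert cell["beta"].mean() == pytest.approx(0.3, abs=0.04)
        assert cell["beta"].std() == pytest.approx(0.5, rel=0.08)


class TestAberrantRoles:
    def test_roles_emit_rule_triggering_behaviour(self, aberrant_cohort, trialset):
        truth = aberrant_cohort["truth"]
        choices = aberrant_cohort["choices"]
        roles = truth.drop_duplicates("participant_id").set_index(
            "participant_id"
        )["role"]
        catch_ids = {t.trial_id for t in trialset if t.is_reference_equal}

        never = roles[roles == "never_uncertain"].index
        assert len(never) == 4
        sub = choices[choices["participant_id"].isin(never)]
        assert not sub["chose_lottery"].any()

        failers = roles[roles == "catch_failer"].index
        assert len(failers) == 4
        sub = choices[
            choices["participant_id"].isin(failers)
            & choices["trial_id"].isin(catch_ids)
        ]
        assert sub["chose_lottery"].all()

    def test_duplicate_ids_share_worker_id(self, aberrant_cohort):
        participants = aberrant_cohort["participants"]
        phase1 = participants[participants["phase"] == 1]
        dup_counts = phase1.groupby("mturk_like_id").size()
        assert (dup_counts > 1).sum() == 2  # 5% of 40 agents -> 2 duplicated ids

    def test_age_gap_agents_have_large_gap(self, aberrant_cohort):
        truth = aberrant_cohort["truth"]
        participants = aberrant_cohort["participants"]
        gap_agents = set(truth[truth["role"] == "age_gap"]["participant_id"])
        wide = participants.pivot(index="participant_id", columns="phase",
                                  values="age")
        gaps = (wide[2] - wide[1]).abs()
        assert (gaps[list(gap_agents)] > 2).all()
        assert (gaps[~gaps.index.isin(gap_agents)] <= 2).all()
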