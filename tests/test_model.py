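"""Valuation + softmax model: hand-checked values, oracle equivalence,
monotonicity properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskamb.model import (
    LIKELIHOOD_EPS,
    AgentParams,
    ModelSpec,
    TrialArrays,
    choice_probability,
    negative_log_likelihood,
    nll_closure,
    subjective_value,
    trial_arrays,
)


def naive_nll(alpha, beta, gamma, trials, chose):
    """Independent per-trial re-implementation (plain math, no vectorization)."""
    total = 0.0
    for (p_win, amb, value, v_ref), c in zip(trials, chose):
        sv_l = (p_win - beta * amb / 2.0) * value**alpha
        sv_c = (1.0 - beta * 0.0 / 2.0) * v_ref**alpha
        p = 1.0 / (1.0 + math.exp(-gamma * (sv_l - sv_c)))
        p = min(max(p, LIKELIHOOD_EPS), 1.0 - LIKELIHOOD_EPS)
        total -= math.log(p) if c else math.log(1.0 - p)
    return total


class TestSubjectiveValue:
    def test_certain_reference_is_value_independent_of_alpha(self):
        for alpha in (0.3, 1.0, 2.5):
            assert subjective_value(1.0, 0.0, 1.0, alpha, 0.7) == 1.0

    def test_risk_neutral_linear_case(self):
        assert subjective_value(0.5, 0.0, 4.0, 1.0, 0.0) == 2.0

    def test_ambiguity_discount_hand_value(self):
        sv = subjective_value(0.5, 0.74, 4.0, 1.0, 0.5)
        assert sv == pytest.approx((0.5 - 0.185) * 4.0)  # 1.26

    def test_null_outcome_worth_zero(self):
        assert subjective_value(0.75, 0.0, 0.0, 0.6, 0.0) == 0.0

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            subjective_value(0.5, 0.0, 4.0, -1.0, 0.0)
        with pytest.raises(ValueError):
            subjective_value(0.5, 0.0, -4.0, 1.0, 0.0)


class TestChoiceProbability:
    def test_equal_values_give_half(self):
        assert choice_probability(2.0, 2.0, 3.7) == 0.5

    def test_logistic_hand_value(self):
        assert choice_probability(2.0, 1.0, 1.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.0)), abs=1e-9
        )

    def test_noiseless_limit(self):
        assert choice_probability(2.0, 1.0, 1e6) == pytest.approx(1.0)
        assert choice_probability(1.0, 2.0, 1e6) == pytest.approx(0.0)

    def test_overflow_safe(self):
        assert choice_probability(1e6, -1e6, 100.0) == 1.0

    @given(
        delta=st.floats(-5, 5),
        gamma=st.floats(0.01, 5),
    )
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_in_sv_difference(self, delta, gamma):
        # gamma*|delta| <= 25 keeps the logistic away from float saturation
        p1 = choice_probability(delta, 0.0, gamma)
        p2 = choice_probability(delta + 0.1, 0.0, gamma)
        assert p2 > p1


class TestNegativeLogLikelihood:
    def test_closed_form_two_coin_flip_trials(self):
        """Two trials at P_V = 0.5, both lottery -> 2 ln 2."""
        # reference-equal lotteries at P = 1: SV_L = SV_C so P_V = 1/2 exactly
        arrays = TrialArrays(
            win_probability=np.array([1.0, 1.0]),
            ambiguity_level=np.array([0.0, 0.0]),
            value=np.array([1.0, 1.0]),
            value_certain=1.0,
        )
        nll = negative_log_likelihood((1.0, 0.0, 2.0), np.array([1, 1]), arrays)
        assert nll == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_matches_naive_oracle_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = 20
            p_win = rng.choice([0.25, 0.5, 0.75, 1.0], size=n)
            amb = np.where(p_win == 0.5, rng.choice([0.0, 0.24, 0.5, 0.74], size=n), 0.0)
            value = rng.choice([0.0, 1.0, 2.0, 3.0, 4.0], size=n)
            chose = rng.random(n) < 0.5
            alpha = rng.uniform(0.2, 3.0)
            beta = rng.uniform(-2.0, 2.0)
            gamma = rng.uniform(0.05, 8.0)
            arrays = TrialArrays(p_win, amb, value, 1.0)
            fast = negative_log_likelihood((alpha, beta, gamma), chose, arrays)
            slow = naive_nll(
                alpha, beta, gamma,
                list(zip(p_win, amb, value, [1.0] * n)), chose,
            )
            assert fast == pytest.approx(slow, abs=1e-9)
            closure = nll_closure(chose, arrays)
            assert closure(alpha, beta, gamma) == pytest.approx(fast, abs=1e-12)

    def test_empty_choice_set_raises(self):
        arrays = TrialArrays(np.array([0.5]), np.array([0.0]), np.array([2.0]), 1.0)
        with pytest.raises(ValueError):
            negative_log_likelihood((1.0, 0.0, 1.0), np.array([]), arrays)


class TestModelVariants:
    def test_ordinal_and_rating_coincide_when_ratings_equal_ordinals(self, trialset):
        mon = trialset.domain("monetary")
        ordinal = trial_arrays(mon, ModelSpec("ordinal"))
        rating = trial_arrays(
            mon, ModelSpec("rating", {o: float(o) for o in range(5)})
        )
        assert np.array_equal(ordinal.value, rating.value)
        assert ordinal.value_certain == rating.value_certain

    def test_rating_variant_requires_complete_ratings(self, trialset):
        model = ModelSpec("rating", {0: 0.0, 1: 2.0})  # missing 2..4
        with pytest.raises(ValueError):
            trial_arrays(trialset.domain("monetary"), model)

    def test_beta_zero_reduces_ambiguous_to_fifty_percent_risk(self):
        """Under ambiguity neutrality every ambiguous lottery is a 50% lottery."""
        for a in (0.24, 0.5, 0.74):
            sv_amb = subjective_value(0.5, a, 3.0, 0.8, 0.0)
            sv_risk = subjective_value(0.5, 0.0, 3.0, 0.8, 0.0)
            assert sv_amb == sv_risk

    @given(
        beta=st.floats(0.05, 2.0),
        alpha=st.floats(0.2, 3.0),
        amb=st.sampled_from([0.24, 0.5, 0.74]),
    )
    @settings(deadline=None, max_examples=50)
    def test_choice_probability_decreasing_in_beta_on_ambiguous_trials(
        self, beta, alpha, amb
    ):
        sv_neutral = subjective_value(0.5, amb, 4.0, alpha, 0.0)
        sv_averse = subjective_value(0.5, amb, 4.0, alpha, beta)
        assert sv_averse < sv_neutral
        # probability ordering follows, up to logistic saturation at 1.0
        p_neutral = choice_probability(sv_neutral, 1.0, 2.0)
        p_averse = choice_probability(sv_averse, 1.0, 2.0)
        assert p_averse <= p_neutral

    def test_params_validation(self):
        with pytest.raises(ValueError):
            AgentParams(alpha=-1.0, beta=0.0, gamma=1.0)
        with pytest.raises(ValueError):
            AgentParams(alpha=1.0, beta=0.0, gamma=0.0)
        with pytest.raises(ValueError):
            AgentParams(alpha=1.0, beta=float("inf"), gamma=1.0)
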