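"""Language-based utility, softmax choice, dominance and agent draws."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import langgame as lg
from langgame.delta import CaseLabel
from langgame.utility import ACTIONS, Action

PAYOFFS = lg.ActionPayoffs(10, 5, 0)


def triple(z, h, a):
    return lg.SentimentTriple(s_zero=z, s_half=h, s_all=a)


score = st.floats(min_value=1.0, max_value=7.0, allow_nan=False)


class TestUtility:
    def test_additive_form_hand_example(self):
        params = lg.UtilityParams(lambda_sentiment=1.0)
        s = triple(2, 5, 5)
        assert lg.utility(PAYOFFS, s, params, Action.KEEP_ALL) == 12
        assert lg.utility(PAYOFFS, s, params, Action.GIVE_HALF) == 10
        assert lg.utility(PAYOFFS, s, params, Action.GIVE_ALL) == 5

    def test_zero_lambda_reduces_to_payoffs(self):
        params = lg.UtilityParams(lambda_sentiment=0.0)
        for action in ACTIONS:
            assert lg.utility(PAYOFFS, triple(3, 6, 2), params, action) == (
                PAYOFFS.of(action)
            )

    def test_equal_sentiments_preserve_payoff_order(self):
        params = lg.UtilityParams(lambda_sentiment=2.0)
        u = [lg.utility(PAYOFFS, triple(4, 4, 4), params, a) for a in ACTIONS]
        assert u[0] > u[1] > u[2]

    def test_missing_sentiment_errors(self):
        with pytest.raises(ValueError):
            lg.utility(
                PAYOFFS, triple(2, None, 6), lg.UtilityParams(), Action.GIVE_HALF
            )

    def test_invalid_payoff_order_rejected(self):
        with pytest.raises(ValueError):
            lg.ActionPayoffs(5, 10, 0)


class TestChoiceProbabilities:
    def test_equal_utilities_uniform(self):
        # lambda=2, sentiments chosen so pi + 2*s is constant across actions
        probs = lg.choice_probabilities(
            PAYOFFS, triple(1.0, 3.5, 6.0), lg.UtilityParams(lambda_sentiment=2.0)
        )
        assert probs.p_zero == pytest.approx(1 / 3)
        assert probs.p_half == pytest.approx(1 / 3)
        assert probs.p_all == pytest.approx(1 / 3)

    def test_low_temperature_concentrates_on_argmax(self):
        probs = lg.choice_probabilities(
            PAYOFFS,
            triple(2, 7, 3),
            lg.UtilityParams(lambda_sentiment=2.0, temperature=0.01),
        )
        assert probs.p_half > 0.999

    def test_payoff_monotone_when_lambda_zero(self):
        probs = lg.choice_probabilities(
            PAYOFFS, triple(5, 5, 5), lg.UtilityParams(lambda_sentiment=0.0)
        )
        assert probs.p_zero > probs.p_half > probs.p_all

    @given(z=score, h=score, a=score, lam=st.floats(0, 3), t=st.floats(0.1, 10))
    def test_simplex_and_positivity(self, z, h, a, lam, t):
        probs = lg.choice_probabilities(
            PAYOFFS, triple(z, h, a), lg.UtilityParams(lam, t)
        )
        arr = probs.as_array()
        assert (arr > 0).all()
        assert abs(arr.sum() - 1.0) < 1e-12

    @given(
        z=score,
        h=st.floats(1.0, 6.0),
        a=st.floats(1.0, 6.0),
        lam=st.floats(0.1, 3),
        t=st.floats(0.1, 5),
        bump=st.floats(0.01, 1.0),
    )
    @settings(max_examples=150)
    def test_monotone_comparative_statics(self, z, h, a, lam, t, bump):
        """Raising an action's sentiment never lowers its choice probability."""
        params = lg.UtilityParams(lam, t)
        base = lg.choice_probabilities(PAYOFFS, triple(z, h, a), params)
        up_half = lg.choice_probabilities(PAYOFFS, triple(z, h + bump, a), params)
        up_all = lg.choice_probabilities(PAYOFFS, triple(z, h, a + bump), params)
        assert up_half.p_half >= base.p_half - 1e-12
        assert up_all.p_all >= base.p_all - 1e-12


class TestDominance:
    def test_two_action_dilemma_flags(self):
        res = lg.dominance_analysis(PAYOFFS, triple(3.20, 5.50, 4.75))
        assert res.dominated == {
            Action.KEEP_ALL: False,
            Action.GIVE_HALF: False,
            Action.GIVE_ALL: True,
        }
        assert res.case is CaseLabel.TWO_ACTION_DILEMMA

    def test_selfish_dominant_flags(self):
        res = lg.dominance_analysis(PAYOFFS, triple(7, 1, 1))
        assert res.dominated[Action.GIVE_HALF] and res.dominated[Action.GIVE_ALL]
        assert not res.dominated[Action.KEEP_ALL]
        assert res.case is CaseLabel.SELFISH_DOMINANT

    def test_three_way_tension_nothing_dominated(self):
        res = lg.dominance_analysis(PAYOFFS, triple(1, 3, 7))
        assert not any(res.dominated.values())
        assert res.case is CaseLabel.THREE_WAY_TENSION

    def test_grid_consistency_with_classification(self):
        """Dominance structure and the three-case taxonomy agree on a
        half-point grid: no dominated action ⟺ three-way tension;
        the dilemma case always dominates give-all; the selfish case
        dominates both prosocial actions."""
        grid = [1.0 + 0.5 * i for i in range(13)]
        for z, h, a in itertools.product(grid, repeat=3):
            res = lg.dominance_analysis(PAYOFFS, triple(z, h, a))
            assert res.case is lg.classify_case(triple(z, h, a))
            assert not res.dominated[Action.KEEP_ALL]
            if not any(res.dominated.values()):
                assert res.case is CaseLabel.THREE_WAY_TENSION
            if res.case is CaseLabel.TWO_ACTION_DILEMMA:
                assert res.dominated[Action.GIVE_ALL]
            if res.case is CaseLabel.SELFISH_DOMINANT:
                assert res.dominated[Action.GIVE_HALF]
                assert res.dominated[Action.GIVE_ALL]


class TestSimulateAgents:
    def test_seed_determinism(self):
        args = (PAYOFFS, triple(2, 5, 6), lg.UtilityParams(), 5000, 42)
        assert lg.simulate_agents(*args).counts == lg.simulate_agents(*args).counts

    def test_dominant_selfish_action_suppresses_prosociality(self):
        sim = lg.simulate_agents(
            PAYOFFS,
            triple(7, 1, 1),
            lg.UtilityParams(lambda_sentiment=1.0, temperature=0.01),
            10_000,
            0,
        )
        assert sim.prosocial_rate < 0.01

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_frequencies_match_choice_probabilities(self, seed):
        """Empirical action frequencies fall within 5 binomial standard
        errors of the softmax probabilities."""
        params = lg.UtilityParams(lambda_sentiment=1.5, temperature=2.0)
        sents = triple(2.5, 5.5, 6.0)
        n = 10_000
        sim = lg.simulate_agents(PAYOFFS, sents, params, n, seed)
        probs = lg.choice_probabilities(PAYOFFS, sents, params).as_array()
        for action, p in zip(ACTIONS, probs):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(sim.counts[action] / n - p) < 5 * se

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            lg.simulate_agents(PAYOFFS, triple(2, 5, 6), lg.UtilityParams(), 0, 1)


def test_prosocial_rate_increases_with_delta_s():
    """The central behavioural hypothesis holds inside the model: across
    random sentiment triples at fixed payoffs and parameters, simulated
    prosocial rates rank-correlate positively with ΔS."""
    rng = np.random.default_rng(7)
    params = lg.UtilityParams(lambda_sentiment=1.0, temperature=2.0)
    deltas, rates = [], []
    for i in range(600):
        z, h, a = rng.uniform(1.0, 7.0, size=3)
        sents = triple(z, h, a)
        deltas.append(lg.delta_s(sents).value)
        rates.append(
            lg.simulate_agents(PAYOFFS, sents, params, 400, int(rng.integers(2**31))).prosocial_rate
        )
    rho = spearmanr(deltas, rates).statistic
    assert rho > 0.5
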