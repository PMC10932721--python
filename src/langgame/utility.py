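"""Language-based utility and stochastic choice over the three actions.

The model assumes a dictator considers only the three prominent actions
(keep all, give half, give all) and values each by its monetary payoff
plus the sentiment of its verbal description:

    U(a) = pi(a) + lambda * s(a)

with choice probabilities given by a softmax at temperature T:

    P(a) ∝ exp(U(a) / T).

The additive form and the softmax link are this package's modelling
choices: the underlying verbal argument fixes only that utility grows
in both payoff and sentiment, and that the probability of an action
grows with the sentiment of its description.  ``lambda`` converts
sentiment points (1–7 scale) into payoff units; ``T`` sets how noisy
choices are (T → 0 approaches strict maximization, large T approaches
uniform choice over the three actions).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .corpus import SentimentTriple
from .delta import CaseLabel, classify_case

__all__ = [
    "Action",
    "ActionPayoffs",
    "UtilityParams",
    "ChoiceDistribution",
    "DominanceResult",
    "AgentSimulation",
    "utility",
    "choice_probabilities",
    "dominance_analysis",
    "simulate_agents",
]


class Action(str, enum.Enum):
    KEEP_ALL = "keep_all"
    GIVE_HALF = "give_half"
    GIVE_ALL = "give_all"


ACTIONS = (Action.KEEP_ALL, Action.GIVE_HALF, Action.GIVE_ALL)


@dataclass(frozen=True)
class ActionPayoffs:
    """Dictator's monetary payoffs; strictly decreasing in generosity."""

    pi_zero: float = 10.0
    pi_half: float = 5.0
    pi_all: float = 0.0

    def __post_init__(self) -> None:
        if not (self.pi_zero > self.pi_half > self.pi_all >= 0):
            raise ValueError(
                "payoffs must satisfy pi_zero > pi_half > pi_all >= 0, got "
                f"({self.pi_zero}, {self.pi_half}, {self.pi_all})"
            )

    def of(self, action: Action) -> float:
        return {
            Action.KEEP_ALL: self.pi_zero,
            Action.GIVE_HALF: self.pi_half,
            Action.GIVE_ALL: self.pi_all,
        }[action]


@dataclass(frozen=True)
class UtilityParams:
    """Sentiment weight (payoff units per sentiment point) and choice noise."""

    lambda_sentiment: float = 1.0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_sentiment < 0:
            raise ValueError("lambda_sentiment must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class ChoiceDistribution:
    p_zero: float
    p_half: float
    p_all: float

    @property
    def prosocial(self) -> float:
        """Probability of a prosocial choice (give half or give all)."""
        return self.p_half + self.p_all

    def as_array(self) -> np.ndarray:
        return np.array([self.p_zero, self.p_half, self.p_all])


def _sentiment_of(sentiments: SentimentTriple, action: Action) -> float:
    value = {
        Action.KEEP_ALL: sentiments.s_zero,
        Action.GIVE_HALF: sentiments.s_half,
        Action.GIVE_ALL: sentiments.s_all,
    }[action]
    if value is None:
        raise ValueError(f"no sentiment score for action {action.value!r}")
    return value


def utility(
    payoffs: ActionPayoffs,
    sentiments: SentimentTriple,
    params: UtilityParams,
    action: Action,
) -> float:
    """Additive language-based utility pi(a) + lambda * s(a)."""
    return payoffs.of(action) + params.lambda_sentiment * _sentiment_of(
        sentiments, action
    )


def choice_probabilities(
    payoffs: ActionPayoffs,
    sentiments: SentimentTriple,
    params: UtilityParams,
) -> ChoiceDistribution:
    """Softmax choice over the three actions.

    Probabilities are strictly positive, sum to one, and are invariant
    to adding a constant to every utility.
    """
    u = np.array([utility(payoffs, sentiments, params, a) for a in ACTIONS])
    p = softmax(u / params.temperature)
    return ChoiceDistribution(p_zero=float(p[0]), p_half=float(p[1]), p_all=float(p[2]))


@dataclass(frozen=True)
class DominanceResult:
    """Per-action dominance flags and the resulting case label."""

    dominated: dict[Action, bool]
    case: CaseLabel


def dominance_analysis(
    payoffs: ActionPayoffs, sentiments: SentimentTriple
) -> DominanceResult:
    """Flag dominated actions and label the case.

    Action A is dominated by B when B is strictly better on one of
    (payoff, sentiment) and at least as good on the other.  A dominated
    action is never chosen by a strict payoff+sentiment maximizer,
    whatever the weight lambda.
    """
    if sentiments.s_half is None:
        raise ValueError("dominance analysis requires all three sentiment scores")
    coords = {
        a: (payoffs.of(a), _sentiment_of(sentiments, a)) for a in ACTIONS
    }
    dominated: dict[Action, bool] = {}
    for a in ACTIONS:
        pa, sa = coords[a]
        dominated[a] = any(
            (pb > pa and sb >= sa) or (pb >= pa and sb > sa)
            for b, (pb, sb) in coords.items()
            if b is not a
        )
    return DominanceResult(dominated=dominated, case=classify_case(sentiments))


@dataclass(frozen=True)
class AgentSimulation:
    counts: dict[Action, int]
    n_agents: int
    prosocial_rate: float


def simulate_agents(
    payoffs: ActionPayoffs,
    sentiments: SentimentTriple,
    params: UtilityParams,
    n_agents: int,
    seed: int | np.random.Generator,
) -> AgentSimulation:
    """Draw ``n_agents`` independent softmax choices and tally them.

    The prosocial rate is the share of agents giving half or all.  A
    fixed integer seed reproduces the counts exactly.
    """
    if n_agents <= 0:
        raise ValueError("n_agents must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    probs = choice_probabilities(payoffs, sentiments, params)
    counts = rng.multinomial(n_agents, probs.as_array())
    return AgentSimulation(
        counts={a: int(c) for a, c in zip(ACTIONS, counts)},
        n_agents=n_agents,
        prosocial_rate=float(counts[1] + counts[2]) / n_agents,
    )
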