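"""The piecewise sentiment statistic ΔS and the three-case taxonomy.

ΔS measures the sentiment advantage of the prosocial action
descriptions over the selfish one in a dictator-game instruction:

    ΔS = S_half − S_zero                 if S_all ≤ S_half,
    ΔS = (S_all + S_half)/2 − S_zero     if S_all > S_half.

The case split reflects the underlying choice structure.  When the
equal split carries the highest sentiment, giving everything is
dominated (worse on both payoff and sentiment) and the dilemma is
two-way, so only S_half matters for the prosocial side.  When giving
everything carries the highest sentiment, all three actions are in
tension and the prosocial pull is the average sentiment of the two
prosocial actions.

For two-action designs with no explicit equal-split option (``s_half``
absent) this module applies the degenerate two-action rule
ΔS = S_all − S_zero.  That rule is this package's extension: the
published definition is silent on binary variants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .corpus import Corpus, SentimentTriple

__all__ = [
    "Branch",
    "CaseLabel",
    "DeltaSValue",
    "DescriptiveStats",
    "delta_s",
    "classify_case",
    "describe_corpus",
]


class Branch(str, enum.Enum):
    """Which branch of the piecewise ΔS definition applied."""

    HALF = "half_branch"  # s_all <= s_half: ΔS = s_half - s_zero
    AVERAGED = "averaged_branch"  # s_all > s_half: ΔS = (s_all+s_half)/2 - s_zero
    TWO_ACTION = "two_action_branch"  # s_half absent: ΔS = s_all - s_zero


class CaseLabel(str, enum.Enum):
    """Three-case taxonomy of a sentiment triple.

    ``SELFISH_DOMINANT``: keeping everything is strictly highest in
    sentiment, so it maximizes payoff and sentiment simultaneously.
    ``TWO_ACTION_DILEMMA``: the equal split carries the (weakly) highest
    prosocial sentiment; giving everything is dominated and the conflict
    is payoff-vs-sentiment between keeping all and giving half.
    ``THREE_WAY_TENSION``: giving everything is strictly highest in
    sentiment and no action is best on both coordinates.
    """

    SELFISH_DOMINANT = "selfish_dominant"
    TWO_ACTION_DILEMMA = "two_action_dilemma"
    THREE_WAY_TENSION = "three_way_tension"


@dataclass(frozen=True)
class DeltaSValue:
    value: float
    branch: Branch

    def __float__(self) -> float:
        return self.value


def delta_s(sentiments: SentimentTriple) -> DeltaSValue:
    """Compute ΔS for one condition.

    Examples
    --------
    >>> from langgame.corpus import SentimentTriple
    >>> delta_s(SentimentTriple(s_zero=3.20, s_half=5.50, s_all=4.75)).value
    2.3
    >>> delta_s(SentimentTriple(s_zero=2.75, s_half=5.50, s_all=6.50)).value
    3.25
    """
    s = sentiments
    if s.s_half is None:
        return DeltaSValue(s.s_all - s.s_zero, Branch.TWO_ACTION)
    if s.s_all <= s.s_half:
        return DeltaSValue(s.s_half - s.s_zero, Branch.HALF)
    return DeltaSValue((s.s_all + s.s_half) / 2.0 - s.s_zero, Branch.AVERAGED)


def classify_case(sentiments: SentimentTriple) -> CaseLabel:
    """Assign the three-case label to a full sentiment triple.

    Ties break towards the more prosocial label: a selfish score merely
    tied with the maximum does not make the selfish action dominant, and
    a half/all tie counts as the two-action dilemma, mirroring the weak
    inequality ``S_all <= S_half`` in the ΔS definition.

    Raises
    ------
    ValueError
        If ``s_half`` is absent — the taxonomy compares all three actions.
    """
    s = sentiments
    if s.s_half is None:
        raise ValueError("classify_case requires all three sentiment scores")
    if s.s_zero > s.s_half and s.s_zero > s.s_all:
        return CaseLabel.SELFISH_DOMINANT
    if s.s_all <= s.s_half:
        return CaseLabel.TWO_ACTION_DILEMMA
    return CaseLabel.THREE_WAY_TENSION


@dataclass(frozen=True)
class DescriptiveStats:
    """Per-action mean / sample s.d. / count over a corpus."""

    mean_s_zero: float
    mean_s_half: Optional[float]
    mean_s_all: float
    sd_s_zero: Optional[float]
    sd_s_half: Optional[float]
    sd_s_all: Optional[float]
    n_s_zero: int
    n_s_half: int
    n_s_all: int

    def __str__(self) -> str:
        def f(x: Optional[float]) -> str:
            return "  --  " if x is None else f"{x:6.3f}"

        return (
            "         s_zero  s_half  s_all\n"
            f"mean     {f(self.mean_s_zero)}  {f(self.mean_s_half)}  {f(self.mean_s_all)}\n"
            f"s.d.     {f(self.sd_s_zero)}  {f(self.sd_s_half)}  {f(self.sd_s_all)}\n"
            f"n        {self.n_s_zero:6d}  {self.n_s_half:6d}  {self.n_s_all:6d}"
        )


def _mean_sd(values: list[float]) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def describe_corpus(corpus: Corpus) -> DescriptiveStats:
    """Per-action mean and sample (n−1) standard deviation.

    Absent ``s_half`` scores simply do not contribute, so the per-action
    counts may differ.  Values are exact; display rounding is left to
    the caller.
    """
    zeros = [r.sentiments.s_zero for r in corpus]
    halves = [r.sentiments.s_half for r in corpus if r.sentiments.s_half is not None]
    alls = [r.sentiments.s_all for r in corpus]
    mz, sz = _mean_sd(zeros)
    mh, sh = _mean_sd(halves)
    ma, sa = _mean_sd(alls)
    assert mz is not None and ma is not None  # corpus is non-empty
    return DescriptiveStats(
        mean_s_zero=mz,
        mean_s_half=mh,
        mean_s_all=ma,
        sd_s_zero=sz,
        sd_s_half=sh,
        sd_s_all=sa,
        n_s_zero=len(zeros),
        n_s_half=len(halves),
        n_s_all=len(alls),
    )
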