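"""Synthetic study corpora with known ground truth.

The generator inverts the two-stage estimation pipeline: it draws
condition-level sentiment triples, computes ΔS, and produces prosocial
rates from a linear model with study-level random slopes,

    rate = alpha + (beta + u_k) * ΔS + eps,   u_k ~ N(0, tau^2),
    eps ~ N(0, sigma^2),

optionally observed as a binomial proportion of ``n_participants``
draws.  Heterogeneity enters as a random slope because the downstream
meta-analysis pools slopes, so tau^2 is exactly what its
between-study variance estimate targets.

Sentiments are drawn per action from independent normals truncated to
the 1–7 scale, with default location/scale equal to the observed
moments of the bundled 61-condition corpus.  An agent-based mode
replaces the linear outcome model with softmax choices from the
language-based utility model, grounding the same regression structure
in individual behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.stats import truncnorm

from .corpus import (
    SCALE_MAX,
    SCALE_MIN,
    ConditionRecord,
    Corpus,
    SentimentTriple,
)
from .delta import delta_s
from .utility import ActionPayoffs, UtilityParams, choice_probabilities, simulate_agents

__all__ = [
    "SentimentMoments",
    "SyntheticConfig",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_corpus_agents",
]


class SentimentMoments(BaseModel):
    """Parent-normal location/scale per action before truncation to [1, 7].

    Defaults are the per-action mean and s.d. of the bundled corpus
    (selfish descriptions score low, prosocial ones high).
    """

    model_config = ConfigDict(frozen=True)

    mean_s_zero: float = 2.600
    sd_s_zero: float = Field(default=0.627, gt=0)
    mean_s_half: float = 5.233
    sd_s_half: float = Field(default=0.929, gt=0)
    mean_s_all: float = 5.369
    sd_s_all: float = Field(default=1.010, gt=0)


class SyntheticConfig(BaseModel):
    """Ground-truth parameters of a generated corpus.

    Defaults mirror the estimation setting the pipeline is validated
    under: 11 pooled studies of 5 conditions each, a true slope of 0.08
    prosocial-rate units per ΔS point, modest slope heterogeneity
    (tau = 0.02) and condition noise (sigma = 0.02), with exact latent
    rates reported (``n_participants = 0``).
    """

    model_config = ConfigDict(frozen=True)

    k_studies: int = Field(default=11, gt=0)
    conditions_per_study: int = Field(default=5, ge=3)
    alpha: float = 0.3
    beta: float = 0.08
    tau: float = Field(default=0.02, ge=0)
    sigma: float = Field(default=0.02, ge=0)
    n_participants: int = Field(default=0, ge=0)
    include_half: bool = True
    sentiment_moments: SentimentMoments = SentimentMoments()
    max_rate_retries: int = Field(default=100, gt=0)
    seed: int = 0


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters plus the realized per-study effects."""

    config: SyntheticConfig
    study_effects: dict[str, float]  # u_k per study
    delta_s: dict[tuple[str, str], float]
    latent_rates: dict[tuple[str, str], float]
    n_clamped: int = 0
    lambda_sentiment: Optional[float] = None
    temperature: Optional[float] = None


@dataclass(frozen=True)
class SyntheticCorpus:
    corpus: Corpus
    truth: SyntheticTruth


def _draw_sentiment(
    rng: np.random.Generator, mean: float, sd: float
) -> float:
    a = (SCALE_MIN - mean) / sd
    b = (SCALE_MAX - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_triple(
    rng: np.random.Generator, m: SentimentMoments, include_half: bool
) -> SentimentTriple:
    return SentimentTriple(
        s_zero=_draw_sentiment(rng, m.mean_s_zero, m.sd_s_zero),
        s_half=(
            _draw_sentiment(rng, m.mean_s_half, m.sd_s_half)
            if include_half
            else None
        ),
        s_all=_draw_sentiment(rng, m.mean_s_all, m.sd_s_all),
    )


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a corpus under the random-slope linear outcome model.

    Latent rates outside [0, 1] trigger a redraw of the condition noise
    (up to ``max_rate_retries``); a draw still outside after the retries
    is clamped to the boundary and counted in ``truth.n_clamped``.  A
    config that forces every draw out of range (all conditions clamped)
    raises a ``ValueError``.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ConditionRecord] = []
    effects: dict[str, float] = {}
    deltas: dict[tuple[str, str], float] = {}
    latents: dict[tuple[str, str], float] = {}
    n_clamped = 0
    for k in range(config.k_studies):
        study = f"synthetic study {k + 1:02d}"
        u_k = float(rng.normal(0.0, config.tau)) if config.tau > 0 else 0.0
        effects[study] = u_k
        for j in range(config.conditions_per_study):
            label = f"condition {j + 1}"
            triple = _draw_triple(rng, config.sentiment_moments, config.include_half)
            d = delta_s(triple).value
            systematic = config.alpha + (config.beta + u_k) * d
            rate, clamped = _draw_rate(rng, systematic, config)
            n_clamped += clamped
            deltas[(study, label)] = d
            latents[(study, label)] = rate
            observed = _observe(rng, rate, config.n_participants)
            records.append(
                ConditionRecord(
                    study_id=study,
                    condition_label=label,
                    country="Synthetica",
                    sentiments=triple,
                    prosocial_rate=observed,
                    n_participants=config.n_participants or None,
                )
            )
    if n_clamped == len(records):
        raise ValueError(
            "every generated rate fell outside [0, 1]; the config forces "
            "impossible rates — adjust alpha/beta/tau or the sentiment moments"
        )
    corpus = Corpus(
        records=tuple(records),
        provenance=f"synthetic corpus (seed={config.seed})",
    )
    return SyntheticCorpus(
        corpus=corpus,
        truth=SyntheticTruth(
            config=config,
            study_effects=effects,
            delta_s=deltas,
            latent_rates=latents,
            n_clamped=n_clamped,
        ),
    )


def _draw_rate(
    rng: np.random.Generator, systematic: float, config: SyntheticConfig
) -> tuple[float, int]:
    """Systematic rate plus noise, resampled into [0,1]; clamp as last resort."""
    for _ in range(config.max_rate_retries):
        rate = systematic + (
            float(rng.normal(0.0, config.sigma)) if config.sigma > 0 else 0.0
        )
        if 0.0 <= rate <= 1.0:
            return rate, 0
    return min(1.0, max(0.0, rate)), 1


def _observe(
    rng: np.random.Generator, rate: float, n_participants: int
) -> float:
    if n_participants <= 0:
        return rate
    return float(rng.binomial(n_participants, rate)) / n_participants


def generate_corpus_agents(
    config: SyntheticConfig,
    payoffs: ActionPayoffs = ActionPayoffs(),
    params: UtilityParams = UtilityParams(),
) -> SyntheticCorpus:
    """Agent-based variant: rates come from softmax-choosing agents.

    Sentiment generation is identical to :func:`generate_corpus`, but
    each condition's prosocial rate is the share of ``n_participants``
    simulated agents choosing give-half or give-all under the
    language-based utility model (the exact choice probability when
    ``n_participants`` is 0).  The truth records the utility parameters
    instead of a regression slope; ``alpha``/``beta``/``tau``/``sigma``
    are ignored.  Requires a full triple per condition.
    """
    if not config.include_half:
        raise ValueError("agent-based generation requires all three actions")
    rng = np.random.default_rng(config.seed)
    records: list[ConditionRecord] = []
    deltas: dict[tuple[str, str], float] = {}
    latents: dict[tuple[str, str], float] = {}
    for k in range(config.k_studies):
        study = f"synthetic study {k + 1:02d}"
        for j in range(config.conditions_per_study):
            label = f"condition {j + 1}"
            triple = _draw_triple(rng, config.sentiment_moments, True)
            deltas[(study, label)] = delta_s(triple).value
            p = choice_probabilities(payoffs, triple, params).prosocial
            latents[(study, label)] = p
            if config.n_participants > 0:
                sim = simulate_agents(
                    payoffs, triple, params, config.n_participants, rng
                )
                observed = sim.prosocial_rate
            else:
                observed = p
            records.append(
                ConditionRecord(
                    study_id=study,
                    condition_label=label,
                    country="Synthetica",
                    sentiments=triple,
                    prosocial_rate=observed,
                    n_participants=config.n_participants or None,
                )
            )
    corpus = Corpus(
        records=tuple(records),
        provenance=f"synthetic agent-based corpus (seed={config.seed})",
    )
    return SyntheticCorpus(
        corpus=corpus,
        truth=SyntheticTruth(
            config=config,
            study_effects={},
            delta_s=deltas,
            latent_rates=latents,
            lambda_sentiment=params.lambda_sentiment,
            temperature=params.temperature,
        ),
    )
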