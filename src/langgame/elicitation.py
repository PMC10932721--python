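"""Sentiment-elicitation prompts, scorer-backend contract and mock.

Sentiment scores are elicited by showing a scorer (originally a chat
LLM) the complete experimental instructions of a dictator-game
condition, then asking it to estimate the average 1–7 sentiment rating
a named population would give to each prominent action, described *in
the instruction's own words*.

Four protocol variants are supported:

``baseline``
    population of 1000 people in the experiment's country; fresh
    conversation per condition (no cross-condition contamination).
``usa_population``
    the country is replaced by the USA.
``unspecified_size``
    the population size is omitted.
``single_chat``
    baseline wording, but one running conversation per study: the
    transcript persists across that study's conditions.

The backend contract is plain text-in/text-out.  A deterministic mock
backend (prompt-hash scoring) makes the whole pipeline runnable and
testable offline; reproducing any particular live model's scores is a
non-goal — the bundled corpus, not re-elicitation, is the reference
dataset.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

from .corpus import SCALE_MAX, SCALE_MIN, SentimentTriple
from .utility import Action

__all__ = [
    "Variant",
    "PromptSpec",
    "ElicitationResult",
    "ElicitationError",
    "ScoreParseError",
    "ScorerBackend",
    "MockBackend",
    "build_prompt",
    "parse_score",
    "elicit_condition",
    "mock_backend",
]

VARIANTS = ("baseline", "usa_population", "unspecified_size", "single_chat")
Variant = str


@dataclass(frozen=True)
class PromptSpec:
    """Everything needed to build the three per-action prompts.

    ``action_phrases`` maps each action to the exact wording the source
    instruction uses for it; the half phrase is absent in two-action
    designs.
    """

    instruction_text: str
    country: str
    action_phrases: dict[Action, str]
    variant: Variant = "baseline"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for action, phrase in self.action_phrases.items():
            if not phrase.strip():
                raise ValueError(f"empty action phrase for {action.value!r}")
        for required in (Action.KEEP_ALL, Action.GIVE_ALL):
            if required not in self.action_phrases:
                raise ValueError(f"missing action phrase for {required.value!r}")


@dataclass(frozen=True)
class ElicitationResult:
    sentiments: SentimentTriple
    raw_replies: dict[Action, str]
    backend_id: str


class ElicitationError(RuntimeError):
    """Backend failure after the configured retries; carries the prompt."""

    def __init__(self, message: str, prompt: str):
        super().__init__(message)
        self.prompt = prompt


class ScoreParseError(ValueError):
    pass


class ScorerBackend(Protocol):
    """Synchronous text-in/text-out scorer.

    ``reset`` starts a fresh conversation; stateless backends may make
    it a no-op.  ``backend_id`` identifies the scorer in result logs.
    """

    backend_id: str

    def reply(self, prompt: str) -> str: ...

    def reset(self) -> None: ...


_POPULATION_BASELINE = (
    "Now imagine that there is a population of 1000 people living in "
    "{country}. What do you think the average response to the following "
    "questions would be? (Please return an exact number with two decimal "
    "digits)."
)
_POPULATION_UNSPECIFIED = (
    "Now imagine that there is a population living in {country}. What do "
    "you think the average response to the following questions would be? "
    "(Please return an exact number with two decimal digits)."
)
_QUESTION = (
    "How negative or positive is the action of ‘{action}’ on a "
    "1–7 scale, with 1 being ‘very negative’ and 7 being "
    "‘very positive’?"
)


def build_prompt(spec: PromptSpec, action: Action) -> str:
    """Render the elicitation prompt for one action.

    Pure: identical specs yield identical text.  The population
    sentence depends on the variant; ``single_chat`` changes
    conversation handling, not wording.
    """
    if action not in spec.action_phrases:
        raise ValueError(f"spec has no phrase for action {action.value!r}")
    country = "the USA" if spec.variant == "usa_population" else spec.country
    population = (
        _POPULATION_UNSPECIFIED
        if spec.variant == "unspecified_size"
        else _POPULATION_BASELINE
    ).format(country=country)
    question = _QUESTION.format(action=spec.action_phrases[action])
    return (
        "Please read the following decision problem:\n"
        f"{spec.instruction_text.strip()}\n"
        f"{population}\n"
        f"{question}"
    )


_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?")


def parse_score(reply: str) -> float:
    """Extract the score from a backend reply.

    Takes the FIRST decimal literal in the text (bare or embedded in a
    sentence) — a deterministic tie-break for chatty replies; the raw
    reply is kept alongside for audit.
    """
    if not reply or not reply.strip():
        raise ScoreParseError("empty reply")
    m = _NUMBER_RE.search(reply)
    if m is None:
        raise ScoreParseError(f"no number found in reply: {reply!r}")
    value = float(m.group())
    if not (SCALE_MIN <= value <= SCALE_MAX):
        raise ScoreParseError(f"score {value} outside the 1-7 scale")
    return value


@dataclass
class MockBackend:
    """Deterministic offline scorer: hash of (seed, transcript, prompt).

    Scores are uniform-ish over [1, 7] with exactly two decimals.  The
    transcript makes single-chat elicitation genuinely history
    dependent while remaining reproducible; ``reset`` clears it.
    """

    seed: int = 0
    transcript: list[str] = field(default_factory=list)

    @property
    def backend_id(self) -> str:
        return f"mock(seed={self.seed})"

    def reply(self, prompt: str) -> str:
        digest = hashlib.sha256(
            "\x1e".join([str(self.seed), *self.transcript, prompt]).encode("utf-8")
        ).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64
        score = round(1.0 + 6.0 * u, 2)
        reply = f"{score:.2f}"
        self.transcript.extend([prompt, reply])
        return reply

    def reset(self) -> None:
        self.transcript.clear()


def mock_backend(seed: int = 0) -> MockBackend:
    return MockBackend(seed=seed)


def elicit_condition(
    spec: PromptSpec,
    backend: ScorerBackend,
    retries: int = 3,
    log: Optional[Callable[[str], None]] = None,
) -> ElicitationResult:
    """Elicit one score per present action.

    Under every variant except ``single_chat`` the backend conversation
    is reset before the condition, so no state leaks between
    conditions.  Backend failures (exceptions or unparseable replies)
    are retried up to ``retries`` times per prompt before raising
    :class:`ElicitationError`.
    """
    if spec.variant != "single_chat":
        backend.reset()
    scores: dict[Action, float] = {}
    replies: dict[Action, str] = {}
    for action in (Action.KEEP_ALL, Action.GIVE_HALF, Action.GIVE_ALL):
        if action not in spec.action_phrases:
            continue
        prompt = build_prompt(spec, action)
        last_error: Exception | None = None
        for attempt in range(1 + retries):
            try:
                reply = backend.reply(prompt)
                scores[action] = parse_score(reply)
                replies[action] = reply
                if log is not None:
                    log(f"[{backend.backend_id}] {action.value}: {reply!r}")
                break
            except Exception as exc:  # noqa: BLE001 - backend is third-party code
                last_error = exc
        else:
            raise ElicitationError(
                f"backend {backend.backend_id} failed for {action.value} "
                f"after {1 + retries} attempts: {last_error}",
                prompt,
            )
    return ElicitationResult(
        sentiments=SentimentTriple(
            s_zero=scores[Action.KEEP_ALL],
            s_half=scores.get(Action.GIVE_HALF),
            s_all=scores[Action.GIVE_ALL],
        ),
        raw_replies=replies,
        backend_id=backend.backend_id,
    )
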