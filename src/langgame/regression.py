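"""Per-study OLS of prosocial rate on ΔS, with eligibility screening.

The estimation pipeline is deliberately two-stage: within each study a
simple linear regression (with intercept) relates the prosocial rate of
each condition to that condition's ΔS; the per-study slopes and their
standard errors then feed the meta-analytic pooling stage.  Studies
differ in population, stakes and procedure, so only within-study
contrasts identify the slope.

A study needs at least three conditions — two points determine a unique
line and leave no residual degrees of freedom for a standard error —
and nonzero ΔS variance.  A zero-residual (perfectly collinear) fit is
likewise ineligible for pooling, because its inverse-variance weight
would be infinite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .corpus import MIN_CONDITIONS_PER_STUDY, Corpus
from .delta import delta_s

__all__ = ["StudyStatus", "StudyEffect", "fit_study", "screen_studies"]

#: ΔS spreads below this are treated as zero variance (scores carry two
#: decimals, so real spreads are never this small).
_VAR_EPS = 1e-12


class StudyStatus(str, enum.Enum):
    OK = "ok"
    DROPPED_TOO_FEW = "dropped_too_few"
    DROPPED_ZERO_VARIANCE = "dropped_zero_variance"
    DROPPED_ZERO_RESIDUAL = "dropped_zero_residual"


@dataclass(frozen=True)
class StudyEffect:
    """Slope of prosocial rate on ΔS for one study, with its SE."""

    study_id: str
    slope: Optional[float]
    se: Optional[float]
    k_conditions: int
    status: StudyStatus

    @property
    def poolable(self) -> bool:
        return self.status is StudyStatus.OK


def fit_study(
    points: Sequence[tuple[float, float]], study_id: str = ""
) -> StudyEffect:
    """Closed-form simple OLS of y (rate) on x (ΔS).

    slope = Σ(x−x̄)(y−ȳ) / Σ(x−x̄)²,
    se    = sqrt( (SSE / (k−2)) / Σ(x−x̄)² ).

    Degenerate inputs are reported through ``status`` rather than
    raised: fewer than three points, zero ΔS variance, or a perfect fit
    (zero residual sum of squares, hence se = 0).
    """
    k = len(points)
    if k < MIN_CONDITIONS_PER_STUDY:
        return StudyEffect(study_id, None, None, k, StudyStatus.DROPPED_TOO_FEW)
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    xbar = sum(xs) / k
    ybar = sum(ys) / k
    sxx = sum((x - xbar) ** 2 for x in xs)
    if sxx <= _VAR_EPS:
        return StudyEffect(study_id, None, None, k, StudyStatus.DROPPED_ZERO_VARIANCE)
    sxy = sum((x - xbar) * (y - ybar) for x, y in points)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    sse = sum((y - (intercept + slope * x)) ** 2 for x, y in points)
    se = math.sqrt((sse / (k - 2)) / sxx)
    if se <= 0.0 or not math.isfinite(se):
        return StudyEffect(
            study_id, slope, 0.0, k, StudyStatus.DROPPED_ZERO_RESIDUAL
        )
    return StudyEffect(study_id, slope, se, k, StudyStatus.OK)


def screen_studies(
    corpus: Corpus, require_rate: bool = True
) -> list[StudyEffect]:
    """Fit every study in the corpus and assign eligibility statuses.

    Conditions without a prosocial rate are excluded from their study's
    fit (outcome joins are external to the score table); with
    ``require_rate`` they raise instead.
    """
    effects: list[StudyEffect] = []
    for study_id, recs in corpus.by_study().items():
        points: list[tuple[float, float]] = []
        for rec in recs:
            if rec.prosocial_rate is None:
                if require_rate:
                    raise ValueError(
                        f"condition ({rec.study_id!r}, {rec.condition_label!r}) "
                        "has no prosocial_rate"
                    )
                continue
            points.append((delta_s(rec.sentiments).value, rec.prosocial_rate))
        effects.append(fit_study(points, study_id=study_id))
    return effects
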