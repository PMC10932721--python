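"""Fixed-effects and DerSimonian–Laird random-effects pooling.

Study slopes b_i with standard errors se_i are combined by inverse-
variance weighting.  Fixed-effects pooling uses w_i = 1/se_i² and
assumes a single common effect.  The DerSimonian–Laird random-effects
estimator first measures excess dispersion with Cochran's

    Q = Σ w_i (b_i − b_FE)²,

then moment-estimates the between-study variance

    τ² = max(0, (Q − df) / C),   C = Σw_i − Σw_i²/Σw_i,   df = k − 1,

and re-pools with starred weights w*_i = 1/(se_i² + τ²).  I² =
max(0, (Q − df)/Q)·100 expresses the share of total variation due to
heterogeneity.  Confidence intervals are Wald-normal at the fixed
critical value 1.959964; when τ̂² = 0 the random-effects result reduces
exactly to the fixed-effects one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from scipy.stats import norm

from .corpus import Corpus
from .regression import StudyEffect, StudyStatus, screen_studies

__all__ = ["Z_CRIT", "MetaResult", "ForestRow", "pool_fixed", "pool_random_dl", "run_meta", "MetaRun"]

#: 97.5% normal quantile, fixed for bit-stable confidence intervals.
Z_CRIT = 1.959964


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float
    tau2: float
    i2: float
    method: Literal["fixed", "random_dl"]
    weights: dict[str, float]  # normalized, sum to 1
    k: int


@dataclass(frozen=True)
class ForestRow:
    row_id: str  # study_id or "overall"
    effect: float
    ci_low: float
    ci_high: float
    weight: float


def _poolable(effects: Sequence[StudyEffect]) -> list[StudyEffect]:
    ok = [e for e in effects if e.status is StudyStatus.OK]
    if not ok:
        raise ValueError("no poolable study effects (empty pooling set)")
    for e in ok:
        assert e.slope is not None and e.se is not None and e.se > 0
    return ok


def _pool(effects: Sequence[StudyEffect], tau2: float) -> tuple[float, float, dict[str, float]]:
    w = {e.study_id: 1.0 / (e.se**2 + tau2) for e in effects}  # type: ignore[operator]
    total = sum(w.values())
    pooled = sum(w[e.study_id] * e.slope for e in effects) / total  # type: ignore[operator]
    se = math.sqrt(1.0 / total)
    weights = {sid: wi / total for sid, wi in w.items()}
    return pooled, se, weights


def _q_statistic(effects: Sequence[StudyEffect]) -> float:
    pooled_fe, _, _ = _pool(effects, 0.0)
    return sum((1.0 / e.se**2) * (e.slope - pooled_fe) ** 2 for e in effects)  # type: ignore[operator]


def _result(
    effects: Sequence[StudyEffect],
    tau2: float,
    q: float,
    method: Literal["fixed", "random_dl"],
) -> MetaResult:
    pooled, se, weights = _pool(effects, tau2)
    z = pooled / se
    p = 2.0 * float(norm.sf(abs(z)))
    df = len(effects) - 1
    i2 = 0.0 if q <= 0.0 else max(0.0, (q - df) / q) * 100.0
    return MetaResult(
        pooled=pooled,
        se=se,
        ci_low=pooled - Z_CRIT * se,
        ci_high=pooled + Z_CRIT * se,
        z=z,
        p=p,
        q=q,
        tau2=tau2,
        i2=i2,
        method=method,
        weights=weights,
        k=len(effects),
    )


def pool_fixed(effects: Sequence[StudyEffect]) -> MetaResult:
    """Inverse-variance fixed-effects pooling of the OK studies."""
    ok = _poolable(effects)
    return _result(ok, 0.0, _q_statistic(ok), "fixed")


def pool_random_dl(effects: Sequence[StudyEffect]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of the OK studies."""
    ok = _poolable(effects)
    q = _q_statistic(ok)
    df = len(ok) - 1
    if df == 0:
        tau2 = 0.0
    else:
        w = [1.0 / e.se**2 for e in ok]  # type: ignore[operator]
        c = sum(w) - sum(wi**2 for wi in w) / sum(w)
        tau2 = max(0.0, (q - df) / c)
    return _result(ok, tau2, q, "random_dl")


@dataclass(frozen=True)
class MetaRun:
    """Full pooling run: result, forest table and the drop log."""

    result: MetaResult
    forest: list[ForestRow]
    effects: list[StudyEffect]
    dropped: dict[str, str] = field(default_factory=dict)  # study_id -> reason


def run_meta(
    corpus: Corpus, method: Literal["fixed", "random"] = "random"
) -> MetaRun:
    """Screen studies, pool the eligible slopes, and build the forest.

    Every condition in the corpus must carry a prosocial rate.  Dropped
    studies appear in the drop log with their reason; if all studies
    drop, the error names each one.
    """
    effects = screen_studies(corpus)
    dropped = {
        e.study_id: e.status.value
        for e in effects
        if e.status is not StudyStatus.OK
    }
    try:
        result = (
            pool_fixed(effects) if method == "fixed" else pool_random_dl(effects)
        )
    except ValueError:
        reasons = "; ".join(f"{sid}: {why}" for sid, why in dropped.items())
        raise ValueError(f"all studies dropped from pooling ({reasons})") from None
    forest: list[ForestRow] = []
    for e in effects:
        if e.status is not StudyStatus.OK:
            continue
        assert e.slope is not None and e.se is not None
        forest.append(
            ForestRow(
                row_id=e.study_id,
                effect=e.slope,
                ci_low=e.slope - Z_CRIT * e.se,
                ci_high=e.slope + Z_CRIT * e.se,
                weight=result.weights[e.study_id],
            )
        )
    forest.append(
        ForestRow(
            row_id="overall",
            effect=result.pooled,
            ci_low=result.ci_low,
            ci_high=result.ci_high,
            weight=1.0,
        )
    )
    return MetaRun(result=result, forest=forest, effects=effects, dropped=dropped)
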