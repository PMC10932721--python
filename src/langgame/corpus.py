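"""Condition-level corpus model, validation and file I/O.

A *corpus* is an ordered collection of dictator-game experimental
conditions.  Each condition carries the sentiment scores that a scorer
(human raters or a large language model) attached to the verbal
descriptions of the three prominent actions — keeping the whole
endowment, giving half, and giving everything — on a 1–7 scale
(1 = very negative, 7 = very positive), plus optional behavioural
outcome data (prosocial rate and sample size).

The package ships a bundled corpus of 61 conditions from 12 published
dictator-game studies (:func:`packaged_fixture`), the dataset used
throughout the documentation and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "SentimentTriple",
    "ConditionRecord",
    "Corpus",
    "ValidationReport",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "validate_corpus",
    "packaged_fixture",
    "CSV_COLUMNS",
]

#: Canonical column order of the CSV interchange format.  Empty string
#: denotes an absent value.
CSV_COLUMNS = [
    "study_id",
    "condition_label",
    "country",
    "s_zero",
    "s_half",
    "s_all",
    "prosocial_rate",
    "n_participants",
]

SCALE_MIN = 1.0
SCALE_MAX = 7.0


class CorpusFormatError(ValueError):
    """Raised when a corpus file cannot be parsed or fails validation."""


class SentimentTriple(BaseModel):
    """Sentiment scores of the three prominent dictator-game actions.

    ``s_half`` may be absent: some designs (binary dictator variants)
    offer no explicit equal-split option, so no half phrase exists to
    score.  Absence is first-class and is never imputed.
    """

    model_config = ConfigDict(frozen=True)

    s_zero: float = Field(ge=SCALE_MIN, le=SCALE_MAX)
    s_half: Optional[float] = Field(default=None, ge=SCALE_MIN, le=SCALE_MAX)
    s_all: float = Field(ge=SCALE_MIN, le=SCALE_MAX)

    @property
    def has_half(self) -> bool:
        return self.s_half is not None


class ConditionRecord(BaseModel):
    """One experimental condition with provenance and optional outcome.

    ``country`` is metadata only: it enters the elicitation prompt but
    never any numerical computation.
    """

    model_config = ConfigDict(frozen=True)

    study_id: str
    condition_label: str
    country: str = ""
    sentiments: SentimentTriple
    prosocial_rate: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    n_participants: Optional[int] = Field(default=None, gt=0)


class Corpus(BaseModel):
    """Ordered, non-empty collection of condition records."""

    model_config = ConfigDict(frozen=True)

    records: tuple[ConditionRecord, ...]
    provenance: str = ""

    @model_validator(mode="after")
    def _non_empty(self) -> "Corpus":
        if not self.records:
            raise ValueError("a corpus must contain at least one record")
        return self

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ConditionRecord]:  # type: ignore[override]
        return iter(self.records)

    @property
    def study_ids(self) -> list[str]:
        """Distinct study identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.study_id, None)
        return list(seen)

    def by_study(self) -> dict[str, list[ConditionRecord]]:
        """Partition the records by ``study_id`` (insertion-ordered)."""
        groups: dict[str, list[ConditionRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.study_id, []).append(rec)
        return groups

    def get(self, study_id: str, condition_label: str) -> ConditionRecord:
        for rec in self.records:
            if rec.study_id == study_id and rec.condition_label == condition_label:
                return rec
        raise KeyError((study_id, condition_label))

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten into a DataFrame with the canonical CSV columns."""
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "study_id": rec.study_id,
                    "condition_label": rec.condition_label,
                    "country": rec.country,
                    "s_zero": rec.sentiments.s_zero,
                    "s_half": rec.sentiments.s_half,
                    "s_all": rec.sentiments.s_all,
                    "prosocial_rate": rec.prosocial_rate,
                    "n_participants": rec.n_participants,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


@dataclass
class ValidationReport:
    """Summary of corpus structure and eligibility for study-level fits."""

    n_studies: int
    n_conditions: int
    ineligible_studies: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [
            f"studies:    {self.n_studies}",
            f"conditions: {self.n_conditions}",
            f"ineligible for study-level regression (<3 conditions): "
            f"{len(self.ineligible_studies)}",
        ]
        lines += [f"  - {s}" for s in self.ineligible_studies]
        lines += [f"warning: {w}" for w in self.warnings]
        lines += [f"error: {e}" for e in self.errors]
        return "\n".join(lines)


def _parse_optional_float(raw: object, row: int, col: str) -> Optional[float]:
    if raw is None or (isinstance(raw, str) and raw.strip() == ""):
        return None
    if isinstance(raw, float) and pd.isna(raw):
        return None
    try:
        return float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise CorpusFormatError(
            f"row {row}: column {col!r}: cannot parse {raw!r} as a number"
        ) from None


def _record_from_mapping(row: dict, idx: int) -> ConditionRecord:
    for col in ("study_id", "condition_label"):
        if not str(row.get(col, "") or "").strip():
            raise CorpusFormatError(f"row {idx}: column {col!r} is required")
    scores = {
        col: _parse_optional_float(row.get(col), idx, col)
        for col in ("s_zero", "s_half", "s_all")
    }
    for col in ("s_zero", "s_all"):
        if scores[col] is None:
            raise CorpusFormatError(f"row {idx}: column {col!r} is required")
    for col, val in scores.items():
        if val is not None and not (SCALE_MIN <= val <= SCALE_MAX):
            raise CorpusFormatError(
                f"row {idx}: column {col!r}: score {val} outside the 1-7 scale"
            )
    rate = _parse_optional_float(row.get("prosocial_rate"), idx, "prosocial_rate")
    if rate is not None and not (0.0 <= rate <= 1.0):
        raise CorpusFormatError(
            f"row {idx}: column 'prosocial_rate': {rate} outside [0, 1]"
        )
    n_raw = _parse_optional_float(row.get("n_participants"), idx, "n_participants")
    n = int(n_raw) if n_raw is not None else None
    if n is not None and n <= 0:
        raise CorpusFormatError(f"row {idx}: column 'n_participants': {n} not positive")
    return ConditionRecord(
        study_id=str(row["study_id"]).strip(),
        condition_label=str(row["condition_label"]).strip(),
        country=str(row.get("country", "") or "").strip(),
        sentiments=SentimentTriple(
            s_zero=scores["s_zero"], s_half=scores["s_half"], s_all=scores["s_all"]
        ),
        prosocial_rate=rate,
        n_participants=n,
    )


def read_corpus(
    path: str | Path, format: Literal["csv", "json"] | None = None
) -> Corpus:
    """Read a corpus from CSV or JSON.

    The format is inferred from the file suffix when not given.  The CSV
    schema is ``study_id,condition_label,country,s_zero,s_half,s_all,
    prosocial_rate,n_participants`` with a header row; empty fields are
    absent values.  JSON holds an array of objects with the same keys.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise CorpusFormatError(f"missing columns: {missing}")
        raw_rows = df.to_dict(orient="records")
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if not isinstance(payload, list):
            raise CorpusFormatError("JSON corpus must be an array of objects")
        raw_rows = payload
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown format {format!r}")

    records = [_record_from_mapping(row, i + 1) for i, row in enumerate(raw_rows)]
    return Corpus(records=tuple(records), provenance=str(path))


def write_corpus(
    corpus: Corpus, path: str | Path, format: Literal["csv", "json"] | None = None
) -> None:
    """Write a corpus to CSV or JSON (scores serialized at two decimals)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"

    def fmt(x: Optional[float]) -> str:
        return "" if x is None else f"{x:.2f}"

    if format == "csv":
        lines = [",".join(CSV_COLUMNS)]
        for rec in corpus:
            cells = [
                _csv_quote(rec.study_id),
                _csv_quote(rec.condition_label),
                _csv_quote(rec.country),
                fmt(rec.sentiments.s_zero),
                fmt(rec.sentiments.s_half),
                fmt(rec.sentiments.s_all),
                "" if rec.prosocial_rate is None else f"{rec.prosocial_rate:.6f}",
                "" if rec.n_participants is None else str(rec.n_participants),
            ]
            lines.append(",".join(cells))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        payload = []
        for rec in corpus:
            payload.append(
                {
                    "study_id": rec.study_id,
                    "condition_label": rec.condition_label,
                    "country": rec.country,
                    "s_zero": round(rec.sentiments.s_zero, 2),
                    "s_half": (
                        None
                        if rec.sentiments.s_half is None
                        else round(rec.sentiments.s_half, 2)
                    ),
                    "s_all": round(rec.sentiments.s_all, 2),
                    "prosocial_rate": rec.prosocial_rate,
                    "n_participants": rec.n_participants,
                }
            )
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _csv_quote(value: str) -> str:
    if any(ch in value for ch in ',"\n'):
        return '"' + value.replace('"', '""') + '"'
    return value


#: Minimum conditions a study needs for a slope standard error to exist:
#: two points determine a unique line, leaving no residual information.
MIN_CONDITIONS_PER_STUDY = 3


def validate_corpus(corpus: Corpus) -> ValidationReport:
    """Check structural invariants and regression eligibility.

    Studies with fewer than three conditions are flagged ineligible for
    study-level regression; duplicate ``(study_id, condition_label)``
    pairs are errors.
    """
    groups = corpus.by_study()
    errors: list[str] = []
    warnings: list[str] = []
    seen: set[tuple[str, str]] = set()
    for rec in corpus:
        key = (rec.study_id, rec.condition_label)
        if key in seen:
            errors.append(f"duplicate (study_id, condition_label): {key}")
        seen.add(key)
    ineligible = [
        sid
        for sid, recs in groups.items()
        if len(recs) < MIN_CONDITIONS_PER_STUDY
    ]
    n_missing_half = sum(1 for rec in corpus if not rec.sentiments.has_half)
    if n_missing_half:
        warnings.append(
            f"{n_missing_half} condition(s) lack an s_half score "
            "(two-action designs)"
        )
    return ValidationReport(
        n_studies=len(groups),
        n_conditions=len(corpus),
        ineligible_studies=ineligible,
        warnings=warnings,
        errors=errors,
    )


def packaged_fixture() -> Corpus:
    """The bundled corpus: 61 dictator-game conditions from 12 studies.

    Sentiment scores are GPT-4 ratings of the action descriptions in the
    original experimental instructions, on the 1–7 scale, as published in
    the meta-analysis this package operationalizes.  The six conditions
    of the Capraro & Vanzo study have no equal-split option and hence no
    ``s_half``.  Country values come from the cited source articles'
    stated subject pools; for multi-site or ambiguous studies (Dreber et
    al., Kettner & Waichman, Walkowitz) the primary site was used — they
    are metadata only and affect nothing numerical.

    No behavioural outcomes are bundled: the source articles' giving
    rates are not part of the published score table.
    """
    ref = resources.files("langgame.data").joinpath("dictator_sentiments.csv")
    with resources.as_file(ref) as path:
        corpus = read_corpus(path, format="csv")
    return Corpus(
        records=corpus.records,
        provenance="bundled dictator-game sentiment corpus (61 conditions, 12 studies)",
    )
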