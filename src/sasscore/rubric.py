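"""Severity-score rubric engine.

The SAS severity score is an organ-system-based rubric of 15 ordinal
clinical categories, each scored from 0 (least severe) up to a
per-category maximum between 2 and 5 points. Categories are grouped into
a neurodevelopmental and a systemic subscale; the total score is the sum
of the two subscales (47 points maximum under the packaged default
schema). The engine is fully schema-driven: the category set, grouping,
and point maxima all come from a JSON schema file, so a revised rubric
can be dropped in without code changes.

Scoring rules
-------------
* Only individuals aged three years or older are scored; younger records
  are excluded with a logged reason, not silently dropped.
* A missing category level contributes 0 points (default-zero
  imputation) and is counted in ``n_imputed`` so that analysts can
  identify low-information records.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ConfigError, DataValidationError, IneligibilityError

__all__ = [
    "MIN_SCORING_AGE_YEARS",
    "RubricCategory",
    "RubricSchema",
    "PhenotypeRecord",
    "ScoreSet",
    "default_rubric_path",
    "load_rubric",
    "score_individual",
    "score_cohort",
]

#: Minimum age (decimal years, inclusive) at which the score is defined.
MIN_SCORING_AGE_YEARS = 3.0

_DATA_DIR = Path(__file__).parent / "data"

Group = Literal["neurodevelopmental", "systemic"]


class RubricCategory(BaseModel):
    """One ordinal clinical category of the rubric."""

    model_config = ConfigDict(frozen=True)

    name: str
    group: Group
    max_points: int
    level_labels: tuple[str, ...]
    placeholder: bool = False

    @model_validator(mode="after")
    def _check(self) -> "RubricCategory":
        if not 2 <= self.max_points <= 5:
            raise ValueError(
                f"category {self.name!r}: max_points must be in [2, 5], got {self.max_points}"
            )
        if len(self.level_labels) != self.max_points + 1:
            raise ValueError(
                f"category {self.name!r}: expected {self.max_points + 1} level labels, "
                f"got {len(self.level_labels)}"
            )
        return self


class RubricSchema(BaseModel):
    """An ordered collection of rubric categories plus a version tag."""

    model_config = ConfigDict(frozen=True)

    categories: tuple[RubricCategory, ...]
    version: str = "unversioned"

    @model_validator(mode="after")
    def _check(self) -> "RubricSchema":
        names = [c.name for c in self.categories]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate category names: {sorted(dupes)}")
        groups = {c.group for c in self.categories}
        if len(self.categories) and groups != {"neurodevelopmental", "systemic"}:
            raise ValueError("both the neurodevelopmental and systemic groups must be non-empty")
        return self

    @property
    def category_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)

    @property
    def max_total(self) -> int:
        return sum(c.max_points for c in self.categories)

    def category(self, name: str) -> RubricCategory:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    def names_in_group(self, group: Group) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories if c.group == group)


class PhenotypeRecord(BaseModel):
    """One individual's demographics and observed rubric levels.

    ``levels`` maps category name to an integer level; a value of
    ``None`` (or an absent key) marks the item as not observed.
    """

    model_config = ConfigDict(frozen=True)

    individual_id: str
    sex: Literal["male", "female"]
    age_years: float
    levels: Mapping[str, Optional[int]] = {}

    @field_validator("age_years")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("age_years must be non-negative")
        return v


class ScoreSet(BaseModel):
    """Per-category points and the three composite scores for one individual."""

    model_config = ConfigDict(frozen=True)

    individual_id: str
    per_category: Mapping[str, int]
    neurodevelopmental: int
    systemic: int
    total: int
    n_imputed: int


def default_rubric_path() -> Path:
    """Path of the packaged default rubric schema."""
    return _DATA_DIR / "rubric_default.json"


def load_rubric(config_source: Union[str, Path, Mapping]) -> RubricSchema:
    """Load and validate a rubric schema from a JSON file or a parsed mapping.

    Raises :class:`ConfigError` with every failed constraint named if the
    config is malformed or violates a schema invariant.
    """
    if isinstance(config_source, (str, Path)):
        path = Path(config_source)
        try:
            raw = json.loads(path.read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read rubric config {path}: {exc}") from exc
    else:
        raw = dict(config_source)
    raw.pop("_comment", None)
    try:
        return RubricSchema.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries per-field detail
        raise ConfigError(f"rubric schema validation failed: {exc}") from exc


def score_individual(record: PhenotypeRecord, schema: RubricSchema) -> ScoreSet:
    """Score one eligible individual under the rubric.

    Missing levels contribute 0 points and increment ``n_imputed``.

    Raises
    ------
    IneligibilityError
        If the individual is younger than three years.
    DataValidationError
        If an observed level is out of range or names an unknown category.
    """
    if record.age_years < MIN_SCORING_AGE_YEARS:
        raise IneligibilityError(
            f"{record.individual_id}: age {record.age_years} < {MIN_SCORING_AGE_YEARS} years"
        )
    known = set(schema.category_names)
    unknown = set(record.levels) - known
    if unknown:
        raise DataValidationError(
            f"{record.individual_id}: unknown categories {sorted(unknown)}"
        )
    per_category: dict[str, int] = {}
    n_imputed = 0
    for cat in schema.categories:
        level = record.levels.get(cat.name)
        if level is None:
            per_category[cat.name] = 0
            n_imputed += 1
            continue
        if not 0 <= level <= cat.max_points:
            raise DataValidationError(
                f"{record.individual_id}: level {level} out of range [0, "
                f"{cat.max_points}] for category {cat.name!r}"
            )
        per_category[cat.name] = int(level)
    neuro = sum(per_category[n] for n in schema.names_in_group("neurodevelopmental"))
    syst = sum(per_category[n] for n in schema.names_in_group("systemic"))
    return ScoreSet(
        individual_id=record.individual_id,
        per_category=per_category,
        neurodevelopmental=neuro,
        systemic=syst,
        total=neuro + syst,
        n_imputed=n_imputed,
    )


def score_cohort(
    records: Iterable[PhenotypeRecord], schema: RubricSchema
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a cohort, returning ``(scores, exclusions)``.

    ``scores`` has one row per eligible individual: ``individual_id``,
    ``sex``, ``age_years``, one column per rubric category, the three
    composites and ``n_imputed``. ``exclusions`` lists every record that
    could not be scored, with the reason.

    Raises :class:`DataValidationError` on duplicate individual ids.
    """
    records = list(records)
    ids = [r.individual_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise DataValidationError(f"duplicate individual_id values: {sorted(dupes)}")

    rows: list[dict] = []
    excluded: list[dict] = []
    for rec in records:
        try:
            ss = score_individual(rec, schema)
        except (IneligibilityError, DataValidationError) as exc:
            excluded.append({"individual_id": rec.individual_id, "reason": str(exc)})
            continue
        row = {
            "individual_id": ss.individual_id,
            "sex": rec.sex,
            "age_years": rec.age_years,
            **ss.per_category,
            "neurodevelopmental": ss.neurodevelopmental,
            "systemic": ss.systemic,
            "total": ss.total,
            "n_imputed": ss.n_imputed,
        }
        rows.append(row)

    score_cols = [
        "individual_id",
        "sex",
        "age_years",
        *schema.category_names,
        "neurodevelopmental",
        "systemic",
        "total",
        "n_imputed",
    ]
    scores = pd.DataFrame(rows, columns=score_cols)
    exclusions = pd.DataFrame(excluded, columns=["individual_id", "reason"])
    return scores, exclusions
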