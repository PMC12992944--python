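"""Declarative rule sets for VTE scoring.

A rule set is data, not code: each scoring factor is a named rule with a
point weight, a scoring stage and a small predicate over patient fields.
This keeps the department protocol auditable and lets alternative cutoff
choices (age 35 vs 40, preterm 34 vs 37 weeks, threshold 2 vs 3) be expressed
as alternative config files rather than code changes.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any, Mapping, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .types import ScoreStage

_OPS = {
    "ge": lambda a, b: a >= b,
    "gt": lambda a, b: a > b,
    "le": lambda a, b: a <= b,
    "lt": lambda a, b: a < b,
    "eq": lambda a, b: a == b,
}


class Condition(BaseModel):
    """One comparison against a patient field, e.g. ``bmi >= 30``.

    ``op`` is one of ge/gt/le/lt/eq/is_true. ``is_true`` needs no value and
    tests a boolean flag.
    """

    model_config = ConfigDict(extra="forbid")

    field: str
    op: str
    value: Any = None

    @model_validator(mode="after")
    def _check_op(self) -> "Condition":
        if self.op not in _OPS and self.op != "is_true":
            raise ValueError(f"unknown operator {self.op!r}")
        if self.op != "is_true" and self.value is None:
            raise ValueError(f"operator {self.op!r} requires a value")
        return self

    def evaluate(self, record: Mapping[str, Any]) -> bool:
        if self.field not in record:
            raise KeyError(f"missing field {self.field!r}")
        v = record[self.field]
        if self.op == "is_true":
            return bool(v)
        # enum-valued fields compare by their string value
        v = getattr(v, "value", v)
        return bool(_OPS[self.op](v, self.value))

    def evaluate_frame(self, df: pd.DataFrame) -> pd.Series:
        """Vectorized evaluation over a patient table (one row per patient)."""
        if self.field not in df.columns:
            raise KeyError(f"missing column {self.field!r}")
        col = df[self.field]
        if self.op == "is_true":
            return col.astype(bool)
        return _OPS[self.op](col, self.value)


class Rule(BaseModel):
    """A named scoring factor: points awarded when its predicate holds.

    ``all`` conditions are conjoined; ``any`` conditions are disjoined; when
    both are present the rule requires ``all`` AND at least one of ``any``.
    """

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    name: str
    points: int = Field(default=1, ge=1, le=2)
    stage: ScoreStage = ScoreStage.pre_operative
    all_of: list[Condition] = Field(default_factory=list, alias="all")
    any_of: list[Condition] = Field(default_factory=list, alias="any")

    @model_validator(mode="after")
    def _check_predicate(self) -> "Rule":
        if not self.all_of and not self.any_of:
            raise ValueError(f"rule {self.name!r} has an empty predicate")
        return self

    def triggered(self, record: Mapping[str, Any]) -> bool:
        if not all(c.evaluate(record) for c in self.all_of):
            return False
        if self.any_of and not any(c.evaluate(record) for c in self.any_of):
            return False
        return True

    def triggered_frame(self, df: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=df.index)
        for c in self.all_of:
            mask &= c.evaluate_frame(df)
        if self.any_of:
            any_mask = pd.Series(False, index=df.index)
            for c in self.any_of:
                any_mask |= c.evaluate_frame(df)
            mask &= any_mask
        return mask


class DosingTable(BaseModel):
    """Weight-banded enoxaparin dosing for the pharmacologic tier."""

    drug: str = "enoxaparin"
    duration_days: int = 10
    weight_cutoff_kg: float = 100.0
    dose_below_cutoff_mg: int = 40
    dose_at_or_above_cutoff_mg: int = 60


class RuleSet(BaseModel):
    """A complete scoring protocol: factors, tier thresholds and dosing."""

    model_config = ConfigDict(extra="forbid")

    name: str
    version: str = "1"
    factors: list[Rule]
    mechanical_threshold: int = 2
    pharmacologic_threshold: int = 3
    dosing: DosingTable = Field(default_factory=DosingTable)

    @model_validator(mode="after")
    def _check_names(self) -> "RuleSet":
        names = [r.name for r in self.factors]
        if len(names) != len(set(names)):
            raise ValueError("duplicate factor names in rule set")
        return self

    @property
    def pre_operative_factors(self) -> list[Rule]:
        return [r for r in self.factors if r.stage == ScoreStage.pre_operative]

    @property
    def markup_factors(self) -> list[Rule]:
        return [r for r in self.factors if r.stage == ScoreStage.post_operative_markup]


def load_ruleset(source: Union[str, Path]) -> RuleSet:
    """Load a rule set from a YAML file path or a bundled preset name.

    Bundled presets: ``department`` (the scoring protocol itself). Guideline
    comparator presets live in :mod:`vtescore.guidelines`.
    """
    path = Path(source)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        text = (
            importlib.resources.files("vtescore")
            .joinpath(f"rulesets/{source}.yaml")
            .read_text()
        )
    return RuleSet.model_validate(yaml.safe_load(text))


def default_ruleset() -> RuleSet:
    """The department cesarean-section VTE prophylaxis protocol."""
    return load_ruleset("department")
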