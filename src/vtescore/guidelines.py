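"""Comparator implementations of external thromboprophylaxis guidelines.

Recodes a cesarean cohort under RCOG-, ACCP- and ACOG-style rule sets so
their hypothetical prophylaxis rates can be compared with the department
score protocol on the same denominator:

* RCOG-style: universal mechanical prophylaxis; pharmacologic prophylaxis for
  every intrapartum/urgent cesarean, and for elective cesareans with at least
  one risk factor from the guideline's list.
* ACCP-style: pharmacologic prophylaxis with one major risk factor, two or
  more minor factors, or one minor factor plus an emergency cesarean.
* ACOG-style: universal pneumatic compression only; pharmacologic prophylaxis
  reserved for prior VTE / high-risk thrombophilia (a group the department
  protocol handles via antenatal LMWH and excludes from scoring, hence 0%
  after exclusions).

The published recodings do not enumerate the exact factor lists applied, so
the bundled presets are documented approximations; institutions should supply
their own lists through the same config schema.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .ruleset import Rule, RuleSet
from .scoring import score_table, summarize_scored_table
from .types import CSUrgency, GuidelineRecommendation, RiskFactorProfile

__all__ = [
    "GuidelineRuleSet",
    "load_guideline",
    "recode_rcog",
    "recode_accp",
    "recode_acog",
    "recode_profile",
    "recode_table",
    "compare_guidelines",
]


class PharmacologicRule(BaseModel):
    """Disjunctive trigger for pharmacologic prophylaxis.

    Pharmacologic prophylaxis is recommended when any holds:
    >=1 major factor; >= ``min_minor_alone`` minor factors; >=
    ``min_minor_with_emergency`` minor factors at an emergency cesarean;
    or (``emergency_triggers_alone``) an emergency cesarean by itself.
    """

    model_config = ConfigDict(extra="forbid")

    major_factors: list[Rule] = Field(default_factory=list)
    minor_factors: list[Rule] = Field(default_factory=list)
    min_minor_alone: Optional[int] = None
    min_minor_with_emergency: Optional[int] = None
    emergency_triggers_alone: bool = False


class GuidelineRuleSet(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    mechanical_policy: str = "universal"  # universal | threshold
    pharmacologic: PharmacologicRule


def load_guideline(source: Union[str, Path]) -> GuidelineRuleSet:
    """Load a guideline from a YAML path or bundled preset (rcog/accp/acog)."""
    path = Path(source)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        text = (
            importlib.resources.files("vtescore")
            .joinpath(f"rulesets/{source}.yaml")
            .read_text()
        )
    return GuidelineRuleSet.model_validate(yaml.safe_load(text))


def recode_profile(
    profile: Union[RiskFactorProfile, Mapping],
    guideline: GuidelineRuleSet,
) -> GuidelineRecommendation:
    """Recode one patient under an external guideline."""
    if not isinstance(profile, RiskFactorProfile):
        profile = RiskFactorProfile.model_validate(profile)
    record = profile.model_dump()
    rule = guideline.pharmacologic

    majors = [r.name for r in rule.major_factors if r.triggered(record)]
    minors = [r.name for r in rule.minor_factors if r.triggered(record)]
    emergency = profile.cs_urgency == CSUrgency.emergency

    pharmacologic = bool(majors)
    rationale = list(majors)
    if rule.min_minor_alone is not None and len(minors) >= rule.min_minor_alone:
        pharmacologic = True
        rationale += minors
    if (
        rule.min_minor_with_emergency is not None
        and emergency
        and len(minors) >= rule.min_minor_with_emergency
    ):
        pharmacologic = True
        rationale += [m for m in minors if m not in rationale] + ["emergency_cs"]
    if rule.emergency_triggers_alone and emergency:
        pharmacologic = True
        if "emergency_cs" not in rationale:
            rationale.append("emergency_cs")

    mechanical = True if guideline.mechanical_policy == "universal" else pharmacologic
    return GuidelineRecommendation(
        guideline=guideline.name,
        mechanical=mechanical,
        pharmacologic=pharmacologic,
        rationale=rationale,
    )


def recode_rcog(profile: Union[RiskFactorProfile, Mapping]) -> GuidelineRecommendation:
    return recode_profile(profile, load_guideline("rcog"))


def recode_accp(profile: Union[RiskFactorProfile, Mapping]) -> GuidelineRecommendation:
    return recode_profile(profile, load_guideline("accp"))


def recode_acog(profile: Union[RiskFactorProfile, Mapping]) -> GuidelineRecommendation:
    return recode_profile(profile, load_guideline("acog"))


def recode_table(df: pd.DataFrame, guideline: GuidelineRuleSet) -> pd.DataFrame:
    """Vectorized recoding: adds ``mechanical``/``pharmacologic`` bool columns."""
    work = df.copy()
    if "cs_urgency" in work.columns:
        work["cs_urgency"] = work["cs_urgency"].map(lambda v: getattr(v, "value", v))
    rule = guideline.pharmacologic

    n_major = pd.Series(0, index=work.index)
    for r in rule.major_factors:
        n_major += r.triggered_frame(work).astype(int)
    n_minor = pd.Series(0, index=work.index)
    for r in rule.minor_factors:
        n_minor += r.triggered_frame(work).astype(int)
    emergency = work["cs_urgency"] == CSUrgency.emergency.value

    pharm = n_major >= 1
    if rule.min_minor_alone is not None:
        pharm |= n_minor >= rule.min_minor_alone
    if rule.min_minor_with_emergency is not None:
        pharm |= emergency & (n_minor >= rule.min_minor_with_emergency)
    if rule.emergency_triggers_alone:
        pharm |= emergency

    out = df.copy()
    out["mechanical"] = True if guideline.mechanical_policy == "universal" else pharm
    out["pharmacologic"] = pharm
    return out


_DEFAULT_GUIDELINES = ("rcog", "accp", "acog")


def compare_guidelines(
    cohort: Union[pd.DataFrame, Sequence[Union[RiskFactorProfile, Mapping]]],
    guidelines: Optional[Sequence[GuidelineRuleSet]] = None,
    department_ruleset: Optional[RuleSet] = None,
) -> pd.DataFrame:
    """Prophylaxis rate table across the department protocol and guidelines.

    Antenatal-LMWH patients are excluded first (mirroring the study design),
    so all percentages share the same denominator. Returns one row per
    (guideline, prophylaxis type) with counts and percentages.
    """
    if not isinstance(cohort, pd.DataFrame):
        records = []
        for p in cohort:
            if not isinstance(p, RiskFactorProfile):
                p = RiskFactorProfile.model_validate(p)
            records.append(p.model_dump())
        cohort = pd.DataFrame(records)
    if len(cohort) == 0:
        raise ValueError("cannot compare guidelines on an empty cohort")

    if "on_antenatal_lmwh" in cohort.columns:
        cohort = cohort.loc[~cohort["on_antenatal_lmwh"].astype(bool)]
    if len(cohort) == 0:
        raise ValueError("no patients remain after antenatal-LMWH exclusion")
    n = len(cohort)

    rows = []
    scored = score_table(cohort, department_ruleset)
    summary = summarize_scored_table(scored, department_ruleset)
    rows.append(("department_protocol", "mechanical", summary.mechanical_prophylaxis))
    rows.append(("department_protocol", "pharmacologic", summary.pharmacologic_prophylaxis))

    if guidelines is None:
        guidelines = [load_guideline(name) for name in _DEFAULT_GUIDELINES]
    for g in guidelines:
        rec = recode_table(cohort, g)
        rows.append((g.name, "mechanical", int(rec["mechanical"].sum())))
        rows.append((g.name, "pharmacologic", int(rec["pharmacologic"].sum())))

    table = pd.DataFrame(rows, columns=["guideline", "prophylaxis", "count"])
    table["n"] = n
    table["percent"] = 100.0 * table["count"] / n
    return table
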