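"""Domain types for post-cesarean VTE thromboprophylaxis scoring.

The central object is :class:`RiskFactorProfile`, one patient's demographic,
obstetric and medical risk-factor record as assessed around the time of
cesarean section (CS). Scoring produces a :class:`VTEScoreResult` (itemized
points, pre-operative and final scores, risk tier) and a
:class:`ProphylaxisPlan` (mechanical and/or pharmacologic prophylaxis with
enoxaparin dosing).
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class CSUrgency(str, enum.Enum):
    """Whether the cesarean was planned (elective) or intrapartum/urgent."""

    elective = "elective"
    emergency = "emergency"


class ScoreStage(str, enum.Enum):
    pre_operative = "pre_operative"
    post_operative_markup = "post_operative_markup"


class RiskTier(str, enum.Enum):
    """Protocol risk strata: low (<2), moderate (=2), high (>=3)."""

    low = "low"
    moderate = "moderate"
    high = "high"


class ProphylaxisTier(str, enum.Enum):
    early_mobilization_only = "early_mobilization_only"
    mechanical = "mechanical"
    mechanical_plus_pharmacologic = "mechanical_plus_pharmacologic"
    antenatal_lmwh_continued = "antenatal_lmwh_continued"


class RiskFactorProfile(BaseModel):
    """One patient's risk-factor record at the time of cesarean delivery.

    Continuous covariates (age, BMI, booking weight, gestational age, blood
    loss) are kept raw; the rule set applies the cutoffs, so alternative
    cutoff choices (e.g. age 35 vs 40) never require re-encoding the data.
    """

    model_config = ConfigDict(extra="forbid")

    age: int = Field(ge=12, le=60, description="maternal age in completed years")
    bmi: float = Field(gt=0, description="prepregnancy or early-pregnancy BMI, kg/m^2")
    weight: float = Field(gt=0, description="booking/early-pregnancy body weight, kg")
    parity: int = Field(ge=0)
    gestational_age_at_delivery: float = Field(ge=20, le=43, description="completed weeks")
    cs_urgency: CSUrgency

    pre_eclampsia: bool = False
    multiple_pregnancy: bool = False
    prolonged_labor_gt24h: bool = False
    stillbirth: bool = False
    medical_comorbidity: bool = False
    low_risk_thrombophilia: bool = False
    current_smoker: bool = False
    gross_varicose_veins: bool = False
    current_systemic_infection: bool = False
    immobility: bool = False
    family_history_vte: bool = False

    pph_ml: float = Field(default=0.0, ge=0, description="intra/post-operative blood loss, mL")
    transfusion: bool = False

    on_antenatal_lmwh: bool = False
    prior_vte_or_high_risk_thrombophilia: bool = False


class ScoreComponent(BaseModel):
    """A single triggered rule: factor name, its points, and scoring stage."""

    factor_name: str
    points: int = Field(ge=1, le=2)
    stage: ScoreStage = ScoreStage.pre_operative


class VTEScoreResult(BaseModel):
    """Itemized VTE score for one patient.

    ``pre_op_score`` is the score known before the cesarean; ``final_score``
    additionally carries the postpartum markup (+1 for major PPH >= 1000 mL or
    transfusion). Intraoperative pneumatic-cuff attribution
    (``mechanical_during_op``) is decided from the pre-operative score only:
    a patient reaching 2 solely through the markup was not cuffed during the
    operation.
    """

    components: list[ScoreComponent] = Field(default_factory=list)
    pre_op_score: int = Field(default=0, ge=0)
    final_score: int = Field(default=0, ge=0)
    risk_tier: RiskTier = RiskTier.low
    mechanical_during_op: bool = False
    excluded_antenatal_lmwh: bool = False
    markup_applied: bool = False

    @model_validator(mode="after")
    def _check_consistency(self) -> "VTEScoreResult":
        if self.excluded_antenatal_lmwh:
            return self
        if self.final_score != sum(c.points for c in self.components):
            raise ValueError("final_score must equal the sum of component points")
        if self.final_score - self.pre_op_score not in (0, 1):
            raise ValueError("markup may add at most one point")
        return self


class ProphylaxisPlan(BaseModel):
    """Recommended prophylaxis: tier plus enoxaparin dose/duration if any."""

    tier: ProphylaxisTier
    drug: Optional[str] = None
    dose_mg: Optional[int] = None
    duration_days: Optional[int] = None

    @model_validator(mode="after")
    def _check_dosing(self) -> "ProphylaxisPlan":
        pharmacologic = self.tier == ProphylaxisTier.mechanical_plus_pharmacologic
        if pharmacologic and self.dose_mg not in (40, 60):
            raise ValueError("pharmacologic tier requires enoxaparin 40 or 60 mg")
        if not pharmacologic and self.tier != ProphylaxisTier.antenatal_lmwh_continued:
            if self.dose_mg is not None:
                raise ValueError("dose only applies to pharmacologic tiers")
        return self


class GuidelineRecommendation(BaseModel):
    """Output of recoding one patient under an external guideline."""

    guideline: str
    mechanical: bool
    pharmacologic: bool
    rationale: list[str] = Field(default_factory=list)


class TwoByTwoTable(BaseModel):
    """Event counts in two cohorts (A = preprotocol, B = protocol by convention)."""

    events_a: int = Field(ge=0)
    n_a: int = Field(gt=0)
    events_b: int = Field(ge=0)
    n_b: int = Field(gt=0)

    @model_validator(mode="after")
    def _check_counts(self) -> "TwoByTwoTable":
        if self.events_a > self.n_a or self.events_b > self.n_b:
            raise ValueError("events cannot exceed group size")
        return self


class ConfusionMatrix(BaseModel):
    """Screening 2x2: high-risk flag vs observed postpartum VTE event."""

    tp: int = Field(ge=0)
    fp: int = Field(ge=0)
    fn: int = Field(ge=0)
    tn: int = Field(ge=0)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def events(self) -> int:
        return self.tp + self.fn
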