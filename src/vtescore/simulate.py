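"""Synthetic cesarean cohorts with the study's statistical structure.

The generator draws each risk factor as an independent Bernoulli at the
observed cohort prevalence (protocol-period defaults; a preprotocol set is
also bundled), backfills continuous covariates consistently with the sampled
flags (a patient flagged preterm gets a gestational age below 34 weeks, and
so on), assigns VTE events at the score-stratum incidences observed under the
protocol (score < 2, = 2, >= 3), and assigns bleeding complications at a
score-independent rate.

Because factors are independent, the protocol score is a weighted
Poisson-binomial variable: fourteen weight-1 Bernoullis, one three-valued BMI
component contributing {0, 1, 2}, and a weight-1 postpartum markup.
:func:`exact_score_distribution` computes its exact pmf by sequential
convolution, which serves both as a fast design tool (expected prophylaxis
rates without simulation) and as a cross-check on the sampler.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .ruleset import RuleSet, default_ruleset
from .scoring import score_table
from .types import RiskTier

__all__ = [
    "SyntheticCohortParams",
    "ScoreDistribution",
    "generate_cohort",
    "exact_score_distribution",
    "expected_prophylaxis_rates",
    "WEIGHT_ONE_FACTORS",
]

# Weight-1 boolean factors of the department score, in sampling order.
# BMI is handled separately as a 3-way categorical (0/1/2 points) and the
# PPH/transfusion markup as the post-operative stage.
WEIGHT_ONE_FACTORS = (
    "age_ge_40",
    "parity_ge_3",
    "pre_eclampsia",
    "multiple_pregnancy",
    "preterm_lt_34wk",
    "prolonged_labor_gt24h",
    "stillbirth",
    "medical_comorbidity",
    "low_risk_thrombophilia",
    "current_smoker",
    "gross_varicose_veins",
    "current_systemic_infection",
    "immobility",
    "family_history_vte",
)

# Observed factor prevalences in the two study periods (proportions).
PROTOCOL_PREVALENCES = {
    "age_ge_40": 0.112,
    "parity_ge_3": 8 / 4803,
    "bmi_25_to_30": 0.13,
    "bmi_ge_30": 0.0497,
    "pre_eclampsia": 0.0335,
    "multiple_pregnancy": 0.047,
    "preterm_lt_34wk": 0.0999,
    "prolonged_labor_gt24h": 0.0079,
    "stillbirth": 2 / 4803,
    "medical_comorbidity": 0.0114,
    "low_risk_thrombophilia": 0.0023,
    "current_smoker": 0.0062,
    "gross_varicose_veins": 0.0006,
    "current_systemic_infection": 0.0033,
    "immobility": 0.0,
    "family_history_vte": 0.0008,
    "pph_or_transfusion": 0.0605,
    "emergency_cs": 0.586,
}

PREPROTOCOL_PREVALENCES = {
    "age_ge_40": 0.101,
    "parity_ge_3": 1 / 3309,
    "bmi_25_to_30": 0.109,
    "bmi_ge_30": 0.0372,
    "pre_eclampsia": 0.0299,
    "multiple_pregnancy": 0.06,
    "preterm_lt_34wk": 0.101,
    "prolonged_labor_gt24h": 0.0108,
    "stillbirth": 3 / 3309,
    "medical_comorbidity": 0.010,
    "low_risk_thrombophilia": 0.0015,
    "current_smoker": 0.0087,
    "gross_varicose_veins": 0.0006,
    "current_systemic_infection": 0.0006,
    "immobility": 0.0,
    "family_history_vte": 0.0018,
    "pph_or_transfusion": 0.0401,
    "emergency_cs": 0.575,
}

# Observed VTE incidence by final-score stratum under the protocol.
EVENT_RISK_BY_STRATUM = {
    RiskTier.low.value: 1 / 4064,
    RiskTier.moderate.value: 1 / 583,
    RiskTier.high.value: 3 / 156,
}


class SyntheticCohortParams(BaseModel):
    """Parameters of one synthetic cohort draw.

    ``treatment_effect_rr`` multiplies the stratum event risk for patients
    the protocol treats pharmacologically (final score >= 3); the default 1.0
    models no effect, so the stratum incidences are recovered as-is.
    """

    model_config = ConfigDict(extra="forbid")

    n: int = Field(ge=0, default=4803)
    factor_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(PROTOCOL_PREVALENCES)
    )
    event_risk_by_stratum: dict[str, float] = Field(
        default_factory=lambda: dict(EVENT_RISK_BY_STRATUM)
    )
    treatment_effect_rr: float = Field(gt=0, default=1.0)
    bleeding_rate: float = Field(ge=0, le=1, default=0.0076)
    antenatal_lmwh_rate: float = Field(ge=0, le=1, default=0.0)
    seed: int = 0

    @field_validator("factor_prevalences", "event_risk_by_stratum")
    @classmethod
    def _probabilities(cls, v: dict[str, float]) -> dict[str, float]:
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability {k}={p} outside [0, 1]")
        return v

    @field_validator("factor_prevalences")
    @classmethod
    def _bmi_bands(cls, v: dict[str, float]) -> dict[str, float]:
        if v.get("bmi_25_to_30", 0) + v.get("bmi_ge_30", 0) > 1:
            raise ValueError("BMI band prevalences sum above 1")
        return v

    @classmethod
    def protocol_period(cls, n: int = 4803, seed: int = 0, **kw) -> "SyntheticCohortParams":
        return cls(n=n, seed=seed, **kw)

    @classmethod
    def preprotocol_period(cls, n: int = 3309, seed: int = 0, **kw) -> "SyntheticCohortParams":
        return cls(
            n=n,
            seed=seed,
            factor_prevalences=dict(PREPROTOCOL_PREVALENCES),
            bleeding_rate=0.0096,
            **kw,
        )


class ScoreDistribution(BaseModel):
    """Exact pmf of the protocol score under factor independence."""

    pmf: dict[int, float]

    @field_validator("pmf")
    @classmethod
    def _valid_pmf(cls, v: dict[int, float]) -> dict[int, float]:
        if any(p < 0 for p in v.values()):
            raise ValueError("negative probability in pmf")
        if abs(sum(v.values()) - 1.0) > 1e-12:
            raise ValueError("pmf does not sum to 1")
        return v

    @property
    def support(self) -> list[int]:
        return sorted(self.pmf)

    def mean(self) -> float:
        return sum(k * p for k, p in self.pmf.items())

    def tail_prob(self, k: int) -> float:
        """P(score >= k)."""
        return sum(p for s, p in self.pmf.items() if s >= k)


def _bernoulli(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    return rng.random(n) < p


def generate_cohort(
    params: SyntheticCohortParams,
    ruleset: Optional[RuleSet] = None,
) -> pd.DataFrame:
    """Draw a synthetic cohort as a patient table with outcome columns.

    Reproducible given ``params.seed``; all randomness flows through one
    ``numpy.random.Generator``. Continuous covariates are sampled uniformly
    within the band implied by each factor flag — enough to exercise the
    cutoff logic, with no claim about within-band shape.
    """
    rs = ruleset or default_ruleset()
    rng = np.random.default_rng(params.seed)
    n = params.n
    prev = params.factor_prevalences

    cols: dict[str, np.ndarray] = {}

    # age: integer, >= 40 with the stated prevalence
    old = _bernoulli(rng, prev.get("age_ge_40", 0.0), n)
    cols["age"] = np.where(old, rng.integers(40, 46, n), rng.integers(20, 40, n))

    # BMI: 3-way categorical band, numeric value uniform within band
    u = rng.random(n)
    p_over = prev.get("bmi_25_to_30", 0.0)
    p_obese = prev.get("bmi_ge_30", 0.0)
    bmi = rng.uniform(18.5, 24.99, n)
    over = u < p_over
    obese = (u >= p_over) & (u < p_over + p_obese)
    bmi[over] = rng.uniform(25.0, 29.99, int(over.sum()))
    bmi[obese] = rng.uniform(30.0, 42.0, int(obese.sum()))
    cols["bmi"] = bmi
    cols["weight"] = np.round(bmi * rng.uniform(1.50, 1.78, n) ** 2, 1)

    multiparous = _bernoulli(rng, prev.get("parity_ge_3", 0.0), n)
    cols["parity"] = np.where(multiparous, rng.integers(3, 6, n), rng.integers(0, 3, n))

    preterm = _bernoulli(rng, prev.get("preterm_lt_34wk", 0.0), n)
    cols["gestational_age_at_delivery"] = np.round(
        np.where(preterm, rng.uniform(26.0, 33.9, n), rng.uniform(37.0, 41.9, n)), 1
    )

    emergency = _bernoulli(rng, prev.get("emergency_cs", 0.0), n)
    cols["cs_urgency"] = np.where(emergency, "emergency", "elective")

    for f in WEIGHT_ONE_FACTORS:
        if f in ("age_ge_40", "parity_ge_3", "preterm_lt_34wk"):
            continue  # already realized through the continuous covariates
        cols[f] = _bernoulli(rng, prev.get(f, 0.0), n)

    # postpartum markup: major PPH and/or transfusion
    markup = _bernoulli(rng, prev.get("pph_or_transfusion", 0.0), n)
    transfusion = markup & _bernoulli(rng, 0.3, n)
    cols["pph_ml"] = np.round(
        np.where(markup, rng.uniform(1000.0, 3000.0, n), rng.uniform(100.0, 900.0, n)), 0
    )
    cols["transfusion"] = transfusion

    cols["on_antenatal_lmwh"] = _bernoulli(rng, params.antenatal_lmwh_rate, n)
    cols["prior_vte_or_high_risk_thrombophilia"] = cols["on_antenatal_lmwh"].copy()

    df = pd.DataFrame(cols)

    # outcomes: VTE risk by final-score stratum, diluted by the treatment
    # effect for patients the protocol treats; bleeding independent of score
    if n > 0:
        scored = score_table(df, rs)
        risk = scored["risk_tier"].map(params.event_risk_by_stratum).astype(float)
        treated = (scored["final_score"] >= rs.pharmacologic_threshold).fillna(False)
        risk = risk * np.where(treated, params.treatment_effect_rr, 1.0)
        risk = risk.fillna(0.0)  # excluded antenatal-LMWH rows carry no modelled risk
        df["vte_event"] = rng.random(n) < risk.to_numpy()
        df["bleeding_event"] = _bernoulli(rng, params.bleeding_rate, n)
    else:
        df["vte_event"] = np.array([], dtype=bool)
        df["bleeding_event"] = np.array([], dtype=bool)
    return df


def _convolve(pmf: np.ndarray, outcome_probs: dict[int, float]) -> np.ndarray:
    out = np.zeros(len(pmf) + max(outcome_probs))
    for points, p in outcome_probs.items():
        if p:
            out[points : points + len(pmf)] += p * pmf
    return out


def exact_score_distribution(
    params: SyntheticCohortParams,
    include_markup: bool = True,
) -> ScoreDistribution:
    """Exact protocol-score pmf under the independence model.

    Sequential convolution over the factor components (a weighted
    Poisson-binomial): each weight-1 factor contributes {0, 1}, the BMI band
    contributes {0, 1, 2}, and — for the final score — the postpartum markup
    contributes {0, 1}. Set ``include_markup=False`` for the pre-operative
    score distribution.
    """
    prev = params.factor_prevalences
    pmf = np.array([1.0])

    p_over = prev.get("bmi_25_to_30", 0.0)
    p_obese = prev.get("bmi_ge_30", 0.0)
    pmf = _convolve(pmf, {0: 1 - p_over - p_obese, 1: p_over, 2: p_obese})

    for f in WEIGHT_ONE_FACTORS:
        p = prev.get(f, 0.0)
        pmf = _convolve(pmf, {0: 1 - p, 1: p})

    if include_markup:
        p = prev.get("pph_or_transfusion", 0.0)
        pmf = _convolve(pmf, {0: 1 - p, 1: p})

    # renormalize away accumulated float error before the 1e-12 invariant
    pmf = pmf / pmf.sum()
    return ScoreDistribution(pmf={k: float(p) for k, p in enumerate(pmf)})


def expected_prophylaxis_rates(
    params: SyntheticCohortParams,
    ruleset: Optional[RuleSet] = None,
) -> tuple[float, float]:
    """Expected (mechanical %, pharmacologic %) under the independence model.

    Mechanical prophylaxis is attributed from the pre-operative score
    (P(pre-op >= 2)); pharmacologic from the final score (P(final >= 3)).
    """
    rs = ruleset or default_ruleset()
    pre = exact_score_distribution(params, include_markup=False)
    fin = exact_score_distribution(params, include_markup=True)
    return (
        100.0 * pre.tail_prob(rs.mechanical_threshold),
        100.0 * fin.tail_prob(rs.pharmacologic_threshold),
    )
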