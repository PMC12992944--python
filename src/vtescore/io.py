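"""Patient-table CSV I/O, result writing and bundled fixtures.

The patient CSV schema has one row per patient with columns named exactly as
:class:`~vtescore.types.RiskFactorProfile` fields (booleans encoded 0/1 or
true/false) plus optional ``vte_event``/``bleeding_event`` outcome columns.
A schema-version comment line is written at the top of every file; parsing is
strict by default — clinical-style data should fail loudly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from pydantic import ValidationError

from .types import RiskFactorProfile

__all__ = [
    "PatientTable",
    "read_patient_csv",
    "write_patient_csv",
    "write_results",
    "load_worked_example_cases",
    "SCHEMA_VERSION",
]

logger = logging.getLogger("vtescore")

SCHEMA_VERSION = "1"
_SCHEMA_COMMENT = f"# vtescore patient table, schema={SCHEMA_VERSION}"

MANDATORY_COLUMNS = (
    "age",
    "bmi",
    "weight",
    "parity",
    "gestational_age_at_delivery",
    "cs_urgency",
)
BOOLEAN_COLUMNS = (
    "pre_eclampsia",
    "multiple_pregnancy",
    "prolonged_labor_gt24h",
    "stillbirth",
    "medical_comorbidity",
    "low_risk_thrombophilia",
    "current_smoker",
    "gross_varicose_veins",
    "current_systemic_infection",
    "immobility",
    "family_history_vte",
    "transfusion",
    "on_antenatal_lmwh",
    "prior_vte_or_high_risk_thrombophilia",
)
OUTCOME_COLUMNS = ("vte_event", "bleeding_event")
SCHEMA_COLUMNS = MANDATORY_COLUMNS + BOOLEAN_COLUMNS + ("pph_ml",) + OUTCOME_COLUMNS

_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no", ""}


@dataclass
class PatientTable:
    """Validated patient records plus provenance metadata."""

    df: pd.DataFrame
    source: Optional[str] = None
    schema_version: str = SCHEMA_VERSION
    warnings: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def to_profiles(self) -> list[RiskFactorProfile]:
        cols = [c for c in self.df.columns if c in SCHEMA_COLUMNS and c not in OUTCOME_COLUMNS]
        return [
            RiskFactorProfile.model_validate(rec)
            for rec in self.df[cols].to_dict("records")
        ]


def _parse_bool_column(col: pd.Series, name: str) -> pd.Series:
    def parse(v, idx):
        if isinstance(v, bool):
            return v
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE or s == "nan":
            return False
        raise ValueError(f"unparseable boolean {v!r} at row {idx}, column {name!r}")

    return pd.Series([parse(v, i) for i, v in col.items()], index=col.index)


def read_patient_csv(
    path: Union[str, Path], validate: bool = True
) -> PatientTable:
    """Read and validate a patient CSV.

    Unknown columns are kept but warned about; missing optional booleans
    default to false with a warning; a missing mandatory column raises a
    schema error naming the column. With ``validate=True`` every row is
    checked against the profile invariants and an invalid cell raises with
    its row index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    warns: list[str] = []
    unknown = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    if unknown:
        warns.append(f"unknown columns kept unvalidated: {unknown}")
    for c in BOOLEAN_COLUMNS:
        if c not in df.columns:
            warns.append(f"optional column {c!r} missing; defaulting to false")
            df[c] = False
        else:
            df[c] = _parse_bool_column(df[c], c)
    if "pph_ml" not in df.columns:
        warns.append("optional column 'pph_ml' missing; defaulting to 0")
        df["pph_ml"] = 0.0
    for c in OUTCOME_COLUMNS:
        if c in df.columns:
            df[c] = _parse_bool_column(df[c], c)
    for w in warns:
        logger.warning(w)

    if validate and len(df):
        cols = [c for c in df.columns if c in SCHEMA_COLUMNS and c not in OUTCOME_COLUMNS]
        for i, rec in enumerate(df[cols].to_dict("records")):
            try:
                RiskFactorProfile.model_validate(rec)
            except ValidationError as exc:
                raise ValueError(f"invalid record at row {i}: {exc}") from exc

    return PatientTable(df=df, source=str(path), warnings=warns)


def write_patient_csv(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a patient table with the schema-version header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_SCHEMA_COMMENT + "\n")
        df.to_csv(fh, index=False)
    return path


def write_results(
    results: pd.DataFrame,
    path: Union[str, Path],
    text_report: Optional[str] = None,
    ndigits: int = 4,
) -> Path:
    """Write a results table: machine CSV (unrounded) plus optional text.

    The CSV carries full-precision values in deterministic column order; the
    companion ``.txt`` (when ``text_report`` is given) carries the
    printed-precision human-readable report.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if len(results) == 0:
        logger.warning("writing empty results table (header only)")
    results.to_csv(path, index=False)
    if text_report is not None:
        path.with_suffix(".txt").write_text(text_report)
    return path


def load_worked_example_cases() -> PatientTable:
    """The 16 published postpartum-VTE case profiles (bundled fixture).

    Each row reconstructs one case's risk-factor list; ``printed_score`` is
    the score as published and ``expected_final_score`` the score implied by
    the tabulated factor list (these differ for one protocol-period case
    whose published scalar is inconsistent with its own factor annotation —
    see docs/methods.md).
    """
    src = files("vtescore").joinpath("data/published_vte_cases.csv")
    with src.open("rb") as fh:
        df = pd.read_csv(fh, comment="#")
    for c in BOOLEAN_COLUMNS:
        if c not in df.columns:
            df[c] = False
        else:
            df[c] = _parse_bool_column(df[c], c)
    df["vte_event"] = _parse_bool_column(df["vte_event"], "vte_event")
    return PatientTable(df=df, source="bundled:published_vte_cases.csv")
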