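"""Per-patient threshold evaluation of the five burn-care outcome indicators.

A patient achieves **textbook outcome** when all five indicators are achieved
simultaneously:

1. *length_of_stay* — actual index-admission LOS not longer than predicted LOS;
2. *wound_infection* — no clinically diagnosed wound infection in the QCI period;
3. *other_complications* — no coded complication, where ARDS and polyneuropathy
   do not count in patients with TBSA >= 20% (they occur frequently in that
   subgroup as part of the expected course);
4. *discharge_destination* — discharged to the usual residence (a deceased
   patient cannot be, so death fails this indicator);
5. *predicted_mortality* — no unexpected death: failing requires death in the
   QCI period attributed to the primary treatment while the predicted risk of
   mortality was at or below the cutoff (default 25%).
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .risk_models import (
    DEFAULT_RISK_MODEL,
    RiskModelConfig,
    predicted_los,
    predicted_mortality_risk,
    revised_baux_score,
)

__all__ = [
    "INDICATORS",
    "ETIOLOGIES",
    "DISCHARGE_DESTINATIONS",
    "COMPLICATION_VOCABULARY",
    "TBSA_EXEMPT_COMPLICATIONS",
    "TBSA_EXEMPTION_THRESHOLD",
    "PatientRecord",
    "IndicatorEvaluation",
    "TextbookOutcome",
    "eval_length_of_stay",
    "eval_wound_infection",
    "eval_other_complications",
    "eval_discharge_destination",
    "eval_predicted_mortality",
    "evaluate_patient",
    "textbook_outcome",
]

INDICATORS = (
    "length_of_stay",
    "wound_infection",
    "other_complications",
    "discharge_destination",
    "predicted_mortality",
)

ETIOLOGIES = ("flame", "scald", "fat_hot_oil", "contact", "chemical", "electrical", "other")
DISCHARGE_DESTINATIONS = ("usual_residence", "other", "deceased")

# complications not counted in patients with TBSA >= this threshold
TBSA_EXEMPTION_THRESHOLD = 20.0
TBSA_EXEMPT_COMPLICATIONS = frozenset({"ards", "polyneuropathy"})


def _load_vocabulary() -> frozenset:
    text = resources.files("bcqci.data").joinpath("complications_v1.txt").read_text()
    codes = []
    for line in text.splitlines():
        line = re.sub(r"#.*$", "", line).strip()
        if line:
            codes.append(line)
    return frozenset(codes)


COMPLICATION_VOCABULARY = _load_vocabulary()


@dataclass
class PatientRecord:
    """One admitted adult burn patient with clinical course and utilization.

    ``qci_date`` is the start of the first specialized-burn-care episode; all
    outcomes and utilization refer to the 12-month QCI period that follows.
    ``utilization`` maps priced item codes to volumes (days, sessions, ...).
    """

    patient_id: str
    qci_date: _dt.date
    age_years: int
    sex: str
    etiology: str
    tbsa_percent: float
    inhalation_injury: bool
    actual_los_days: int
    icu_days: int
    readmission_days: int
    n_surgeries: int
    complications: tuple = ()
    wound_infection: bool = False
    died_in_qci_period: bool = False
    death_due_to_primary_treatment: bool = False
    discharge_destination: str = "usual_residence"
    utilization: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_years < 18:
            raise ValueError(f"{self.patient_id}: adult cohort requires age >= 18")
        if not (0.0 <= self.tbsa_percent <= 100.0):
            raise ValueError(f"{self.patient_id}: TBSA must lie in [0, 100]")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if self.etiology not in ETIOLOGIES:
            raise ValueError(f"{self.patient_id}: unknown etiology {self.etiology!r}")
        if self.discharge_destination not in DISCHARGE_DESTINATIONS:
            raise ValueError(
                f"{self.patient_id}: unknown discharge destination {self.discharge_destination!r}"
            )
        if min(self.actual_los_days, self.icu_days, self.readmission_days, self.n_surgeries) < 0:
            raise ValueError(f"{self.patient_id}: negative day/surgery count")
        if self.icu_days > self.actual_los_days:
            raise ValueError(f"{self.patient_id}: ICU days exceed index-admission LOS")
        if self.died_in_qci_period != (self.discharge_destination == "deceased"):
            raise ValueError(
                f"{self.patient_id}: death flag and discharge destination disagree"
            )
        if any(v < 0 for v in self.utilization.values()):
            raise ValueError(f"{self.patient_id}: negative utilization volume")
        self.complications = tuple(self.complications)


@dataclass(frozen=True)
class IndicatorEvaluation:
    indicator: str
    achieved: bool
    detail: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class TextbookOutcome:
    achieved: bool
    failed_indicators: tuple

    def __post_init__(self) -> None:
        assert self.achieved == (len(self.failed_indicators) == 0)


def eval_length_of_stay(record: PatientRecord, predicted: float) -> IndicatorEvaluation:
    """Achieved unless the actual index LOS is strictly longer than predicted."""
    if predicted < 0:
        raise ValueError("predicted LOS must be non-negative")
    return IndicatorEvaluation(
        "length_of_stay",
        achieved=record.actual_los_days <= predicted,
        detail={"predicted_los_days": float(predicted), "actual_los_days": record.actual_los_days},
    )


def eval_wound_infection(record: PatientRecord) -> IndicatorEvaluation:
    return IndicatorEvaluation("wound_infection", achieved=not record.wound_infection)


def counted_complications(record: PatientRecord) -> tuple:
    """Complication codes after the high-TBSA exemption, validated against the vocabulary."""
    unknown = [c for c in record.complications if c not in COMPLICATION_VOCABULARY]
    if unknown:
        raise ValueError(f"unknown complication code(s): {', '.join(sorted(unknown))}")
    if record.tbsa_percent >= TBSA_EXEMPTION_THRESHOLD:
        return tuple(c for c in record.complications if c not in TBSA_EXEMPT_COMPLICATIONS)
    return tuple(record.complications)


def eval_other_complications(record: PatientRecord) -> IndicatorEvaluation:
    counted = counted_complications(record)
    return IndicatorEvaluation(
        "other_complications",
        achieved=len(counted) == 0,
        detail={"n_counted_complications": len(counted)},
    )


def eval_discharge_destination(record: PatientRecord) -> IndicatorEvaluation:
    return IndicatorEvaluation(
        "discharge_destination",
        achieved=record.discharge_destination == "usual_residence",
    )


def eval_predicted_mortality(
    record: PatientRecord,
    risk: float,
    cutoff: float = DEFAULT_RISK_MODEL.mortality_risk_cutoff,
    rule: str = "unexpected_death",
) -> IndicatorEvaluation:
    """Fail on an unexpected death.

    Under the default ``unexpected_death`` rule the indicator fails only when
    the patient died in the QCI period, the death is attributed to the primary
    treatment (or its complications), and the predicted mortality risk was at
    or below the cutoff.  The alternative ``any_attributed_or_low_risk`` rule
    reads the attribution and low-risk conditions disjunctively, so any death
    that is either attributed or low-risk fails.  Survivors always achieve.
    """
    if not (0.0 <= risk <= 1.0):
        raise ValueError("risk must be a probability")
    if not record.died_in_qci_period:
        failed = False
    elif rule == "unexpected_death":
        failed = record.death_due_to_primary_treatment and risk <= cutoff
    elif rule == "any_attributed_or_low_risk":
        failed = record.death_due_to_primary_treatment or risk <= cutoff
    else:
        raise ValueError(f"unknown mortality rule variant {rule!r}")
    return IndicatorEvaluation(
        "predicted_mortality",
        achieved=not failed,
        detail={"predicted_risk": float(risk), "cutoff": float(cutoff)},
    )


def evaluate_patient(
    record: PatientRecord,
    config: RiskModelConfig = DEFAULT_RISK_MODEL,
    mortality_rule: str = "unexpected_death",
) -> dict:
    """All five indicator evaluations for one patient, keyed by indicator name."""
    pred_los = predicted_los(
        record.age_years, record.tbsa_percent, record.inhalation_injury, config
    )
    score = revised_baux_score(
        record.age_years, record.tbsa_percent, record.inhalation_injury, config
    )
    risk = predicted_mortality_risk(score, config)
    evals = {
        "length_of_stay": eval_length_of_stay(record, pred_los),
        "wound_infection": eval_wound_infection(record),
        "other_complications": eval_other_complications(record),
        "discharge_destination": eval_discharge_destination(record),
        "predicted_mortality": eval_predicted_mortality(
            record, risk, config.mortality_risk_cutoff, rule=mortality_rule
        ),
    }
    evals["predicted_mortality"].detail["revised_baux_score"] = float(score)  # type: ignore[index]
    return evals


def textbook_outcome(evaluations: Iterable[IndicatorEvaluation]) -> TextbookOutcome:
    """Conjunction of the five indicators; lists the failed ones."""
    evals = list(evaluations)
    names = [e.indicator for e in evals]
    if sorted(names) != sorted(INDICATORS):
        raise ValueError(
            f"textbook outcome needs exactly one evaluation per indicator, got {names}"
        )
    failed = tuple(e.indicator for e in evals if not e.achieved)
    return TextbookOutcome(achieved=len(failed) == 0, failed_indicators=failed)
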