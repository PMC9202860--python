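"""Patient input -> nomogram placement -> treatment advice -> family education.

The engine routes one infant's record through the guideline table: compute
postnatal age, convert TSB to mg/dL, resolve the stratum and risk class,
look up the phototherapy and exchange thresholds at that age, and emit one
of three advice tiers:

* ``no_treatment`` — TSB below the phototherapy threshold;
* ``start_phototherapy`` — TSB at or above the phototherapy threshold but
  below the exchange threshold;
* ``intensive_pt_consider_exchange`` — TSB at or above the exchange
  threshold: start intensive phototherapy immediately and consider exchange
  transfusion.

A TSB exactly at a threshold triggers the treatment (conservative rule).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources

import yaml

from .guideline_tables import (
    GuidelineTable,
    Intervention,
    RiskClass,
    Stratum,
    stratum_for,
)

__all__ = [
    "RiskFactor",
    "AdviceTier",
    "PatientRecord",
    "Recommendation",
    "MissingTSBError",
    "UMOL_PER_MG_DL",
    "HYPOALBUMINEMIA_CUTOFF",
    "postnatal_age_hours",
    "to_mg_dl",
    "risk_class_of",
    "recommend",
    "education_checklist",
]

# Standard molar conversion for bilirubin: 1 mg/dL = 17.1 umol/L.
UMOL_PER_MG_DL = 17.1

# Hypoalbuminemia cut-off, kept verbatim as the tool prints it ("<30 mg/L").
# The conventional unit for serum albumin is g/L; see docs/methods.md.
HYPOALBUMINEMIA_CUTOFF = "<30 mg/L"


class RiskFactor(str, enum.Enum):
    """Neurotoxicity risk factors (adapted from the AAP risk-factor list)."""

    ABO_RH_INCOMPATIBILITY = "abo_rh_incompatibility"
    HAEMOLYSIS = "haemolysis"          # G6PD deficiency or spherocytosis
    OTHER_ILLNESS = "other_illness"    # asphyxia, infection
    HYPOALBUMINEMIA = "hypoalbuminemia"
    NONE_DECLARED = "none_declared"
    UNKNOWN = "unknown"


class TSBUnit(str, enum.Enum):
    MG_DL = "mg_dl"
    UMOL_L = "umol_l"


class AdviceTier(enum.IntEnum):
    """Ordered advice tiers; higher means more aggressive treatment."""

    NO_TREATMENT = 0
    START_PHOTOTHERAPY = 1
    INTENSIVE_PT_CONSIDER_EXCHANGE = 2

    @property
    def label(self) -> str:
        return _TIER_LABELS[self]


_TIER_LABELS = {
    AdviceTier.NO_TREATMENT: "no_treatment",
    AdviceTier.START_PHOTOTHERAPY: "start_phototherapy",
    AdviceTier.INTENSIVE_PT_CONSIDER_EXCHANGE: "intensive_pt_consider_exchange",
}


class MissingTSBError(ValueError):
    """Raised when advice is requested without a TSB measurement."""

    def __init__(self) -> None:
        super().__init__(
            "no TSB value: the infant cannot be placed on the nomogram; "
            "measure total serum bilirubin before requesting advice"
        )


@dataclass(frozen=True)
class PatientRecord:
    """One infant's state at one record time point."""

    ga_weeks: float
    birth_datetime: datetime
    record_datetime: datetime
    bw_g: float
    tsb_value: float | None
    tsb_unit: TSBUnit = TSBUnit.MG_DL
    risk_factors: frozenset[RiskFactor] = field(
        default_factory=lambda: frozenset({RiskFactor.UNKNOWN})
    )

    def __post_init__(self) -> None:
        if self.record_datetime < self.birth_datetime:
            raise ValueError(
                f"record time {self.record_datetime} precedes birth "
                f"{self.birth_datetime}"
            )
        if self.bw_g <= 0:
            raise ValueError(f"birth weight must be positive, got {self.bw_g}")
        if self.tsb_value is not None and self.tsb_value < 0:
            raise ValueError(f"TSB must be non-negative, got {self.tsb_value}")
        rf = frozenset(self.risk_factors)
        object.__setattr__(self, "risk_factors", rf)
        if not rf:
            raise ValueError("risk_factors must not be empty; use none_declared")
        named = rf - {RiskFactor.NONE_DECLARED}
        if RiskFactor.NONE_DECLARED in rf and named:
            raise ValueError(
                "none_declared is exclusive of named risk factors, got "
                f"{sorted(f.value for f in rf)}"
            )

    @property
    def age_hours(self) -> float:
        return postnatal_age_hours(self.birth_datetime, self.record_datetime)

    @property
    def tsb_mg_dl(self) -> float | None:
        if self.tsb_value is None:
            return None
        return to_mg_dl(self.tsb_value, self.tsb_unit)


@dataclass(frozen=True)
class Recommendation:
    """Treatment advice plus every intermediate quantity, for display."""

    advice: AdviceTier
    stratum: Stratum
    risk_class: RiskClass
    age_hours: float
    tsb_mg_dl: float
    pt_threshold: float
    et_threshold: float

    def to_dict(self) -> dict:
        return {
            "advice": self.advice.label,
            "stratum": self.stratum.label,
            "risk_class": self.risk_class.value,
            "age_hours": self.age_hours,
            "tsb_mg_dl": self.tsb_mg_dl,
            "pt_threshold_mg_dl": self.pt_threshold,
            "et_threshold_mg_dl": self.et_threshold,
        }


def postnatal_age_hours(birth: datetime, record: datetime) -> float:
    """Exact postnatal age in hours (real-valued)."""
    if record < birth:
        raise ValueError(f"record time {record} precedes birth {birth}")
    return (record - birth).total_seconds() / 3600.0


def to_mg_dl(value: float, unit: TSBUnit | str) -> float:
    """Convert a TSB value to mg/dL (umol/L divides by 17.1)."""
    if value < 0:
        raise ValueError(f"TSB must be non-negative, got {value}")
    unit = TSBUnit(unit)
    if unit is TSBUnit.MG_DL:
        return float(value)
    return float(value) / UMOL_PER_MG_DL


def risk_class_of(risk_factors: frozenset[RiskFactor] | set[RiskFactor]) -> RiskClass:
    """Collapse the risk-factor set to the nomogram's two risk classes.

    'No risk factors declared' is uncomplicated hyperbilirubinemia; any named
    factor — or 'unknown', since the factors could not be excluded — places
    the infant in the with-risk class.
    """
    rf = frozenset(risk_factors)
    if not rf:
        raise ValueError("risk factor set must not be empty")
    if rf == {RiskFactor.NONE_DECLARED}:
        return RiskClass.NO_RISK
    return RiskClass.WITH_RISK


def recommend(patient: PatientRecord, guideline: GuidelineTable) -> Recommendation:
    """Full advice pipeline for one patient record.

    Raises :class:`MissingTSBError` when the record carries no TSB value.
    """
    tsb = patient.tsb_mg_dl
    if tsb is None:
        raise MissingTSBError()
    stratum = stratum_for(patient.ga_weeks, patient.bw_g)
    rc = risk_class_of(patient.risk_factors)
    age = patient.age_hours
    pt_thr = guideline.threshold(stratum, Intervention.PHOTOTHERAPY, rc, age)
    et_thr = guideline.threshold(stratum, Intervention.EXCHANGE_TRANSFUSION, rc, age)
    if tsb >= et_thr:
        tier = AdviceTier.INTENSIVE_PT_CONSIDER_EXCHANGE
    elif tsb >= pt_thr:
        tier = AdviceTier.START_PHOTOTHERAPY
    else:
        tier = AdviceTier.NO_TREATMENT
    return Recommendation(
        advice=tier,
        stratum=stratum,
        risk_class=rc,
        age_hours=age,
        tsb_mg_dl=tsb,
        pt_threshold=pt_thr,
        et_threshold=et_thr,
    )


def _load_checklist_catalog() -> dict:
    ref = resources.files("bilinorm.data").joinpath("education_checklist.yaml")
    try:
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    except FileNotFoundError as exc:  # packaging defect
        raise RuntimeError("education checklist resource missing") from exc
    if not isinstance(raw, dict) or "tiers" not in raw:
        raise RuntimeError("education checklist resource malformed")
    return raw


def education_checklist(
    recommendation: Recommendation, lang: str = "en"
) -> list[str]:
    """Family-education checklist items for an advice tier.

    Items follow the NICE neonatal-jaundice communication guidance, adapted
    for the advice tiers this tool emits.  Bilingual catalog (``en``/``id``);
    English default.  Deterministic: same recommendation, same items.
    """
    catalog = _load_checklist_catalog()
    if lang not in catalog.get("languages", ["en"]):
        raise ValueError(f"unsupported checklist language: {lang!r}")
    tier_items = catalog["tiers"].get(recommendation.advice.label)
    if not tier_items:
        raise RuntimeError(
            f"checklist catalog has no items for tier {recommendation.advice.label}"
        )
    common = catalog.get("common", {}).get(lang, [])
    return list(common) + [item[lang] for item in tier_items]
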