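"""Acute bilirubin encephalopathy (BIND-M) and kernicterus spectrum
disorder (KSD) scoring.

The classification bands are fixed clinical cut-offs:

* BIND-M total: 0 no ABE; 1-4 mild; 5-6 moderate; >6 severe.
* KSD total: 0-2 no kernicterus; 3-5 possible; 6-9 probable; 10-14 definite.

Per-item point rubrics vary between published versions, so item maxima are
configurable; the bands above depend only on the total and are hard-coded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "ABEBand",
    "KSDBand",
    "BINDMAssessment",
    "KSDAssessment",
    "bind_m_classify",
    "ksd_classify",
    "bind_m_band",
    "ksd_band",
    "KSD_MAX_TOTAL",
]


class ABEBand(str, enum.Enum):
    NO_ABE = "no_abe"
    MILD_ABE = "mild_abe"
    MODERATE_ABE = "moderate_abe"
    SEVERE_ABE = "severe_abe"


class KSDBand(str, enum.Enum):
    NO_KERNICTERUS = "no_kernicterus"
    POSSIBLE = "possible"
    PROBABLE = "probable"
    DEFINITE = "definite"


# Default per-item maxima for the modified BIND exam (configurable).
BINDM_DEFAULT_MAXIMA = {
    "mental_status": 3,
    "muscle_tone": 3,
    "altered_cry": 2,
    "altered_gaze": 1,
}

KSD_MAX_TOTAL = 14

# Default per-component maxima for the KSD risk score; the components sum
# to the 0-14 scale the bands are defined on.
KSD_DEFAULT_MAXIMA = {
    "highest_tsb": 3,
    "risk_factors": 1,
    "neuro_exam_presentation": 2,
    "neuro_exam_followup": 2,
    "enamel_dysplasia": 1,
    "abr_result": 2,
    "mri_findings": 3,
}


def _check_items(items: dict[str, int], maxima: dict[str, int], what: str) -> None:
    if set(items) != set(maxima):
        raise ValueError(
            f"{what}: items {sorted(items)} do not match rubric {sorted(maxima)}"
        )
    for name, score in items.items():
        if not isinstance(score, int):
            raise ValueError(f"{what}: item '{name}' must be an integer")
        if not (0 <= score <= maxima[name]):
            raise ValueError(
                f"{what}: item '{name}' = {score} outside [0, {maxima[name]}]"
            )


@dataclass(frozen=True)
class BINDMAssessment:
    """One modified-BIND exam: mental status, muscle tone, cry, gaze."""

    mental_status: int
    muscle_tone: int
    altered_cry: int
    altered_gaze: int
    maxima: dict[str, int] = field(default_factory=lambda: dict(BINDM_DEFAULT_MAXIMA))

    def __post_init__(self) -> None:
        _check_items(self.items, self.maxima, "BIND-M")

    @property
    def items(self) -> dict[str, int]:
        return {
            "mental_status": self.mental_status,
            "muscle_tone": self.muscle_tone,
            "altered_cry": self.altered_cry,
            "altered_gaze": self.altered_gaze,
        }

    @property
    def total(self) -> int:
        return sum(self.items.values())


@dataclass(frozen=True)
class KSDAssessment:
    """One kernicterus spectrum disorder risk assessment (total 0-14)."""

    components: dict[str, int]
    maxima: dict[str, int] = field(default_factory=lambda: dict(KSD_DEFAULT_MAXIMA))

    def __post_init__(self) -> None:
        _check_items(self.components, self.maxima, "KSD")
        if self.total > KSD_MAX_TOTAL:
            raise ValueError(f"KSD total {self.total} exceeds {KSD_MAX_TOTAL}")

    @property
    def total(self) -> int:
        return sum(self.components.values())


def bind_m_band(total: int) -> ABEBand:
    """Band for a BIND-M total: 0 / 1-4 / 5-6 / >6."""
    if total < 0:
        raise ValueError(f"BIND-M total must be non-negative, got {total}")
    if total == 0:
        return ABEBand.NO_ABE
    if total <= 4:
        return ABEBand.MILD_ABE
    if total <= 6:
        return ABEBand.MODERATE_ABE
    return ABEBand.SEVERE_ABE


def ksd_band(total: int) -> KSDBand:
    """Band for a KSD total: 0-2 / 3-5 / 6-9 / 10-14."""
    if not (0 <= total <= KSD_MAX_TOTAL):
        raise ValueError(f"KSD total must be in [0, {KSD_MAX_TOTAL}], got {total}")
    if total <= 2:
        return KSDBand.NO_KERNICTERUS
    if total <= 5:
        return KSDBand.POSSIBLE
    if total <= 9:
        return KSDBand.PROBABLE
    return KSDBand.DEFINITE


def bind_m_classify(assessment: BINDMAssessment) -> tuple[ABEBand, int]:
    """Classify an exam into an ABE severity band; returns (band, total)."""
    total = assessment.total
    return bind_m_band(total), total


def ksd_classify(assessment: KSDAssessment) -> tuple[KSDBand, int]:
    """Classify a follow-up risk assessment; returns (band, total)."""
    total = assessment.total
    return ksd_band(total), total
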