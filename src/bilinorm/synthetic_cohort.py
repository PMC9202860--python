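"""Seeded synthetic chart-review cohorts and packaged study fixtures.

Two things live here:

* :func:`fixtures` — the published aggregate tables of the two-hospital
  evaluation study: the pre/post treatment-classification and demographic
  contingency tables (255 pre-introduction and 181 post-introduction
  records) and the 43-respondent technology-acceptance questionnaire counts.

* :func:`generate_cohort` — a generator of individual-level treatment
  records whose audit classification is known by construction: each record
  first draws its intended category (correct / over / under / inappropriate)
  from configurable per-epoch rates, then builds a TSB value and treatment
  flags consistent with that category relative to the guideline thresholds.
  This guarantees the audit pipeline can be tested end to end without
  inventing bilirubin kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .adherence_audit import ContingencyTable, Epoch, TreatmentRecord
from .decision_engine import PatientRecord, RiskFactor, TSBUnit
from .guideline_tables import (
    GuidelineTable,
    Intervention,
    RiskClass,
    stratum_for,
    threshold_at,
)
from .questionnaire import LikertItem, LikertTable, Section

__all__ = [
    "CohortConfig",
    "StudyFixtures",
    "fixtures",
    "generate_cohort",
    "TABLE2_CALIBRATED_RATES",
]


# Per-epoch category rates observed in the evaluation study
# (correct, over, under, inappropriate).
TABLE2_CALIBRATED_RATES = {
    Epoch.PRE: {"correct": 0.38, "over": 0.34, "under": 0.14, "inappropriate": 0.14},
    Epoch.POST: {"correct": 0.51, "over": 0.32, "under": 0.10, "inappropriate": 0.07},
}

_CATEGORIES = ("correct", "over", "under", "inappropriate")

_RISK_CATEGORIES = (
    frozenset({RiskFactor.ABO_RH_INCOMPATIBILITY}),
    frozenset({RiskFactor.HAEMOLYSIS}),
    frozenset({RiskFactor.OTHER_ILLNESS}),
    frozenset({RiskFactor.NONE_DECLARED}),
    frozenset({RiskFactor.UNKNOWN}),
)

# birth-weight sampling windows (g) for the four preterm guideline bands
_BW_WINDOWS = ((500.0, 1000.0), (1001.0, 1499.0), (1500.0, 1999.0), (2000.0, 4200.0))


@dataclass(frozen=True)
class CohortConfig:
    """Marginals and category rates for a two-epoch synthetic cohort.

    Defaults reproduce the evaluation study's observed marginals: epoch
    sizes 255/181, 52% of infants below 35 weeks, the printed birth-weight
    and risk-factor splits, and the pre/post category rates 38/34/14/14 and
    51/32/10/7 percent.
    """

    n_pre: int = 255
    n_post: int = 181
    ga_lt35_prob: float = 226 / 436
    bw_band_probs: tuple[float, float, float, float] = (
        3 / 436,
        42 / 436,
        248 / 436,
        143 / 436,
    )
    risk_category_probs: tuple[float, ...] = (
        3 / 436,
        1 / 436,
        250 / 436,
        139 / 436,
        43 / 436,
    )
    target_rates: dict[Epoch, dict[str, float]] = field(
        default_factory=lambda: {
            e: dict(r) for e, r in TABLE2_CALIBRATED_RATES.items()
        }
    )
    tsb_noise_sd: float = 1.5  # mg/dL margin scale around thresholds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pre <= 0 or self.n_post <= 0:
            raise ValueError("epoch sizes must be positive")
        if not 0 <= self.ga_lt35_prob <= 1:
            raise ValueError("ga_lt35_prob must be a probability")
        for name, probs in (
            ("bw_band_probs", self.bw_band_probs),
            ("risk_category_probs", self.risk_category_probs),
        ):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability simplex")
        if len(self.risk_category_probs) != len(_RISK_CATEGORIES):
            raise ValueError("risk_category_probs must have 5 entries")
        for epoch, rates in self.target_rates.items():
            if set(rates) != set(_CATEGORIES):
                raise ValueError(f"epoch {epoch}: rates must cover {_CATEGORIES}")
            if abs(sum(rates.values()) - 1.0) > 1e-9:
                raise ValueError(f"epoch {epoch}: rates must sum to 1")
        if self.tsb_noise_sd <= 0:
            raise ValueError("tsb_noise_sd must be positive")


class GenerationError(RuntimeError):
    """The requested category cannot be constructed at the drawn thresholds."""


def _draw_patient_frame(rng: np.random.Generator, config: CohortConfig):
    """GA, BW, risk set and postnatal age for one record."""
    if rng.random() < config.ga_lt35_prob:
        ga = float(rng.uniform(28.0, 34.9))
    else:
        ga = float(rng.uniform(35.0, 42.0))
    band = int(rng.choice(4, p=np.asarray(config.bw_band_probs)))
    lo, hi = _BW_WINDOWS[band]
    bw = float(np.round(rng.uniform(lo, hi)))
    risk = _RISK_CATEGORIES[int(rng.choice(5, p=np.asarray(config.risk_category_probs)))]
    # postnatal age ~ few days, clipped to the nomogram's plotted span
    age_h = float(np.clip(rng.normal(98.0, 65.0), 4.0, 336.0))
    return ga, bw, risk, age_h


def _tsb_for_category(
    rng: np.random.Generator,
    category: str,
    pt_thr: float,
    noise_sd: float,
) -> tuple[float | None, bool, bool]:
    """(tsb, tsb_measured, pt_given) realising the intended category."""
    if pt_thr <= 0:
        raise GenerationError(f"phototherapy threshold {pt_thr} is not positive")
    margin = abs(rng.normal(0.0, noise_sd)) + 0.05
    if category == "inappropriate":
        return None, False, True
    if category == "under":
        return pt_thr + margin, True, False
    if category == "over":
        below = pt_thr - margin
        if below <= 0:
            below = pt_thr * float(rng.uniform(0.2, 0.8))
        return below, True, True
    # correct: indicated-and-treated or below-threshold-and-withheld
    if rng.random() < 0.5:
        return pt_thr + margin, True, True
    below = pt_thr - margin
    if below <= 0:
        below = pt_thr * float(rng.uniform(0.2, 0.8))
    return below, True, False


def generate_cohort(
    config: CohortConfig, guideline: GuidelineTable
) -> list[TreatmentRecord]:
    """Generate a deterministic two-epoch cohort of treatment records.

    For each record the intended audit category is drawn first, then the TSB
    and treatment flags are constructed so the record classifies into that
    category against ``guideline``.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    base_birth = datetime(2019, 1, 1, 0, 0)
    records: list[TreatmentRecord] = []
    plan = [(Epoch.PRE, config.n_pre), (Epoch.POST, config.n_post)]
    i = 0
    for epoch, n in plan:
        rates = config.target_rates[epoch]
        probs = np.array([rates[c] for c in _CATEGORIES])
        cats = rng.choice(len(_CATEGORIES), size=n, p=probs)
        for k in range(n):
            category = _CATEGORIES[int(cats[k])]
            ga, bw, risk, age_h = _draw_patient_frame(rng, config)
            stratum = stratum_for(ga, bw)
            rc = RiskClass.NO_RISK if risk == {RiskFactor.NONE_DECLARED} else RiskClass.WITH_RISK
            pt_thr = guideline.threshold(
                stratum, Intervention.PHOTOTHERAPY, rc, age_h
            )
            tsb, measured, pt_given = _tsb_for_category(
                rng, category, pt_thr, config.tsb_noise_sd
            )
            birth = base_birth + timedelta(hours=float(i))
            patient = PatientRecord(
                ga_weeks=round(ga, 1),
                birth_datetime=birth,
                record_datetime=birth + timedelta(hours=age_h),
                bw_g=bw,
                tsb_value=None if tsb is None else round(tsb, 2),
                tsb_unit=TSBUnit.MG_DL,
                risk_factors=risk,
            )
            records.append(
                TreatmentRecord(
                    patient=patient,
                    tsb_measured=measured,
                    pt_given=pt_given,
                    exchange_given=False,
                    epoch=epoch,
                )
            )
            i += 1
    return records


@dataclass(frozen=True)
class StudyFixtures:
    """Aggregate tables printed by the evaluation study."""

    classification: ContingencyTable
    correct_vs_rest: ContingencyTable
    over_vs_rest: ContingencyTable
    under_vs_rest: ContingencyTable
    inappropriate_vs_rest: ContingencyTable
    ga: ContingencyTable
    bw: ContingencyTable
    risk: ContingencyTable
    questionnaire: LikertTable


def fixtures() -> StudyFixtures:
    """Packaged in-study aggregate counts (pre n=255, post n=181; survey n=43)."""
    classification = ContingencyTable(
        ("correct", "over_treatment", "under_treatment", "inappropriate"),
        ((97, 93), (87, 57), (35, 18), (36, 13)),
    )
    return StudyFixtures(
        classification=classification,
        correct_vs_rest=ContingencyTable(
            ("correct", "other"), ((97, 93), (158, 88))
        ),
        over_vs_rest=ContingencyTable(
            ("over_treatment", "other"), ((87, 57), (168, 124))
        ),
        under_vs_rest=ContingencyTable(
            ("under_treatment", "other"), ((35, 18), (220, 163))
        ),
        inappropriate_vs_rest=ContingencyTable(
            ("inappropriate", "other"), ((36, 13), (219, 168))
        ),
        ga=ContingencyTable(("<35", ">=35"), ((137, 89), (118, 92))),
        bw=ContingencyTable(
            ("<1000", "1000-1499", "1500-2499", ">=2500"),
            ((2, 1), (22, 20), (149, 99), (82, 61)),
        ),
        risk=ContingencyTable(
            (
                "abo_rh_incompatibility",
                "haemolysis",
                "sick_infant",
                "no_risk_factors",
                "unknown",
            ),
            ((2, 1), (0, 1), (144, 106), (86, 53), (23, 20)),
        ),
        questionnaire=_questionnaire_fixture(),
    )


def _questionnaire_fixture() -> LikertTable:
    U, E, S, I = (
        Section.USEFULNESS,
        Section.EASE_OF_USE,
        Section.SUBJECTIVE_NORM,
        Section.INTENTION,
    )
    rows: list[tuple[Section, str, tuple[int, ...]]] = [
        (U, "Helps quickly decide the need of phototherapy", (0, 0, 1, 5, 1, 12, 24)),
        (U, "Raises awareness of acute bilirubin encephalopathy", (0, 0, 0, 6, 2, 11, 24)),
        (U, "Raises awareness of kernicterus", (0, 0, 0, 4, 2, 12, 25)),
        (U, "Improves hyperbilirubinemia management", (0, 0, 0, 4, 3, 12, 24)),
        (U, "Improves communication and education to parents", (0, 0, 0, 6, 2, 13, 22)),
        (U, "Improves follow-up for hyperbilirubinemia babies", (0, 0, 0, 4, 2, 14, 23)),
        (E, "Learning to use the tool is easy", (0, 0, 0, 6, 6, 10, 21)),
        (E, "Easy to get the information wanted", (0, 0, 0, 8, 4, 10, 21)),
        (E, "Clear and understandable", (0, 0, 2, 4, 2, 15, 20)),
        (E, "Flexible to use", (0, 0, 2, 3, 7, 10, 21)),
        (E, "Easy to become skillful in using it", (0, 0, 2, 3, 6, 13, 19)),
        (E, "Easy to use", (0, 0, 0, 5, 5, 11, 22)),
        (S, "Colleagues think the tool is important to you", (0, 0, 2, 6, 5, 12, 18)),
        (S, "Important to colleagues that you continue to use it", (0, 0, 1, 8, 4, 13, 17)),
        (S, "Would not matter to colleagues if you stopped", (2, 2, 3, 9, 8, 7, 12)),
        (S, "Colleagues would expect you to continue", (0, 1, 1, 6, 6, 13, 16)),
        (S, "No colleague surprised if you stopped", (0, 1, 3, 12, 5, 9, 13)),
        (S, "Colleagues disappointed if you stopped", (0, 2, 0, 13, 4, 11, 13)),
        (S, "Colleagues would make you feel guilty if you stopped", (0, 3, 1, 11, 7, 10, 11)),
        (I, "Intend to use the tool in the next months", (0, 0, 0, 5, 6, 14, 18)),
        (I, "Predict using the tool in the next months", (0, 0, 1, 6, 5, 12, 19)),
        (I, "Plan to use the tool in the next months", (0, 0, 1, 6, 4, 14, 18)),
    ]
    items = tuple(LikertItem(section=s, text=t, counts=c) for s, t, c in rows)
    return LikertTable(items=items, n_respondents=43)
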