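"""Stratified phototherapy / exchange-transfusion threshold nomograms.

A guideline table holds, for each patient stratum, four piecewise-linear
threshold curves of total serum bilirubin (TSB, mg/dL) against postnatal age
(hours): one per (intervention, risk class) pair.  Strata follow the
Indonesian national guideline layout: a single nomogram for term and
near-term infants (gestational age >= 35 weeks) and four birth-weight bands
for preterm infants (<=1000, 1001-1499, 1500-1999, >1999 g).

The package ships a clearly labelled placeholder default table (the national
guideline's numeric curves are not publicly printed); real guideline values
can be dropped in as a YAML file with the same schema.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "Intervention",
    "RiskClass",
    "BWBand",
    "StratumKind",
    "Stratum",
    "ThresholdCurve",
    "GuidelineTable",
    "GuidelineError",
    "GuidelineParseError",
    "GuidelineValidationError",
    "load_guideline",
    "load_default_guideline",
    "stratum_for",
    "threshold_at",
]


class GuidelineError(Exception):
    """Base class for guideline-table problems."""


class GuidelineParseError(GuidelineError):
    """The file does not conform to the guideline schema."""


class GuidelineValidationError(GuidelineError):
    """The parsed table violates a clinical consistency invariant."""


class Intervention(str, enum.Enum):
    PHOTOTHERAPY = "phototherapy"
    EXCHANGE_TRANSFUSION = "exchange_transfusion"


class RiskClass(str, enum.Enum):
    NO_RISK = "no_risk"
    WITH_RISK = "with_risk"


class BWBand(str, enum.Enum):
    """Preterm birth-weight bands, in grams, exactly as the guideline prints."""

    LE_1000 = "le_1000"
    B1001_1499 = "1001_1499"
    B1500_1999 = "1500_1999"
    GT_1999 = "gt_1999"


class StratumKind(str, enum.Enum):
    TERM_NEAR_TERM = "term_near_term"
    PRETERM_BW = "preterm_bw"


# GA at or above this (weeks) uses the term/near-term nomogram; below it the
# birth-weight bands apply.  35.0 exactly is assigned to term.
TERM_GA_CUTOFF_WEEKS = 35.0

GA_VALID_RANGE = (20.0, 45.0)
BW_VALID_RANGE = (300.0, 6000.0)


@dataclass(frozen=True)
class Stratum:
    """One cell of the guideline's patient stratification.

    Exactly one of ``ga_min_weeks`` (term stratum) or ``bw_band`` (preterm
    stratum) is set, depending on ``kind``.
    """

    kind: StratumKind
    ga_min_weeks: float | None = None
    bw_band: BWBand | None = None

    def __post_init__(self) -> None:
        if self.kind is StratumKind.TERM_NEAR_TERM:
            if self.ga_min_weeks is None or self.bw_band is not None:
                raise GuidelineValidationError(
                    "term_near_term stratum must set ga_min_weeks and not bw_band"
                )
        else:
            if self.bw_band is None or self.ga_min_weeks is not None:
                raise GuidelineValidationError(
                    "preterm_bw stratum must set bw_band and not ga_min_weeks"
                )

    @property
    def label(self) -> str:
        if self.kind is StratumKind.TERM_NEAR_TERM:
            return "term_near_term"
        return f"preterm_{self.bw_band.value}"


TERM_STRATUM = Stratum(StratumKind.TERM_NEAR_TERM, ga_min_weeks=TERM_GA_CUTOFF_WEEKS)
PRETERM_STRATA = {
    band: Stratum(StratumKind.PRETERM_BW, bw_band=band) for band in BWBand
}
ALL_STRATA: tuple[Stratum, ...] = (TERM_STRATUM, *PRETERM_STRATA.values())


@dataclass(frozen=True)
class ThresholdCurve:
    """Piecewise-linear TSB threshold (mg/dL) versus postnatal age (hours).

    Outside the knot span the curve is clamped to the terminal knot values
    (no extrapolation), which is deterministic and clinically conservative.
    """

    intervention: Intervention
    risk_class: RiskClass
    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise GuidelineValidationError(
                f"curve ({self.intervention.value}, {self.risk_class.value}): "
                "needs at least 2 knots"
            )
        ages = [a for a, _ in self.knots]
        tsbs = [t for _, t in self.knots]
        if any(a < 0 for a in ages):
            raise GuidelineParseError("knot ages must be non-negative")
        if any(ages[i] >= ages[i + 1] for i in range(len(ages) - 1)):
            raise GuidelineParseError(
                f"curve ({self.intervention.value}, {self.risk_class.value}): "
                f"knot ages must be strictly increasing, got {ages}"
            )
        if any(t <= 0 for t in tsbs):
            raise GuidelineParseError("all knot TSB values must be > 0 mg/dL")

    @property
    def ages(self) -> np.ndarray:
        return np.array([a for a, _ in self.knots], dtype=float)

    @property
    def tsbs(self) -> np.ndarray:
        return np.array([t for _, t in self.knots], dtype=float)


def threshold_at(curve: ThresholdCurve, age_hours: float) -> float:
    """TSB threshold (mg/dL) at a postnatal age, by linear interpolation.

    Ages before the first or after the last knot clamp to the terminal knot
    value.  ``age_hours`` must be non-negative.
    """
    if age_hours < 0:
        raise ValueError(f"age_hours must be non-negative, got {age_hours}")
    # np.interp clamps outside the knot span, which is exactly the contract
    return float(np.interp(age_hours, curve.ages, curve.tsbs))


def stratum_for(ga_weeks: float, bw_g: float) -> Stratum:
    """Route a (gestational age, birth weight) pair to its nomogram stratum.

    GA >= 35 weeks uses the term/near-term nomogram regardless of birth
    weight; below 35 weeks the birth-weight band applies (<=1000, 1001-1499,
    1500-1999, >1999 g, interpreted on the printed gram boundaries).
    """
    lo, hi = GA_VALID_RANGE
    if not (lo <= ga_weeks <= hi):
        raise ValueError(f"ga_weeks {ga_weeks} outside valid range {GA_VALID_RANGE}")
    blo, bhi = BW_VALID_RANGE
    if not (blo <= bw_g <= bhi):
        raise ValueError(f"bw_g {bw_g} outside valid range {BW_VALID_RANGE}")
    if ga_weeks >= TERM_GA_CUTOFF_WEEKS:
        return TERM_STRATUM
    if bw_g <= 1000:
        band = BWBand.LE_1000
    elif bw_g <= 1499:
        band = BWBand.B1001_1499
    elif bw_g <= 1999:
        band = BWBand.B1500_1999
    else:
        band = BWBand.GT_1999
    return PRETERM_STRATA[band]


@dataclass
class GuidelineTable:
    """A complete, validated set of threshold curves.

    ``curves`` maps stratum label -> (intervention, risk_class) -> curve.
    All TSB values are mg/dL internally; unit conversion happens upstream.
    """

    name: str
    version: str
    curves: dict[str, dict[tuple[Intervention, RiskClass], ThresholdCurve]] = field(
        default_factory=dict
    )

    # ages at which cross-curve orderings are checked eagerly
    _CHECK_GRID_H = np.linspace(0.0, 336.0, 337)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        expected = {s.label for s in ALL_STRATA}
        if set(self.curves) != expected:
            missing = expected - set(self.curves)
            extra = set(self.curves) - expected
            raise GuidelineValidationError(
                f"strata mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        pairs = [(i, r) for i in Intervention for r in RiskClass]
        for label, by_pair in self.curves.items():
            if set(by_pair) != set(pairs):
                raise GuidelineValidationError(
                    f"stratum {label}: must define all four "
                    "(intervention, risk_class) curves"
                )
            for rc in RiskClass:
                pt = by_pair[(Intervention.PHOTOTHERAPY, rc)]
                et = by_pair[(Intervention.EXCHANGE_TRANSFUSION, rc)]
                for age in self._CHECK_GRID_H:
                    if threshold_at(et, age) < threshold_at(pt, age) - 1e-9:
                        raise GuidelineValidationError(
                            f"stratum {label}, risk {rc.value}: exchange threshold "
                            f"below phototherapy threshold at hour {age:g}"
                        )
            for iv in Intervention:
                nr = by_pair[(iv, RiskClass.NO_RISK)]
                wr = by_pair[(iv, RiskClass.WITH_RISK)]
                for age in self._CHECK_GRID_H:
                    if threshold_at(wr, age) > threshold_at(nr, age) + 1e-9:
                        raise GuidelineValidationError(
                            f"stratum {label}, {iv.value}: with-risk threshold "
                            f"above no-risk threshold at hour {age:g}"
                        )

    def curve(
        self, stratum: Stratum, intervention: Intervention, risk_class: RiskClass
    ) -> ThresholdCurve:
        return self.curves[stratum.label][(intervention, risk_class)]

    def threshold(
        self,
        stratum: Stratum,
        intervention: Intervention,
        risk_class: RiskClass,
        age_hours: float,
    ) -> float:
        return threshold_at(self.curve(stratum, intervention, risk_class), age_hours)


def _parse_curve(
    label: str, iv: Intervention, rc: RiskClass, raw: object
) -> ThresholdCurve:
    if not isinstance(raw, list) or not all(
        isinstance(k, list) and len(k) == 2 for k in raw
    ):
        raise GuidelineParseError(
            f"stratum {label}, curve ({iv.value}, {rc.value}): knots must be a "
            "list of [age_hours, tsb_mg_dl] pairs"
        )
    try:
        knots = tuple((float(a), float(t)) for a, t in raw)
    except (TypeError, ValueError) as exc:
        raise GuidelineParseError(
            f"stratum {label}, curve ({iv.value}, {rc.value}): non-numeric knot"
        ) from exc
    return ThresholdCurve(intervention=iv, risk_class=rc, knots=knots)


def load_guideline(path: Union[str, Path]) -> GuidelineTable:
    """Load and validate a guideline-table YAML file.

    Schema (see docs/methods.md)::

        name: <text>
        version: <text>          # mandatory
        strata:
          term_near_term:
            phototherapy:
              no_risk:   [[age_h, tsb], ...]
              with_risk: [[age_h, tsb], ...]
            exchange_transfusion: {...}
          preterm_le_1000: {...}
          ...

    Malformed files raise :class:`GuidelineParseError` naming the offending
    field; clinically inconsistent tables (e.g. an exchange curve dipping
    below the phototherapy curve) raise :class:`GuidelineValidationError`
    naming the stratum and age.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise GuidelineParseError(f"{path}: not valid YAML: {exc}") from exc
    return _table_from_mapping(raw, source=str(path))


def _table_from_mapping(raw: object, source: str = "<mapping>") -> GuidelineTable:
    if not isinstance(raw, dict):
        raise GuidelineParseError(f"{source}: top level must be a mapping")
    for key in ("name", "version", "strata"):
        if key not in raw:
            raise GuidelineParseError(f"{source}: missing required field '{key}'")
    if not isinstance(raw["version"], str) or not raw["version"]:
        raise GuidelineParseError(f"{source}: 'version' must be a non-empty string")
    strata_raw = raw["strata"]
    if not isinstance(strata_raw, dict):
        raise GuidelineParseError(f"{source}: 'strata' must be a mapping")
    curves: dict[str, dict[tuple[Intervention, RiskClass], ThresholdCurve]] = {}
    for label, by_iv in strata_raw.items():
        if not isinstance(by_iv, dict):
            raise GuidelineParseError(f"{source}: stratum '{label}' must be a mapping")
        by_pair: dict[tuple[Intervention, RiskClass], ThresholdCurve] = {}
        for iv in Intervention:
            if iv.value not in by_iv:
                raise GuidelineParseError(
                    f"{source}: stratum '{label}' missing intervention '{iv.value}'"
                )
            by_rc = by_iv[iv.value]
            if not isinstance(by_rc, dict):
                raise GuidelineParseError(
                    f"{source}: stratum '{label}', '{iv.value}' must be a mapping"
                )
            for rc in RiskClass:
                if rc.value not in by_rc:
                    raise GuidelineParseError(
                        f"{source}: stratum '{label}', '{iv.value}' missing risk "
                        f"class '{rc.value}'"
                    )
                by_pair[(iv, rc)] = _parse_curve(label, iv, rc, by_rc[rc.value])
        curves[label] = by_pair
    return GuidelineTable(name=str(raw["name"]), version=raw["version"], curves=curves)


def load_default_guideline() -> GuidelineTable:
    """The packaged placeholder default table (see its version string)."""
    ref = resources.files("bilinorm.data").joinpath("default_guideline.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _table_from_mapping(raw, source="packaged default")
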