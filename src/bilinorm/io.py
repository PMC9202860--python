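"""Chart CSV readers/writers, report output and the nomogram plot.

Chart CSV schema (UTF-8, header, ISO-8601 timestamps, decimal point):

    ga_weeks, bw_g, birth_datetime, record_datetime, tsb_value, tsb_unit,
    risk_factors, pt_given, exchange_given, epoch

``tsb_value`` may be blank (no TSB measurement); ``risk_factors`` is a
``;``-separated list of risk-factor names; booleans are ``true``/``false``.
Unknown columns are ignored with a warning.  Malformed rows are collected
as row-level errors with line numbers, never dropped silently.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

from .adherence_audit import Epoch, TreatmentRecord
from .decision_engine import PatientRecord, Recommendation, RiskFactor, TSBUnit
from .guideline_tables import (
    GuidelineTable,
    Intervention,
    RiskClass,
    stratum_for,
)

__all__ = [
    "CHART_COLUMNS",
    "ChartReadError",
    "RowError",
    "read_charts",
    "write_charts",
    "write_report",
    "plot_nomogram",
]

CHART_COLUMNS = (
    "ga_weeks",
    "bw_g",
    "birth_datetime",
    "record_datetime",
    "tsb_value",
    "tsb_unit",
    "risk_factors",
    "pt_given",
    "exchange_given",
    "epoch",
)

@dataclass(frozen=True)
class RowError:
    line: int
    message: str


class ChartReadError(ValueError):
    """One or more chart rows failed validation."""

    def __init__(self, errors: list[RowError]):
        self.errors = errors
        lines = "; ".join(f"line {e.line}: {e.message}" for e in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} malformed chart row(s): {lines}{more}")

    def summary(self) -> dict:
        return {
            "n_errors": len(self.errors),
            "errors": [{"line": e.line, "message": e.message} for e in self.errors],
        }


def _parse_bool(raw: str) -> bool:
    v = raw.strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def _parse_row(row: dict[str, str]) -> TreatmentRecord:
    tsb_raw = (row.get("tsb_value") or "").strip()
    tsb = float(tsb_raw) if tsb_raw else None
    risk_raw = (row.get("risk_factors") or "").strip()
    risk = frozenset(
        RiskFactor(tok.strip()) for tok in risk_raw.split(";") if tok.strip()
    )
    patient = PatientRecord(
        ga_weeks=float(row["ga_weeks"]),
        birth_datetime=datetime.fromisoformat(row["birth_datetime"].strip()),
        record_datetime=datetime.fromisoformat(row["record_datetime"].strip()),
        bw_g=float(row["bw_g"]),
        tsb_value=tsb,
        tsb_unit=TSBUnit(row.get("tsb_unit", "mg_dl").strip() or "mg_dl"),
        risk_factors=risk,
    )
    return TreatmentRecord(
        patient=patient,
        tsb_measured=tsb is not None,
        pt_given=_parse_bool(row["pt_given"]),
        exchange_given=_parse_bool(row.get("exchange_given", "false") or "false"),
        epoch=Epoch(row["epoch"].strip()),
    )


def read_charts(path: str | Path) -> list[TreatmentRecord]:
    """Read a chart CSV; raises :class:`ChartReadError` listing bad rows."""
    records: list[TreatmentRecord] = []
    errors: list[RowError] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ChartReadError([RowError(1, "empty file: no header")])
        missing = set(CHART_COLUMNS) - set(reader.fieldnames)
        # exchange_given is optional; everything else is required
        missing -= {"exchange_given"}
        if missing:
            raise ChartReadError(
                [RowError(1, f"missing required columns: {sorted(missing)}")]
            )
        unknown = set(reader.fieldnames) - set(CHART_COLUMNS)
        if unknown:
            warnings.warn(f"{path}: ignoring unknown columns {sorted(unknown)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row))
            except (ValueError, KeyError) as exc:
                errors.append(RowError(lineno, str(exc)))
    if errors:
        raise ChartReadError(errors)
    return records


def write_charts(records: list[TreatmentRecord], path: str | Path) -> None:
    """Write records to a chart CSV (lossless round-trip with read_charts)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CHART_COLUMNS)
        for r in records:
            p = r.patient
            w.writerow(
                [
                    f"{p.ga_weeks:g}",
                    f"{p.bw_g:g}",
                    p.birth_datetime.isoformat(),
                    p.record_datetime.isoformat(),
                    "" if p.tsb_value is None else f"{p.tsb_value:g}",
                    p.tsb_unit.value,
                    ";".join(sorted(f.value for f in p.risk_factors)),
                    str(r.pt_given).lower(),
                    str(r.exchange_given).lower(),
                    r.epoch.value,
                ]
            )


def write_report(report: dict, path: str | Path) -> None:
    """Write a report mapping as pretty-printed JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")


def plot_nomogram(
    recommendation: Recommendation,
    guideline: GuidelineTable,
    path: str | Path,
) -> None:
    """Plot the patient's nomogram: both threshold curves plus the patient
    point at (postnatal age, TSB)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    stratum = recommendation.stratum
    rc = recommendation.risk_class
    pt = guideline.curve(stratum, Intervention.PHOTOTHERAPY, rc)
    et = guideline.curve(stratum, Intervention.EXCHANGE_TRANSFUSION, rc)
    ages = np.linspace(0, max(168.0, recommendation.age_hours * 1.1), 300)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(ages, np.interp(ages, pt.ages, pt.tsbs), label="phototherapy threshold",
            color="tab:blue")
    ax.plot(ages, np.interp(ages, et.ages, et.tsbs), label="exchange threshold",
            color="tab:red")
    ax.plot(
        [recommendation.age_hours],
        [recommendation.tsb_mg_dl],
        "ko",
        markersize=8,
        label="patient",
    )
    ax.set_xlabel("postnatal age (hours)")
    ax.set_ylabel("TSB (mg/dL)")
    ax.set_title(
        f"{stratum.label}, {rc.value} — advice: {recommendation.advice.label}"
    )
    ax.legend(loc="lower right")
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
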