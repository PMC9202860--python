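"""Guideline-adherence chart audit and pre/post epoch comparison.

Each treatment record (what was actually done) is compared with what the
guideline indicated at the record's TSB, postnatal age, stratum and risk
class, and classified four ways:

* correct — phototherapy given when indicated, or withheld when not;
* over_treatment — phototherapy given with TSB below the phototherapy
  threshold;
* under_treatment — no treatment despite TSB above the threshold;
* inappropriate — phototherapy given without any TSB measurement.

Records with neither a TSB measurement nor phototherapy are unevaluable and
excluded from the four-way table (reported separately).  Exchange
transfusion is recorded and reported but does not enter the classification,
which is defined purely on the phototherapy threshold.

Epoch comparisons use Pearson's chi-square without continuity correction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decision_engine import PatientRecord, Recommendation, recommend
from .guideline_tables import GuidelineTable, TERM_GA_CUTOFF_WEEKS

__all__ = [
    "Epoch",
    "Classification",
    "TreatmentRecord",
    "AuditResult",
    "ContingencyTable",
    "ChiSquareResult",
    "classify_treatment",
    "summarize_epochs",
    "pearson_chi_square",
    "compare_epochs",
    "EpochComparison",
]


class Epoch(str, enum.Enum):
    PRE = "pre"
    POST = "post"


class Classification(str, enum.Enum):
    CORRECT = "correct"
    OVER_TREATMENT = "over_treatment"
    UNDER_TREATMENT = "under_treatment"
    INAPPROPRIATE = "inappropriate"
    UNEVALUABLE = "unevaluable"


# row order of the four-way classification table, as reported
CATEGORY_ORDER = (
    Classification.CORRECT,
    Classification.OVER_TREATMENT,
    Classification.UNDER_TREATMENT,
    Classification.INAPPROPRIATE,
)


@dataclass(frozen=True)
class TreatmentRecord:
    """One administered-treatment record from a chart."""

    patient: PatientRecord
    tsb_measured: bool
    pt_given: bool
    exchange_given: bool
    epoch: Epoch

    def __post_init__(self) -> None:
        if not self.tsb_measured and self.patient.tsb_value is not None:
            raise ValueError("tsb_measured is False but the record carries a TSB value")
        if self.tsb_measured and self.patient.tsb_value is None:
            raise ValueError("tsb_measured is True but the record carries no TSB value")


@dataclass(frozen=True)
class AuditResult:
    record: TreatmentRecord
    classification: Classification
    indicated: Recommendation | None


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 counts, columns = (pre, post) epochs."""

    row_labels: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.row_labels) != len(self.counts):
            raise ValueError("row_labels and counts length mismatch")
        for row in self.counts:
            if len(row) != 2:
                raise ValueError("each row must have exactly 2 epoch counts")
            if any(c < 0 or int(c) != c for c in row):
                raise ValueError("counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def classify_treatment(
    record: TreatmentRecord, guideline: GuidelineTable
) -> AuditResult:
    """Classify one record against the guideline indication.

    Precedence: phototherapy without a TSB measurement is inappropriate;
    no TSB and no phototherapy is unevaluable; otherwise the given/indicated
    agreement decides correct / over / under.
    """
    if record.pt_given and not record.tsb_measured:
        return AuditResult(record, Classification.INAPPROPRIATE, None)
    if not record.tsb_measured:
        return AuditResult(record, Classification.UNEVALUABLE, None)
    rec = recommend(record.patient, guideline)
    indicated = rec.tsb_mg_dl >= rec.pt_threshold
    if indicated == record.pt_given:
        cls = Classification.CORRECT
    elif record.pt_given:
        cls = Classification.OVER_TREATMENT
    else:
        cls = Classification.UNDER_TREATMENT
    return AuditResult(record, cls, rec)


def summarize_epochs(results: list[AuditResult]) -> ContingencyTable:
    """Cross-tabulate the four-way classification by epoch (4 x 2).

    Unevaluable records are excluded.  Raises if either epoch has no
    evaluable record.
    """
    counts = {cat: [0, 0] for cat in CATEGORY_ORDER}
    col = {Epoch.PRE: 0, Epoch.POST: 1}
    for r in results:
        if r.classification is Classification.UNEVALUABLE:
            continue
        counts[r.classification][col[r.record.epoch]] += 1
    totals = [sum(counts[c][j] for c in CATEGORY_ORDER) for j in (0, 1)]
    if any(t == 0 for t in totals):
        raise ValueError(
            f"each epoch needs at least one evaluable record, got pre={totals[0]} "
            f"post={totals[1]}"
        )
    return ContingencyTable(
        row_labels=tuple(c.value for c in CATEGORY_ORDER),
        counts=tuple(tuple(counts[c]) for c in CATEGORY_ORDER),
    )


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Uncorrected Pearson chi-square test of epoch independence.

    Expected counts from row/column marginals; no Yates continuity
    correction.  Degenerate tables (a zero row or column sum) are rejected.
    """
    obs = table.as_array()
    if obs.sum() == 0 or (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: zero total, row sum or column sum")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def _binary_collapse(table: ContingencyTable, row: int) -> ContingencyTable:
    """Collapse an r x 2 table to 'row vs rest' (2 x 2)."""
    arr = table.as_array().astype(int)
    rest = arr.sum(axis=0) - arr[row]
    return ContingencyTable(
        row_labels=(table.row_labels[row], "other"),
        counts=((int(arr[row, 0]), int(arr[row, 1])), (int(rest[0]), int(rest[1]))),
    )


@dataclass(frozen=True)
class EpochComparison:
    """Per-category 2x2 tests, the overall 4x2 test, and demographic tests."""

    classification_table: ContingencyTable
    overall: ChiSquareResult | None
    per_category: dict[str, ChiSquareResult]
    demographics: dict[str, tuple[ContingencyTable, ChiSquareResult]]
    n_unevaluable: int

    def to_dict(self) -> dict:
        def _fmt(r: ChiSquareResult) -> dict:
            return {
                "statistic": round(r.statistic, 4),
                "df": r.df,
                "p_value": round(r.p_value, 3),
            }

        out = {
            "classification_counts": {
                lab: list(row)
                for lab, row in zip(
                    self.classification_table.row_labels,
                    self.classification_table.counts,
                )
            },
            "overall": None if self.overall is None else _fmt(self.overall),
            "per_category": {k: _fmt(v) for k, v in self.per_category.items()},
            "n_unevaluable": self.n_unevaluable,
        }
        out["demographics"] = {
            k: {"counts": [list(r) for r in t.counts], **_fmt(res)}
            for k, (t, res) in self.demographics.items()
        }
        return out


def _demographic_tables(results: list[AuditResult]) -> dict[str, ContingencyTable]:
    """GA split, BW bands and risk categories by epoch, from the records."""
    col = {Epoch.PRE: 0, Epoch.POST: 1}
    ga = [[0, 0], [0, 0]]
    bw_labels = ("<1000", "1000-1499", "1500-2499", ">=2500")
    bw = [[0, 0] for _ in bw_labels]
    risk_labels = (
        "abo_rh_incompatibility",
        "haemolysis",
        "other_illness",
        "none_declared",
        "unknown",
    )
    risk = [[0, 0] for _ in risk_labels]
    from .decision_engine import RiskFactor

    risk_priority = (
        RiskFactor.ABO_RH_INCOMPATIBILITY,
        RiskFactor.HAEMOLYSIS,
        RiskFactor.OTHER_ILLNESS,
        RiskFactor.NONE_DECLARED,
        RiskFactor.UNKNOWN,
    )
    for r in results:
        j = col[r.record.epoch]
        p = r.record.patient
        ga[0 if p.ga_weeks < TERM_GA_CUTOFF_WEEKS else 1][j] += 1
        if p.bw_g < 1000:
            bw[0][j] += 1
        elif p.bw_g < 1500:
            bw[1][j] += 1
        elif p.bw_g < 2500:
            bw[2][j] += 1
        else:
            bw[3][j] += 1
        for k, rf in enumerate(risk_priority):
            if rf in p.risk_factors:
                risk[k][j] += 1
                break
    out = {}
    out["ga"] = ContingencyTable(("<35", ">=35"), tuple(tuple(r) for r in ga))
    out["bw"] = ContingencyTable(bw_labels, tuple(tuple(r) for r in bw))
    out["risk"] = ContingencyTable(risk_labels, tuple(tuple(r) for r in risk))
    return out


def compare_epochs(
    results: list[AuditResult],
    demographic_tables: dict[str, ContingencyTable] | None = None,
) -> EpochComparison:
    """Full pre/post report: overall 4x2 test, per-category 2x2 tests, and
    demographic r x 2 tests (gestational-age split, birth-weight bands,
    risk-factor categories).

    ``demographic_tables`` overrides the tables derived from the records —
    used when only aggregate counts are available.  Rows with zero totals
    (a category absent in both epochs) are dropped before testing.
    """
    table = summarize_epochs(results)
    # categories absent in both epochs are degenerate rows; they are dropped
    # from the tests (but kept in the reported table)
    nonzero = [i for i, row in enumerate(table.counts) if sum(row) > 0]
    if len(nonzero) >= 2:
        overall_table = ContingencyTable(
            tuple(table.row_labels[i] for i in nonzero),
            tuple(table.counts[i] for i in nonzero),
        )
        overall = pearson_chi_square(overall_table)
        per_category = {
            table.row_labels[i]: pearson_chi_square(_binary_collapse(table, i))
            for i in nonzero
        }
    else:
        # every evaluable record fell in one category: no variation to test
        overall = None
        per_category = {}
    demo_in = (
        demographic_tables
        if demographic_tables is not None
        else _demographic_tables(results)
    )
    demographics = {}
    for key, t in demo_in.items():
        arr = t.as_array()
        keep = arr.sum(axis=1) > 0
        if not keep.all():
            t = ContingencyTable(
                tuple(l for l, k in zip(t.row_labels, keep) if k),
                tuple(tuple(int(c) for c in row) for row, k in zip(t.counts, keep) if k),
            )
        demographics[key] = (t, pearson_chi_square(t))
    n_unevaluable = sum(
        1 for r in results if r.classification is Classification.UNEVALUABLE
    )
    return EpochComparison(
        classification_table=table,
        overall=overall,
        per_category=per_category,
        demographics=demographics,
        n_unevaluable=n_unevaluable,
    )
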