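"""Seven-point Likert questionnaire summaries (technology-acceptance style).

Items are grouped into four sections — perceived usefulness, perceived ease
of use, subjective norm, and intention to use — each answered on a 1
(strongly disagree) .. 7 (strongly agree) scale.  Summaries report per-level
counts/percentages and an "agreement rate": the share of respondents at the
agree levels (default {6, 7}).  Percentages are rounded half-up to integers
for display, matching how such tables are conventionally printed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

__all__ = [
    "Section",
    "LikertItem",
    "LikertTable",
    "agreement_rate",
    "item_distribution",
    "section_summary",
    "read_counts_csv",
    "round_half_up",
]

N_LEVELS = 7


class Section(str, enum.Enum):
    USEFULNESS = "usefulness"
    EASE_OF_USE = "ease_of_use"
    SUBJECTIVE_NORM = "subjective_norm"
    INTENTION = "intention"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the last kept digit (display rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LikertItem:
    section: Section
    text: str
    counts: tuple[int, ...]  # levels 1..7

    def __post_init__(self) -> None:
        if len(self.counts) != N_LEVELS:
            raise ValueError(f"need {N_LEVELS} level counts, got {len(self.counts)}")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError("counts must be non-negative integers")

    @property
    def n(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class LikertTable:
    items: tuple[LikertItem, ...]
    n_respondents: int

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        for item in self.items:
            if item.n != self.n_respondents:
                raise ValueError(
                    f"item '{item.text[:40]}...': counts sum to {item.n}, "
                    f"expected {self.n_respondents}"
                )


def agreement_rate(
    item: LikertItem, agree_levels: frozenset[int] | set[int] = frozenset({6, 7})
) -> tuple[int, float]:
    """Percentage of respondents at the agree levels.

    Returns ``(display_percent, exact_percent)`` where the display value is
    rounded half-up to an integer.
    """
    if not agree_levels or not set(agree_levels) <= set(range(1, N_LEVELS + 1)):
        raise ValueError(f"agree_levels must be a non-empty subset of 1..{N_LEVELS}")
    agree = sum(item.counts[lv - 1] for lv in agree_levels)
    exact = 100.0 * agree / item.n
    return int(round_half_up(exact)), exact


def item_distribution(item: LikertItem) -> pd.DataFrame:
    """Per-level counts and percentages for one item."""
    exact = [100.0 * c / item.n for c in item.counts]
    return pd.DataFrame(
        {
            "level": range(1, N_LEVELS + 1),
            "count": item.counts,
            "percent": [int(round_half_up(p)) for p in exact],
            "percent_exact": exact,
        }
    )


def section_summary(
    table: LikertTable, agree_levels: frozenset[int] | set[int] = frozenset({6, 7})
) -> pd.DataFrame:
    """Per-section aggregates: items, mean agreement, pooled agreement."""
    rows = []
    for section in Section:
        items = [it for it in table.items if it.section is section]
        if not items:
            continue
        rates = [agreement_rate(it, agree_levels)[1] for it in items]
        pooled_agree = sum(
            sum(it.counts[lv - 1] for lv in agree_levels) for it in items
        )
        pooled_n = sum(it.n for it in items)
        rows.append(
            {
                "section": section.value,
                "n_items": len(items),
                "mean_agreement_pct": sum(rates) / len(rates),
                "pooled_agreement_pct": 100.0 * pooled_agree / pooled_n,
            }
        )
    return pd.DataFrame(rows)


def read_counts_csv(path: str | Path) -> LikertTable:
    """Read a count-level questionnaire CSV.

    Expected columns: ``section``, ``text``, ``n1`` .. ``n7`` (counts per
    response level).  Every item must sum to the same respondent total.
    """
    df = pd.read_csv(path)
    needed = {"section", "text", *{f"n{i}" for i in range(1, N_LEVELS + 1)}}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    items = tuple(
        LikertItem(
            section=Section(row["section"]),
            text=str(row["text"]),
            counts=tuple(int(row[f"n{i}"]) for i in range(1, N_LEVELS + 1)),
        )
        for _, row in df.iterrows()
    )
    return LikertTable(items=items, n_respondents=items[0].n if items else 0)
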