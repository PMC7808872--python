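"""Composite Scale of Morningness (CS) scoring and chronotype classification.

The CS is a 13-item self-report questionnaire of diurnal preference.  Three
items are answered on a five-point scale (1-5) and the remaining ten on a
four-point scale (1-4), so the total ranges from 13 to 55 with higher totals
indicating morning preference.  Individuals are conventionally classed as
evening (total <= 26), intermediate (27-40) or morning (>= 41) types.

Which three items carry the five-point scale varies between translations of
the instrument; classification depends only on the total, so the module
accepts any per-item scale declaration and defaults to items 1-3 being
five-point.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_ITEMS = 13
DEFAULT_FIVE_POINT_ITEMS = (0, 1, 2)  # 0-based positions of the 1-5 items

SCORE_MIN = 13
SCORE_MAX = 55
EVENING_MAX = 26
MORNING_MIN = 41

CHRONOTYPE_LABELS = ("evening", "intermediate", "morning")


def item_maxima(five_point_items: Sequence[int] = DEFAULT_FIVE_POINT_ITEMS) -> tuple[int, ...]:
    """Per-item maximum score given which items are five-point."""
    five = set(five_point_items)
    if len(five) != 3 or not five <= set(range(N_ITEMS)):
        raise ValueError("exactly three item positions in 0..12 must be five-point")
    return tuple(5 if i in five else 4 for i in range(N_ITEMS))


def score_cs(
    item_scores: Sequence[int],
    five_point_items: Sequence[int] = DEFAULT_FIVE_POINT_ITEMS,
) -> int:
    """Total CS score for one respondent.

    Raises ``ValueError`` naming the offending item if any response is
    missing or outside its declared scale.  Missing responses are rejected
    rather than imputed.
    """
    items = list(item_scores)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item scores, got {len(items)}")
    maxima = item_maxima(five_point_items)
    for i, (v, m) in enumerate(zip(items, maxima)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"item {i + 1}: missing response")
        if int(v) != v or not (1 <= int(v) <= m):
            raise ValueError(f"item {i + 1}: score {v!r} outside 1..{m}")
    return int(sum(int(v) for v in items))


def classify_chronotype(total_score: int) -> str:
    """Map a total CS score to evening / intermediate / morning."""
    if not (SCORE_MIN <= total_score <= SCORE_MAX):
        raise ValueError(f"total score {total_score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    if total_score <= EVENING_MAX:
        return "evening"
    if total_score >= MORNING_MIN:
        return "morning"
    return "intermediate"


def percentage(count: int, total: int) -> float:
    """100 * count / total rounded half-up to one decimal (table convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


AGE_DECADES = ((0, 9), (10, 19), (20, 29), (30, 39), (40, 49), (50, 59), (60, 200))


def summarize_cohort(
    cs_total: Iterable[int],
    sex: Iterable[str],
    age: Iterable[float],
) -> pd.DataFrame:
    """Cohort summary: counts/percentages by sex for age decade and
    chronotype, plus mean +/- SD of the CS total per sex.

    ``sex`` entries must be 'M' or 'F'.  Percentages are column-wise
    (within sex, and within the whole cohort for the total column) and
    rounded half-up to one decimal.
    """
    scores = np.asarray(list(cs_total), dtype=float)
    sexes = np.asarray(list(sex), dtype=object)
    ages = np.asarray(list(age), dtype=float)
    if scores.size == 0:
        raise ValueError("empty cohort")
    if not (scores.size == sexes.size == ages.size):
        raise ValueError("cs_total, sex and age must be aligned")
    unknown = set(sexes) - {"M", "F"}
    if unknown:
        raise ValueError(f"unrecognised sex codes: {sorted(unknown)}")

    labels = np.array([classify_chronotype(int(s)) for s in scores], dtype=object)
    masks = {"male": sexes == "M", "female": sexes == "F", "total": np.ones_like(ages, bool)}
    totals = {col: int(m.sum()) for col, m in masks.items()}

    rows: list[dict[str, object]] = []

    def _count_row(variable: str, member: np.ndarray) -> dict[str, object]:
        row: dict[str, object] = {"variable": variable}
        for col, m in masks.items():
            c = int((member & m).sum())
            row[f"{col}_n"] = c
            row[f"{col}_pct"] = percentage(c, totals[col]) if totals[col] else float("nan")
        return row

    rows.append(
        {
            "variable": "n",
            **{f"{col}_n": totals[col] for col in masks},
            **{f"{col}_pct": 100.0 for col in masks},
        }
    )
    for lo, hi in AGE_DECADES:
        member = (ages >= lo) & (ages <= hi)
        if member.any() or hi <= 59:
            rows.append(_count_row(f"age {lo}-{hi if hi <= 59 else '+'}", member))
    cs_row: dict[str, object] = {"variable": "cs_score_mean_sd"}
    for col, m in masks.items():
        vals = scores[m]
        cs_row[f"{col}_n"] = round(float(vals.mean()), 1) if vals.size else float("nan")
        cs_row[f"{col}_pct"] = round(float(vals.std(ddof=1)), 1) if vals.size > 1 else float("nan")
    rows.append(cs_row)
    for label in CHRONOTYPE_LABELS:
        rows.append(_count_row(f"chronotype {label}", labels == label))

    return pd.DataFrame(rows)
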