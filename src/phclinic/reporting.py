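"""Cohort-level summaries of stratification results.

Per-item and overall grade distributions (counts and half-up-rounded
percentages), optional stratification by sex / area / age band, direct
age-sex standardization of prevalences against an external reference
population, and paired visit-to-visit change statistics for a
measurement (plain paired t test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, localcontext
from typing import Dict, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .cohort_io import CohortTable
from .stratification import GRADE_NAMES, RuleTable, grade_cohort_frame

__all__ = [
    "CohortSummary",
    "summarize_grades",
    "round_percentage",
    "direct_standardize",
    "PairedChange",
    "paired_change",
    "DEFAULT_AGE_BANDS",
]

#: default 10-year age bands, 15–24 … 75+
DEFAULT_AGE_BANDS: Tuple[int, ...] = (15, 25, 35, 45, 55, 65, 75)

GRADE_LEVELS = GRADE_NAMES + ["missing"]


def round_percentage(count: int, total: int, decimals: int = 2) -> float:
    """``100·count/total`` rounded half-up to ``decimals`` places.

    Exact decimal arithmetic, so printed percentages always recompute
    from their own counts (e.g. 5419 of 16,741 → 32.37).
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    with localcontext() as ctx:
        ctx.prec = 50
        pct = (Decimal(count) * 100) / Decimal(total)
        q = Decimal(1).scaleb(-decimals)
        return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def age_band_label(age: float, edges: Sequence[int] = DEFAULT_AGE_BANDS) -> str:
    """Label of the age band containing ``age`` (bands are [lo, hi))."""
    if age < edges[0]:
        return f"<{edges[0]}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= age < hi:
            return f"{lo}-{hi - 1}"
    return f"{edges[-1]}+"


@dataclass
class CohortSummary:
    """Grade distribution of one cohort (or one stratum of it).

    ``table`` is indexed by (item, grade) with ``count`` and ``pct``
    columns; grade levels are green/yellow/orange/red/missing and the
    item set is the rule table's items plus ``overall``. Counts per item
    sum to the cohort size and percentages to 100 (±0.01 from rounding).
    """

    n: int
    table: pd.DataFrame
    by_stratum: Dict[tuple, "CohortSummary"] = field(default_factory=dict)
    strata_columns: Tuple[str, ...] = ()

    def count(self, item: str, grade: str) -> int:
        return int(self.table.loc[(item, grade), "count"])

    def pct(self, item: str, grade: str) -> float:
        return float(self.table.loc[(item, grade), "pct"])

    def pct_at_least(self, item: str, grade: str) -> float:
        """Percentage graded at or worse than ``grade`` on ``item``."""
        start = GRADE_NAMES.index(grade)
        total = sum(self.count(item, g) for g in GRADE_NAMES[start:])
        return round_percentage(total, self.n)

    def prevalence(self, item: str, grade: str) -> float:
        """Crude fraction (not rounded) at or worse than ``grade``."""
        start = GRADE_NAMES.index(grade)
        total = sum(self.count(item, g) for g in GRADE_NAMES[start:])
        return total / self.n

    def to_dict(self) -> dict:
        items: Dict[str, dict] = {}
        for item in self.table.index.get_level_values(0).unique():
            items[item] = {
                g: {"count": self.count(item, g), "pct": self.pct(item, g)}
                for g in GRADE_LEVELS
            }
        return {"n": self.n, "items": items}


def _summary_from_grades(grades: pd.DataFrame, n: int) -> pd.DataFrame:
    rows = []
    for col in grades.columns:
        item = col[len("grade_"):] if col.startswith("grade_") else "overall"
        counts = grades[col].value_counts(dropna=True)
        for g in GRADE_NAMES:
            c = int(counts.get(g, 0))
            rows.append((item, g, c, round_percentage(c, n)))
        miss = int(grades[col].isna().sum())
        rows.append((item, "missing", miss, round_percentage(miss, n)))
    out = pd.DataFrame(rows, columns=["item", "grade", "count", "pct"])
    return out.set_index(["item", "grade"])


def summarize_grades(
    cohort: CohortTable | pd.DataFrame,
    rules: RuleTable,
    strata: Optional[Sequence[str]] = None,
    age_bands: Sequence[int] = DEFAULT_AGE_BANDS,
) -> CohortSummary:
    """Counts and percentages per grade, per item and overall.

    ``strata`` may list any of ``sex``, ``area``, ``age_band``; the
    returned summary then also carries one sub-summary per observed
    stratum combination in ``by_stratum``.
    """
    frame = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort.copy()
    if len(frame) == 0:
        raise ValueError("cannot summarize an empty cohort")
    grades = grade_cohort_frame(frame, rules)
    summary = CohortSummary(n=len(frame), table=_summary_from_grades(grades, len(frame)))

    if strata:
        for col in strata:
            if col == "age_band":
                frame["age_band"] = frame["age"].map(
                    lambda a: age_band_label(a, age_bands)
                )
            elif col not in frame.columns:
                raise ValueError(f"unknown stratification column {col!r}")
        summary.strata_columns = tuple(strata)
        grouped = frame.groupby(list(strata), observed=True, sort=True)
        for key, idx in grouped.groups.items():
            key_t = key if isinstance(key, tuple) else (key,)
            sub_grades = grades.loc[idx]
            summary.by_stratum[key_t] = CohortSummary(
                n=len(idx), table=_summary_from_grades(sub_grades, len(idx))
            )
    return summary


def direct_standardize(
    stratified: CohortSummary,
    reference: Mapping[tuple, float],
    item: str,
    at_least: str = "yellow",
) -> float:
    """Directly standardized prevalence of ``item`` ≥ ``at_least``.

    ``reference`` maps stratum keys — tuples matching the summary's
    ``strata_columns`` (typically ``(sex, age_band)``) — to non-negative
    weights summing to 1. The adjusted prevalence is
    ``Σ_cells weight(cell) · prevalence_in_cell``; every reference cell
    with positive weight must contain at least one cohort subject.
    """
    weights = {k if isinstance(k, tuple) else (k,): w for k, w in reference.items()}
    total = sum(weights.values())
    if any(w < 0 for w in weights.values()):
        raise ValueError("reference weights must be >= 0")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"reference weights sum to {total}, expected 1")
    empty = [k for k, w in weights.items() if w > 0 and k not in stratified.by_stratum]
    if empty:
        raise ValueError(
            f"reference cells with no cohort subjects: {sorted(empty)}"
        )
    return float(
        sum(
            w * stratified.by_stratum[k].prevalence(item, at_least)
            for k, w in weights.items()
            if w > 0
        )
    )


@dataclass
class PairedChange:
    """Paired visit-to-visit change of one measurement."""

    measurement: str
    n: int
    mean_visit1: float
    sd_visit1: float
    mean_visit2: float
    sd_visit2: float
    mean_diff: float
    sd_diff: float
    t_statistic: Optional[float]
    p_value: Optional[float]
    degenerate: bool = False  # zero-variance differences: t undefined

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def paired_change(
    visit1: CohortTable | pd.DataFrame,
    visit2: CohortTable | pd.DataFrame,
    measurement: str,
    stratify_by_grade: Optional[str] = None,
    rules: Optional[RuleTable] = None,
) -> PairedChange | Dict[str, PairedChange]:
    """Paired t test of a measurement between two visits.

    Subjects are matched on ``subject_id``; pairs with the measurement
    missing at either visit are dropped and at least two complete pairs
    are required. The statistic is ``t = mean(d) / (SD(d)/√n)`` with
    ``d = visit2 − visit1`` and a two-sided p from the t distribution on
    n−1 degrees of freedom; when ``SD(d) = 0`` the result is flagged
    degenerate and t/p are ``None``.

    With ``stratify_by_grade`` (an item name; needs ``rules``), returns
    one :class:`PairedChange` per visit-1 grade of that item.
    """
    f1 = visit1.to_frame() if isinstance(visit1, CohortTable) else visit1
    f2 = visit2.to_frame() if isinstance(visit2, CohortTable) else visit2
    merged = f1[["subject_id", measurement]].merge(
        f2[["subject_id", measurement]], on="subject_id", suffixes=("_1", "_2")
    )
    merged = merged.dropna()

    if stratify_by_grade is not None:
        if rules is None:
            raise ValueError("rules are required to stratify by a visit-1 grade")
        grades = grade_cohort_frame(f1, rules)[f"grade_{stratify_by_grade}"]
        lookup = dict(zip(f1["subject_id"], grades))
        out: Dict[str, PairedChange] = {}
        for grade_name in GRADE_NAMES:
            ids = merged["subject_id"].map(lambda s: lookup.get(s) == grade_name)
            sub = merged[ids]
            if len(sub) >= 2:
                out[grade_name] = _paired_stats(sub, measurement)
        return out

    return _paired_stats(merged, measurement)


def _paired_stats(merged: pd.DataFrame, measurement: str) -> PairedChange:
    if len(merged) < 2:
        raise ValueError(
            f"need >= 2 complete pairs for {measurement!r}, got {len(merged)}"
        )
    v1 = merged[f"{measurement}_1"].to_numpy(dtype=float)
    v2 = merged[f"{measurement}_2"].to_numpy(dtype=float)
    d = v2 - v1
    n = len(d)
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        t_stat: Optional[float] = None
        p: Optional[float] = None
        degenerate = True
    else:
        t_stat = float(d.mean() / (sd_d / math.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
        degenerate = False
    return PairedChange(
        measurement=measurement,
        n=n,
        mean_visit1=float(v1.mean()),
        sd_visit1=float(v1.std(ddof=1)),
        mean_visit2=float(v2.mean()),
        sd_visit2=float(v2.std(ddof=1)),
        mean_diff=float(d.mean()),
        sd_diff=sd_d,
        t_statistic=t_stat,
        p_value=p,
        degenerate=degenerate,
    )
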