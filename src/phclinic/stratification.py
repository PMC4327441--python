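"""Four-grade rule-based risk stratification ("Bangladesh-logic").

Each checkup item is graded GREEN < YELLOW < ORANGE < RED against a
threshold table; the overall condition of a subject is the worst colour
over all graded items. Numeric thresholds are half-open ``[lo, hi)``
intervals whose lower edge belongs to the higher-risk bin. Blood-sugar
thresholds depend on fasting status (self-reported hours since the last
meal); waist and waist/hip thresholds depend on sex; the blood-pressure
grade is the worse of the systolic and diastolic component grades.

Items without a measurement, or absent from the rule table, are graded
*missing* — never silently GREEN.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Grade",
    "GradeBin",
    "BinSet",
    "ItemRule",
    "RuleTable",
    "RuleTableError",
    "ItemGrades",
    "compute_bmi",
    "is_fasting",
    "grade_item",
    "grade_subject",
    "aggregate_overall",
    "grade_cohort_frame",
]

#: record fields that feed each bin-set variant selector
SEXES = ("male", "female")
FASTING_STATES = ("fasting", "postprandial")

DEFAULT_FASTING_CUTOFF_H = 8.0


class Grade(enum.IntEnum):
    """Ordered risk grade; ``max()`` gives the worst colour."""

    GREEN = 0
    YELLOW = 1
    ORANGE = 2
    RED = 3

    def __str__(self) -> str:  # serialized form used in CSV/JSON
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "Grade":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown grade {name!r}") from None


GRADE_NAMES = [str(g) for g in Grade]


class RuleTableError(ValueError):
    """Raised for structurally invalid rule tables (gaps, overlaps, ...)."""


def compute_bmi(height_cm: float, weight_kg: float) -> float:
    """Body-mass index, kg/m², from height in cm and weight in kg."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def is_fasting(
    hours_since_meal: float | None, cutoff_h: float = DEFAULT_FASTING_CUTOFF_H
) -> bool | None:
    """Whether a subject counts as fasting for blood-sugar grading.

    Returns ``None`` (unknown) when the meal time was not reported; the
    grading then falls back to the postprandial thresholds, the standard
    practice when fasting cannot be verified.
    """
    if hours_since_meal is None or (
        isinstance(hours_since_meal, float) and math.isnan(hours_since_meal)
    ):
        return None
    if hours_since_meal < 0:
        raise ValueError("hours_since_meal must be >= 0")
    return hours_since_meal >= cutoff_h


# ---------------------------------------------------------------------------
# rule-table data model


@dataclass(frozen=True)
class GradeBin:
    """One grade with its (possibly disjoint) half-open intervals."""

    grade: Grade
    intervals: tuple[tuple[float, float], ...]  # (lo, hi); ±inf for unbounded

    def contains(self, value: float) -> bool:
        return any(lo <= value < hi for lo, hi in self.intervals)


@dataclass(frozen=True)
class BinSet:
    """An ordered set of bins partitioning the measurement axis."""

    bins: tuple[GradeBin, ...]

    def grade_of(self, value: float) -> Grade:
        for b in self.bins:
            if b.contains(value):
                return b.grade
        raise RuleTableError(f"no bin contains value {value!r}")

    def validate(self, item: str) -> None:
        pieces = sorted(
            (lo, hi, b.grade) for b in self.bins for lo, hi in b.intervals
        )
        if not pieces:
            raise RuleTableError(f"item {item!r}: empty bin set")
        if not any(b.grade is Grade.GREEN for b in self.bins):
            raise RuleTableError(f"item {item!r}: no GREEN bin")
        if pieces[0][0] != -math.inf or pieces[-1][1] != math.inf:
            raise RuleTableError(f"item {item!r}: bins do not cover the axis")
        for (lo, hi, _), (lo2, _, _) in zip(pieces, pieces[1:]):
            if lo >= hi:
                raise RuleTableError(f"item {item!r}: empty interval [{lo}, {hi})")
            if hi < lo2:
                raise RuleTableError(
                    f"item {item!r}: gap between {hi} and {lo2}"
                )
            if hi > lo2:
                raise RuleTableError(
                    f"item {item!r}: overlapping bins at {lo2}"
                )
        lo, hi, _ = pieces[-1]
        if lo >= hi:
            raise RuleTableError(f"item {item!r}: empty interval [{lo}, {hi})")

    def edges(self) -> list[float]:
        """Finite interval edges, ascending (useful for feature binning)."""
        es = sorted(
            {e for b in self.bins for iv in b.intervals for e in iv if math.isfinite(e)}
        )
        return es


@dataclass
class ItemRule:
    """Grading rule for one checkup item.

    Exactly one of ``bins``, ``by_sex``, ``by_fasting``, ``components``,
    ``categories`` is set. ``measurement`` names the record field the rule
    reads (``bmi`` and ``waist_hip_ratio`` are derived quantities).
    """

    name: str
    measurement: str | None = None
    bins: BinSet | None = None
    by_sex: dict[str, BinSet] | None = None
    by_fasting: dict[str, BinSet] | None = None
    components: dict[str, "ItemRule"] | None = None
    categories: dict[str, Grade] | None = None

    def validate(self) -> None:
        variants = [
            v is not None
            for v in (self.bins, self.by_sex, self.by_fasting, self.components, self.categories)
        ]
        if sum(variants) != 1:
            raise RuleTableError(
                f"item {self.name!r}: exactly one rule variant must be given"
            )
        if self.bins is not None:
            self.bins.validate(self.name)
        if self.by_sex is not None:
            if set(self.by_sex) != set(SEXES):
                raise RuleTableError(f"item {self.name!r}: by_sex needs male and female")
            for bs in self.by_sex.values():
                bs.validate(self.name)
        if self.by_fasting is not None:
            if set(self.by_fasting) != set(FASTING_STATES):
                raise RuleTableError(
                    f"item {self.name!r}: by_fasting needs fasting and postprandial"
                )
            for bs in self.by_fasting.values():
                bs.validate(self.name)
        if self.components is not None:
            for comp in self.components.values():
                comp.validate()
        if self.categories is not None:
            if not self.categories:
                raise RuleTableError(f"item {self.name!r}: empty category map")
            if Grade.GREEN not in self.categories.values():
                raise RuleTableError(f"item {self.name!r}: no GREEN category")

    def all_edges(self) -> list[float]:
        """Union of finite bin edges over every variant of the item."""
        sets: list[BinSet] = []
        if self.bins is not None:
            sets.append(self.bins)
        if self.by_sex is not None:
            sets.extend(self.by_sex.values())
        if self.by_fasting is not None:
            sets.extend(self.by_fasting.values())
        if self.components is not None:
            return sorted({e for c in self.components.values() for e in c.all_edges()})
        return sorted({e for s in sets for e in s.edges()})


#: measurements stored as booleans, mapped onto rule-table categories
_BOOL_CATEGORIES = {"arrhythmia": ("no", "yes"), "smoker": ("none", "smoker")}


@dataclass
class RuleTable:
    """The machine-readable stratification table."""

    items: dict[str, ItemRule]
    fasting_cutoff_hours: float = DEFAULT_FASTING_CUTOFF_H

    def validate(self) -> "RuleTable":
        for rule in self.items.values():
            rule.validate()
        return self

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "RuleTable":
        items = {
            name: _item_rule_from_dict(name, spec)
            for name, spec in cfg.get("items", {}).items()
        }
        table = cls(
            items=items,
            fasting_cutoff_hours=float(
                cfg.get("fasting_cutoff_hours", DEFAULT_FASTING_CUTOFF_H)
            ),
        )
        return table.validate()

    def to_dict(self) -> dict[str, Any]:
        return {
            "fasting_cutoff_hours": self.fasting_cutoff_hours,
            "items": {name: _item_rule_to_dict(rule) for name, rule in self.items.items()},
        }


def _interval_from_pair(pair: Iterable[Any]) -> tuple[float, float]:
    lo, hi = pair
    return (
        -math.inf if lo is None else float(lo),
        math.inf if hi is None else float(hi),
    )


def _interval_to_pair(iv: tuple[float, float]) -> list[float | None]:
    lo, hi = iv
    return [None if lo == -math.inf else lo, None if hi == math.inf else hi]


def _binset_from_list(bins: Iterable[Mapping[str, Any]]) -> BinSet:
    return BinSet(
        tuple(
            GradeBin(
                Grade.from_name(str(b["grade"])),
                tuple(_interval_from_pair(iv) for iv in b["intervals"]),
            )
            for b in bins
        )
    )


def _binset_to_list(bs: BinSet) -> list[dict[str, Any]]:
    return [
        {"grade": str(b.grade), "intervals": [_interval_to_pair(iv) for iv in b.intervals]}
        for b in bs.bins
    ]


def _item_rule_from_dict(name: str, spec: Mapping[str, Any]) -> ItemRule:
    rule = ItemRule(name=name, measurement=spec.get("measurement"))
    if "bins" in spec:
        rule.bins = _binset_from_list(spec["bins"])
    elif "by_sex" in spec:
        rule.by_sex = {
            sex: _binset_from_list(sub["bins"]) for sex, sub in spec["by_sex"].items()
        }
    elif "by_fasting" in spec:
        rule.by_fasting = {
            st: _binset_from_list(sub["bins"]) for st, sub in spec["by_fasting"].items()
        }
    elif "components" in spec:
        rule.components = {
            comp: _item_rule_from_dict(f"{name}.{comp}", sub)
            for comp, sub in spec["components"].items()
        }
    elif "categories" in spec:
        rule.categories = {
            str(k).lower(): Grade.from_name(str(v)) for k, v in spec["categories"].items()
        }
    return rule


def _item_rule_to_dict(rule: ItemRule) -> dict[str, Any]:
    out: dict[str, Any] = {}
    if rule.measurement is not None:
        out["measurement"] = rule.measurement
    if rule.bins is not None:
        out["bins"] = _binset_to_list(rule.bins)
    if rule.by_sex is not None:
        out["by_sex"] = {s: {"bins": _binset_to_list(b)} for s, b in rule.by_sex.items()}
    if rule.by_fasting is not None:
        out["by_fasting"] = {
            s: {"bins": _binset_to_list(b)} for s, b in rule.by_fasting.items()
        }
    if rule.components is not None:
        out["components"] = {
            c: _item_rule_to_dict(sub) for c, sub in rule.components.items()
        }
    if rule.categories is not None:
        out["categories"] = {k: str(v) for k, v in rule.categories.items()}
    return out


# ---------------------------------------------------------------------------
# scalar grading


@dataclass
class ItemGrades:
    """Per-item grades of one subject; ``None`` marks a missing grade."""

    grades: dict[str, Grade | None] = field(default_factory=dict)

    def __getitem__(self, item: str) -> Grade | None:
        return self.grades[item]

    def __iter__(self):
        return iter(self.grades)

    @property
    def overall(self) -> Grade | None:
        return aggregate_overall(self.grades.values())


def aggregate_overall(grades: Iterable[Grade | None]) -> Grade | None:
    """Worst-colour aggregation: the maximum over non-missing item grades.

    Returns ``None`` only when every item grade is missing.
    """
    present = [g for g in grades if g is not None]
    return max(present) if present else None


def _get(record: Any, name: str) -> Any:
    value = getattr(record, name, None)
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def _derived_value(record: Any, measurement: str) -> float | None:
    if measurement == "bmi":
        bmi = _get(record, "bmi_kg_m2")
        if bmi is not None:
            return float(bmi)
        height, weight = _get(record, "height_cm"), _get(record, "weight_kg")
        if height is None or weight is None:
            return None
        return compute_bmi(float(height), float(weight))
    if measurement == "waist_hip_ratio":
        waist, hip = _get(record, "waist_cm"), _get(record, "hip_cm")
        if waist is None or hip is None:
            return None
        return float(waist) / float(hip)
    value = _get(record, measurement)
    return None if value is None else value


def grade_item(item: str, record: Any, rules: RuleTable) -> Grade | None:
    """Grade one item of one subject record; missing inputs give ``None``."""
    rule = rules.items.get(item)
    if rule is None:
        return None
    return _grade_with_rule(rule, record, rules)


def _grade_with_rule(rule: ItemRule, record: Any, rules: RuleTable) -> Grade | None:
    if rule.components is not None:
        return aggregate_overall(
            _grade_with_rule(comp, record, rules) for comp in rule.components.values()
        )

    value = _derived_value(record, rule.measurement or rule.name)
    if value is None:
        return None

    if rule.categories is not None:
        if rule.measurement in _BOOL_CATEGORIES and isinstance(value, (bool, np.bool_)):
            value = _BOOL_CATEGORIES[rule.measurement][int(value)]
        return rule.categories.get(str(value).lower())

    binset = rule.bins
    if rule.by_sex is not None:
        sex = _get(record, "sex")
        if sex not in rule.by_sex:
            return None
        binset = rule.by_sex[sex]
    elif rule.by_fasting is not None:
        fasting = is_fasting(_get(record, "hours_since_meal"), rules.fasting_cutoff_hours)
        binset = rule.by_fasting["fasting" if fasting else "postprandial"]
    assert binset is not None
    return binset.grade_of(float(value))


def grade_subject(record: Any, rules: RuleTable) -> ItemGrades:
    """Grade every item of the rule table for one subject."""
    return ItemGrades(
        {item: _grade_with_rule(rule, record, rules) for item, rule in rules.items.items()}
    )


# ---------------------------------------------------------------------------
# vectorized grading over a cohort frame


def _nanmax_rows(stack: np.ndarray) -> np.ndarray:
    """Column-wise nanmax that leaves all-NaN columns NaN, quietly."""
    all_nan = np.isnan(stack).all(axis=0)
    out = np.full(stack.shape[1], np.nan)
    if (~all_nan).any():
        out[~all_nan] = np.nanmax(stack[:, ~all_nan], axis=0)
    return out


def _numeric_codes(values: np.ndarray, binset: BinSet) -> np.ndarray:
    out = np.full(values.shape, np.nan)
    finite = np.isfinite(values)
    for b in binset.bins:
        for lo, hi in b.intervals:
            mask = finite & (values >= lo) & (values < hi)
            out[mask] = float(b.grade)
    return out


def _frame_values(frame: pd.DataFrame, measurement: str) -> np.ndarray:
    if measurement == "bmi":
        if "bmi_kg_m2" in frame:
            vals = pd.to_numeric(frame["bmi_kg_m2"], errors="coerce").to_numpy(float)
        else:
            vals = np.full(len(frame), np.nan)
        if "height_cm" in frame and "weight_kg" in frame:
            h = pd.to_numeric(frame["height_cm"], errors="coerce").to_numpy(float)
            w = pd.to_numeric(frame["weight_kg"], errors="coerce").to_numpy(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                derived = w / (h / 100.0) ** 2
            vals = np.where(np.isnan(vals), derived, vals)
        return vals
    if measurement == "waist_hip_ratio":
        if "waist_cm" not in frame or "hip_cm" not in frame:
            return np.full(len(frame), np.nan)
        waist = pd.to_numeric(frame["waist_cm"], errors="coerce").to_numpy(float)
        hip = pd.to_numeric(frame["hip_cm"], errors="coerce").to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return waist / hip
    if measurement not in frame:
        return np.full(len(frame), np.nan)
    return pd.to_numeric(frame[measurement], errors="coerce").to_numpy(float)


def _grade_codes_for_rule(rule: ItemRule, frame: pd.DataFrame, rules: RuleTable) -> np.ndarray:
    n = len(frame)
    if rule.components is not None:
        stack = np.vstack(
            [_grade_codes_for_rule(c, frame, rules) for c in rule.components.values()]
        )
        return _nanmax_rows(stack)

    measurement = rule.measurement or rule.name
    if rule.categories is not None:
        if measurement not in frame:
            return np.full(n, np.nan)
        col = frame[measurement]
        if measurement in _BOOL_CATEGORIES:
            names = _BOOL_CATEGORIES[measurement]
            col = col.map(
                lambda v: v
                if isinstance(v, str)
                else (None if pd.isna(v) else names[int(bool(v))])
            )
        mapped = col.map(
            lambda v: float(rule.categories[str(v).lower()])  # type: ignore[index]
            if (not pd.isna(v)) and str(v).lower() in rule.categories  # type: ignore[operator]
            else np.nan
        )
        return mapped.to_numpy(float)

    values = _frame_values(frame, measurement)
    if rule.bins is not None:
        return _numeric_codes(values, rule.bins)
    if rule.by_sex is not None:
        out = np.full(n, np.nan)
        sex = frame["sex"].astype(str).to_numpy()
        for s, binset in rule.by_sex.items():
            mask = sex == s
            out[mask] = _numeric_codes(values[mask], binset)
        return out
    if rule.by_fasting is not None:
        hours = (
            pd.to_numeric(frame["hours_since_meal"], errors="coerce").to_numpy(float)
            if "hours_since_meal" in frame
            else np.full(n, np.nan)
        )
        fasting = hours >= rules.fasting_cutoff_hours  # NaN compares False
        out = _numeric_codes(values, rule.by_fasting["postprandial"])
        out[fasting] = _numeric_codes(values[fasting], rule.by_fasting["fasting"])
        return out
    raise RuleTableError(f"item {rule.name!r}: no grading variant")


def grade_cohort_frame(frame: pd.DataFrame, rules: RuleTable) -> pd.DataFrame:
    """Grade a whole cohort at once.

    Returns a frame indexed like ``frame`` with one ``grade_<item>`` column
    per rule-table item plus ``overall_grade``, holding lowercase grade
    names with ``NaN`` for missing grades.
    """
    codes = {
        item: _grade_codes_for_rule(rule, frame, rules)
        for item, rule in rules.items.items()
    }
    if codes:
        overall = _nanmax_rows(np.vstack(list(codes.values())))
    else:
        overall = np.full(len(frame), np.nan)

    def _names(arr: np.ndarray) -> pd.Series:
        s = pd.Series(arr, index=frame.index)
        return s.map(lambda c: GRADE_NAMES[int(c)] if not math.isnan(c) else np.nan)

    out = {f"grade_{item}": _names(arr) for item, arr in codes.items()}
    out["overall_grade"] = _names(overall)
    return pd.DataFrame(out, index=frame.index)
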