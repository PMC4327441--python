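"""Subject-record data model and cohort / rule-table I/O.

Cohort tables are plain UTF-8 CSV files with a header row; empty cells and
``NA`` mean missing. One row is one subject visit. Sex and area encodings
are normalized case-insensitively on read (``M``/``male`` → ``male``),
because field-collected data is messy. Rows violating record invariants
are rejected and reported with their row number rather than silently
dropped; ``strict=True`` turns any warning or rejection into an error.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Mapping, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .stratification import RuleTable, compute_bmi

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "CohortTable",
    "RejectedRow",
    "CohortReadError",
    "read_cohort",
    "write_graded_cohort",
    "load_rule_table",
    "save_rule_table",
    "default_rule_table",
]

MANDATORY_COLUMNS = ("subject_id", "age", "sex", "area")

NUMERIC_FIELDS = (
    "waist_cm",
    "hip_cm",
    "height_cm",
    "weight_kg",
    "bmi_kg_m2",
    "sbp_mmHg",
    "dbp_mmHg",
    "blood_sugar_mg_dl",
    "hours_since_meal",
    "pulse_bpm",
    "temperature_c",
    "spo2_pct",
)
CATEGORY_FIELDS = ("urine_protein", "urine_sugar", "urine_urobilinogen")
BOOL_FIELDS = ("literate", "arrhythmia", "smoker")

OCCUPATIONS = ("daily_labor", "business", "service", "student", "housewife", "unemployed")

_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}
_AREA_ALIASES = {"r": "rural", "rural": "rural", "u": "urban", "urban": "urban"}
_BOOL_ALIASES = {
    "1": True, "true": True, "yes": True, "y": True,
    "0": False, "false": False, "no": False, "n": False,
}


class CohortReadError(ValueError):
    pass


class SubjectRecord(BaseModel):
    """One subject visit: demographics, questionnaire flags, measurements.

    Any measurement may be missing (``None``). Supplied numeric
    measurements must be finite and strictly positive (hours since the
    last meal may be zero); SpO2 lies in (0, 100]. A supplied BMI must
    agree with height/weight to within 0.5 kg/m².
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    subject_id: str
    age: int
    sex: Literal["male", "female"]
    area: Literal["rural", "urban"]
    occupation: Optional[Literal[OCCUPATIONS]] = None  # type: ignore[valid-type]
    literate: Optional[bool] = None
    waist_cm: Optional[float] = None
    hip_cm: Optional[float] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    bmi_kg_m2: Optional[float] = None
    sbp_mmHg: Optional[float] = None
    dbp_mmHg: Optional[float] = None
    blood_sugar_mg_dl: Optional[float] = None
    hours_since_meal: Optional[float] = None
    urine_protein: Optional[Literal["negative", "trace", "positive"]] = None
    urine_sugar: Optional[Literal["negative", "trace", "positive"]] = None
    urine_urobilinogen: Optional[Literal["negative", "trace", "positive"]] = None
    pulse_bpm: Optional[float] = None
    arrhythmia: Optional[bool] = None
    smoker: Optional[bool] = None
    temperature_c: Optional[float] = None
    spo2_pct: Optional[float] = None

    @field_validator("age")
    @classmethod
    def _age_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("age must be >= 0")
        return v

    @field_validator(*NUMERIC_FIELDS)
    @classmethod
    def _finite_positive(cls, v: Optional[float], info: Any) -> Optional[float]:
        if v is None:
            return v
        if not math.isfinite(v):
            raise ValueError(f"{info.field_name} must be finite")
        if info.field_name == "hours_since_meal":
            if v < 0:
                raise ValueError("hours_since_meal must be >= 0")
        elif v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        if info.field_name == "spo2_pct" and v > 100:
            raise ValueError("spo2_pct must be in (0, 100]")
        return v

    @model_validator(mode="after")
    def _bmi_consistent(self) -> "SubjectRecord":
        if (
            self.bmi_kg_m2 is not None
            and self.height_cm is not None
            and self.weight_kg is not None
        ):
            derived = compute_bmi(self.height_cm, self.weight_kg)
            if abs(derived - self.bmi_kg_m2) > 0.5:
                raise ValueError(
                    f"bmi_kg_m2={self.bmi_kg_m2:.2f} disagrees with "
                    f"height/weight-derived {derived:.2f} by more than 0.5"
                )
        return self


@dataclass
class RejectedRow:
    row_number: int  # 1-based data-row number in the source file
    subject_id: str | None
    reason: str


@dataclass
class CohortTable:
    """An ordered collection of subject records for one visit."""

    records: list[SubjectRecord]
    visit_label: str = ""
    rejections: list[RejectedRow] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortReadError(f"duplicate subject_id values: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame, one column per record field."""
        return pd.DataFrame(
            [r.model_dump() for r in self.records],
            columns=list(SubjectRecord.model_fields),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, visit_label: str = "") -> "CohortTable":
        records = []
        for row in frame.to_dict("records"):
            clean = {
                k: v
                for k, v in row.items()
                if k in SubjectRecord.model_fields
                and not (v is None or (isinstance(v, float) and math.isnan(v)))
            }
            records.append(SubjectRecord(**clean))
        return cls(records=records, visit_label=visit_label)


# ---------------------------------------------------------------------------
# cohort CSV


def _parse_cell(field_name: str, raw: str, row_no: int, strict: bool) -> Any:
    """Parse one optional cell; malformed values degrade to missing."""
    text = raw.strip()
    low = text.lower()
    if field_name in NUMERIC_FIELDS:
        try:
            return float(text)
        except ValueError:
            _warn(f"row {row_no}: malformed numeric {field_name}={text!r}; treated as missing", strict)
            return None
    if field_name in BOOL_FIELDS:
        if low in _BOOL_ALIASES:
            return _BOOL_ALIASES[low]
        _warn(f"row {row_no}: malformed boolean {field_name}={text!r}; treated as missing", strict)
        return None
    if field_name in CATEGORY_FIELDS:
        if low in ("negative", "trace", "positive"):
            return low
        _warn(f"row {row_no}: unknown category {field_name}={text!r}; treated as missing", strict)
        return None
    if field_name == "occupation":
        if low in OCCUPATIONS:
            return low
        _warn(f"row {row_no}: unknown occupation {text!r}; treated as missing", strict)
        return None
    return text


def _warn(msg: str, strict: bool) -> None:
    if strict:
        raise CohortReadError(msg)
    warnings.warn(msg, stacklevel=3)
    logger.warning(msg)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    visit_label: str = "",
    strict: bool = False,
) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    ``schema`` optionally maps source column names onto record field names
    (``{"systolic": "sbp_mmHg"}``). Missing mandatory columns are a hard
    error; malformed optional cells become missing values with a warning;
    rows violating record invariants are rejected and reported (collected
    in ``CohortTable.rejections``, or raised under ``strict``).
    ``path`` may also be an open text buffer.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if schema:
        raw = raw.rename(columns=dict(schema))
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortReadError(f"{path}: missing mandatory columns {missing_cols}")

    known = [c for c in raw.columns if c in SubjectRecord.model_fields]
    records: list[SubjectRecord] = []
    rejected: list[RejectedRow] = []
    for i, row in enumerate(raw[known].itertuples(index=False), start=1):
        data: dict[str, Any] = {}
        sid = None
        try:
            for field_name, raw_value in zip(known, row):
                text = str(raw_value).strip()
                if text == "" or text.upper() == "NA":
                    continue
                if field_name == "subject_id":
                    sid = data["subject_id"] = text
                elif field_name == "age":
                    data["age"] = int(float(text))
                elif field_name == "sex":
                    data["sex"] = _SEX_ALIASES.get(text.lower())
                    if data["sex"] is None:
                        raise ValueError(f"unrecognized sex {text!r}")
                elif field_name == "area":
                    data["area"] = _AREA_ALIASES.get(text.lower())
                    if data["area"] is None:
                        raise ValueError(f"unrecognized area {text!r}")
                else:
                    value = _parse_cell(field_name, text, i, strict)
                    if value is not None:
                        data[field_name] = value
            records.append(SubjectRecord(**data))
        except CohortReadError:
            raise
        except (ValueError, TypeError) as exc:
            reason = " | ".join(
                line.strip() for line in str(exc).splitlines()[:4] if line.strip()
            )
            if strict:
                raise CohortReadError(f"{path} row {i}: {reason}") from exc
            warnings.warn(f"row {i} rejected: {reason}", stacklevel=2)
            logger.warning("row %d rejected: %s", i, reason)
            rejected.append(RejectedRow(i, sid, reason))
    table = CohortTable(records=records, visit_label=visit_label)
    table.rejections = rejected
    return table


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back to CSV (empty cell = missing)."""
    frame = cohort.to_frame()
    frame.to_csv(path, index=False)


def write_graded_cohort(
    cohort: CohortTable,
    grades: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write the cohort plus its grade columns to CSV.

    ``grades`` is the frame produced by
    :func:`~phclinic.stratification.grade_cohort_frame` (one
    ``grade_<item>`` column per item plus ``overall_grade``); it must have
    one row per record. Missing grades serialize as ``NA``.
    """
    if len(grades) != len(cohort):
        raise ValueError(
            f"grade set count {len(grades)} != record count {len(cohort)}"
        )
    frame = cohort.to_frame()
    out = pd.concat([frame, grades.reset_index(drop=True)], axis=1)
    grade_cols = list(grades.columns)
    out[grade_cols] = out[grade_cols].fillna("NA")
    out.to_csv(path, index=False)


def read_graded_cohort(path: str | Path) -> tuple[CohortTable, pd.DataFrame]:
    """Read a graded-cohort CSV back into a table and its grade frame."""
    import io

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    grade_cols = [c for c in raw.columns if c.startswith("grade_") or c == "overall_grade"]
    grades = raw[grade_cols].replace({"NA": None, "": None})
    buf = io.StringIO()
    raw.drop(columns=grade_cols).to_csv(buf, index=False)
    buf.seek(0)
    cohort = read_cohort(buf)
    return cohort, grades


# ---------------------------------------------------------------------------
# rule-table files


def load_rule_table(path: str | Path) -> RuleTable:
    """Load and validate a rule-table YAML/JSON configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: rule-table file must contain a mapping")
    return RuleTable.from_dict(cfg)


def save_rule_table(rules: RuleTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(rules.to_dict(), fh, sort_keys=False)


def default_rule_table() -> RuleTable:
    """The packaged default four-grade stratification table."""
    ref = resources.files("phclinic").joinpath("data/bangladesh_logic.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return RuleTable.from_dict(yaml.safe_load(fh))
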