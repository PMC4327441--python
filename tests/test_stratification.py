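"""Grading rules: thresholds, variants, aggregation, structural invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phclinic.cohort_io import SubjectRecord
from phclinic.stratification import (
    Grade,
    RuleTable,
    RuleTableError,
    aggregate_overall,
    compute_bmi,
    grade_cohort_frame,
    grade_item,
    grade_subject,
    is_fasting,
)

from conftest import make_record_kwargs

G, Y, O, R = Grade.GREEN, Grade.YELLOW, Grade.ORANGE, Grade.RED


def rec(**kw) -> SubjectRecord:
    return SubjectRecord(**make_record_kwargs(**kw))


# ---------------------------------------------------------------------------
# small pure helpers


@pytest.mark.parametrize(
    "height,weight,expected",
    [(170, 72.25, 25.0), (100, 35, 35.0), (160, 64, 25.0)],
)
def test_compute_bmi(height, weight, expected):
    assert compute_bmi(height, weight) == pytest.approx(expected)


def test_compute_bmi_rejects_nonpositive():
    with pytest.raises(ValueError):
        compute_bmi(0, 70)
    with pytest.raises(ValueError):
        compute_bmi(170, -1)


@pytest.mark.parametrize("hours,expected", [(10, True), (8, True), (2, False), (None, None)])
def test_is_fasting(hours, expected):
    assert is_fasting(hours) is expected


def test_unknown_meal_time_uses_postprandial_bins(rules):
    # 126 mg/dl is orange when fasting but green postprandially; unknown
    # meal time must fall back to the postprandial (unverifiable-fast) bins
    r = rec(blood_sugar_mg_dl=126)
    assert grade_item("blood_sugar", r, rules) is G


# ---------------------------------------------------------------------------
# per-item grading against the printed threshold table


@pytest.mark.parametrize(
    "kwargs,item,expected",
    [
        (dict(bmi_kg_m2=27), "bmi", Y),
        (dict(bmi_kg_m2=35), "bmi", R),
        (dict(height_cm=170, weight_kg=72.25), "bmi", Y),  # derived 25.0
        (dict(sbp_mmHg=150, dbp_mmHg=80), "blood_pressure", O),
        (dict(sbp_mmHg=120, dbp_mmHg=92), "blood_pressure", O),
        (dict(blood_sugar_mg_dl=126, hours_since_meal=10), "blood_sugar", O),
        (dict(blood_sugar_mg_dl=126, hours_since_meal=2), "blood_sugar", G),
        (dict(spo2_pct=89), "spo2", R),
        (dict(sex="male", waist_cm=90), "waist", Y),
        (dict(sex="female", waist_cm=79), "waist", G),
        (dict(pulse_bpm=45), "pulse", O),
        (dict(pulse_bpm=110), "pulse", Y),
        (dict(urine_protein="trace"), "urine_protein", Y),
        (dict(urine_urobilinogen="trace"), "urine_urobilinogen", G),
        (dict(urine_urobilinogen="positive"), "urine_urobilinogen", O),
        (dict(arrhythmia=True), "arrhythmia", O),
        (dict(smoker=True), "smoking", Y),
        (dict(smoker=False), "smoking", G),
        (dict(waist_cm=95, hip_cm=100, sex="male"), "waist_hip_ratio", Y),
        (dict(waist_cm=84, hip_cm=100, sex="female"), "waist_hip_ratio", G),
    ],
)
def test_grade_item_examples(rules, kwargs, item, expected):
    assert grade_item(item, rec(**kwargs), rules) is expected


def test_missing_measurement_gives_missing_grade(rules):
    assert grade_item("waist", rec(), rules) is None
    assert grade_item("bmi", rec(), rules) is None
    # blood pressure with only one component still grades on that component
    assert grade_item("blood_pressure", rec(sbp_mmHg=150), rules) is O


def test_item_absent_from_rule_table_is_missing(rules):
    cfg = rules.to_dict()
    del cfg["items"]["smoking"]
    reduced = RuleTable.from_dict(cfg)
    g = grade_subject(rec(smoker=True), reduced)
    assert "smoking" not in g.grades


def test_grade_subject_matches_itemwise_application(rules):
    r = rec(
        sex="female",
        waist_cm=81,
        hip_cm=93,
        height_cm=155,
        weight_kg=70,
        sbp_mmHg=136,
        dbp_mmHg=88,
        blood_sugar_mg_dl=145,
        hours_since_meal=3,
        urine_protein="negative",
        urine_sugar="trace",
        urine_urobilinogen="trace",
        pulse_bpm=58,
        arrhythmia=False,
        smoker=False,
        temperature_c=36.8,
        spo2_pct=97,
    )
    g = grade_subject(r, rules)
    for item in rules.items:
        assert g[item] is grade_item(item, r, rules)
    assert g.overall is aggregate_overall(g.grades.values())


# ---------------------------------------------------------------------------
# worst-colour aggregation


def test_aggregation_worked_examples():
    assert aggregate_overall([G, O, G, Y]) is O
    assert aggregate_overall([G, G, G, G]) is G
    assert aggregate_overall([Y, None, R]) is R
    assert aggregate_overall([None, None]) is None
    assert aggregate_overall([]) is None


@given(
    st.lists(st.sampled_from([None, G, Y, O, R]), min_size=0, max_size=6),
    st.sampled_from([G, Y, O, R]),
)
def test_aggregation_monotone_commutative_idempotent(grades, extra):
    base = aggregate_overall(grades)
    # commutative: order never matters
    assert aggregate_overall(list(reversed(grades))) == base
    # adding an item never lowers the overall grade
    worse = aggregate_overall(grades + [extra])
    assert base is None or worse >= base
    # idempotent: aggregating the aggregate changes nothing
    if base is not None:
        assert aggregate_overall([base, base]) is base


def test_aggregation_equals_bruteforce_max_over_triples():
    levels = [None, G, Y, O, R]
    for a in levels:
        for b in levels:
            for c in levels:
                present = [g for g in (a, b, c) if g is not None]
                expected = max(present) if present else None
                assert aggregate_overall([a, b, c]) == expected


# ---------------------------------------------------------------------------
# boundary and exhaustiveness properties


def _numeric_variants(rules):
    """(item, record-builder, binset) for every numeric bin-set variant."""
    out = []
    for item, rule in rules.items.items():
        if rule.bins is not None:
            meas = rule.measurement
            if meas == "bmi":
                out.append((item, lambda v: rec(bmi_kg_m2=v), rule.bins))
            else:
                out.append((item, lambda v, m=meas: rec(**{m: v}), rule.bins))
        elif rule.by_sex is not None:
            for sex, bs in rule.by_sex.items():
                if item == "waist_hip_ratio":
                    out.append(
                        (item, lambda v, s=sex: rec(sex=s, waist_cm=100 * v, hip_cm=100), bs)
                    )
                else:
                    out.append((item, lambda v, s=sex: rec(sex=s, waist_cm=v), bs))
        elif rule.by_fasting is not None:
            for state, bs in rule.by_fasting.items():
                h = 12 if state == "fasting" else 2
                out.append(
                    (
                        item,
                        lambda v, hh=h: rec(blood_sugar_mg_dl=v, hours_since_meal=hh),
                        bs,
                    )
                )
        elif rule.components is not None:
            for comp_name, comp in rule.components.items():
                meas = comp.measurement
                out.append((item, lambda v, m=meas: rec(**{m: v}), comp.bins))
    return out


def test_every_lower_edge_is_inclusive_in_higher_risk_bin(rules):
    """Sweep below/at/above every finite threshold of every numeric variant."""
    checked = 0
    for item, build, binset in _numeric_variants(rules):
        for edge in binset.edges():
            eps = max(abs(edge), 1.0) * 1e-9
            below = binset.grade_of(edge - eps)
            at = binset.grade_of(edge)
            above = binset.grade_of(edge + eps)
            assert at is not below, (item, edge)
            assert at is above, (item, edge)
            # verify through the full per-record path as well
            assert grade_item(item, build(edge), rules) is not None
            checked += 1
    assert checked >= 20  # the packaged table has many edges


def test_exhaustiveness_grid_sweep(rules):
    """Exactly one bin matches every value across each item's domain."""
    for item, build, binset in _numeric_variants(rules):
        edges = binset.edges()
        lo, hi = min(edges) - 30, max(edges) + 30
        for v in np.linspace(max(lo, 1e-3), hi, 101):
            matches = [b.grade for b in binset.bins if b.contains(v)]
            assert len(matches) == 1, (item, v, matches)
            assert binset.grade_of(v) is matches[0]


@pytest.mark.parametrize(
    "item,field,direction",
    [
        ("bmi", "bmi_kg_m2", +1),
        ("blood_pressure", "sbp_mmHg", +1),
        ("blood_sugar", "blood_sugar_mg_dl", +1),
        ("temperature", "temperature_c", +1),
        ("spo2", "spo2_pct", -1),
    ],
)
def test_risk_direction_monotonicity(rules, item, field, direction):
    lo = {"bmi_kg_m2": 15, "sbp_mmHg": 80, "blood_sugar_mg_dl": 60,
          "temperature_c": 35.0, "spo2_pct": 80}[field]
    hi = {"bmi_kg_m2": 45, "sbp_mmHg": 220, "blood_sugar_mg_dl": 350,
          "temperature_c": 40.0, "spo2_pct": 100}[field]
    values = np.linspace(lo, hi, 80)[:: direction]
    extra = {"hours_since_meal": 12} if item == "blood_sugar" else {}
    grades = [grade_item(item, rec(**{field: v}, **extra), rules) for v in values]
    assert all(a <= b for a, b in zip(grades, grades[1:]))


# ---------------------------------------------------------------------------
# rule-table validation


def test_gap_in_bins_rejected():
    cfg = {
        "items": {
            "systolic_only": {
                "measurement": "sbp_mmHg",
                "bins": [
                    {"grade": "green", "intervals": [[None, 130]]},
                    {"grade": "orange", "intervals": [[135, None]]},
                ],
            }
        }
    }
    with pytest.raises(RuleTableError, match="systolic_only"):
        RuleTable.from_dict(cfg)


def test_overlapping_bins_rejected():
    cfg = {
        "items": {
            "x": {
                "measurement": "sbp_mmHg",
                "bins": [
                    {"grade": "green", "intervals": [[None, 140]]},
                    {"grade": "yellow", "intervals": [[130, None]]},
                ],
            }
        }
    }
    with pytest.raises(RuleTableError, match="overlap"):
        RuleTable.from_dict(cfg)


def test_missing_green_bin_rejected():
    cfg = {
        "items": {
            "x": {
                "measurement": "sbp_mmHg",
                "bins": [{"grade": "yellow", "intervals": [[None, None]]}],
            }
        }
    }
    with pytest.raises(RuleTableError, match="GREEN"):
        RuleTable.from_dict(cfg)


def test_rule_table_serialization_idempotent(rules):
    once = RuleTable.from_dict(rules.to_dict())
    assert once.to_dict() == rules.to_dict()


# ---------------------------------------------------------------------------
# vectorized path agrees with the scalar path


def test_frame_grading_matches_scalar_grading(rules):
    rng = np.random.default_rng(42)
    rows = []
    for i in range(200):
        rows.append(
            dict(
                subject_id=f"S{i}",
                age=int(rng.integers(15, 80)),
                sex=rng.choice(["male", "female"]),
                area=rng.choice(["rural", "urban"]),
                waist_cm=float(rng.uniform(60, 110)) if rng.random() > 0.1 else None,
                hip_cm=float(rng.uniform(70, 120)),
                height_cm=float(rng.uniform(140, 185)),
                weight_kg=float(rng.uniform(35, 95)),
                sbp_mmHg=float(rng.uniform(90, 200)),
                dbp_mmHg=float(rng.uniform(50, 120)) if rng.random() > 0.2 else None,
                blood_sugar_mg_dl=float(rng.uniform(60, 320)),
                hours_since_meal=float(rng.uniform(0, 15)) if rng.random() > 0.3 else None,
                urine_protein=rng.choice(["negative", "trace", "positive"]),
                pulse_bpm=float(rng.uniform(40, 130)),
                arrhythmia=bool(rng.random() < 0.5),
                smoker=bool(rng.random() < 0.5),
                temperature_c=float(rng.uniform(35.5, 38.5)),
                spo2_pct=float(rng.uniform(85, 100)),
            )
        )
    frame = pd.DataFrame(rows)
    graded = grade_cohort_frame(frame, rules)
    for i, row in enumerate(rows):
        clean = {k: v for k, v in row.items() if v is not None}
        g = grade_subject(SubjectRecord(**clean), rules)
        for item in rules.items:
            cell = graded.iloc[i][f"grade_{item}"]
            expected = None if g[item] is None else str(g[item])
            got = None if (isinstance(cell, float) and math.isnan(cell)) else cell
            assert got == expected, (i, item)
        overall = graded.iloc[i]["overall_grade"]
        assert overall == (str(g.overall) if g.overall is not None else overall)
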