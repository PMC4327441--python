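"""Seeded synthetic checkup cohorts with the study population's structure.

The generator emulates the published marginal structure of the screened
Bangladeshi population: the sex-by-area stratum counts, per-area age
distributions (rural mean 43.6 y SD 14.0, urban mean 29.6 y SD 6.9,
truncated to 15–90 y), a systolic blood pressure of 121 mmHg SD 17 that
drops by 5 mmHg at the follow-up visit, and — after calibration — the
published fractions of subjects graded yellow-or-worse per item.

A single standard-normal latent risk factor, with per-measurement loading
coefficients, induces the positive cross-item correlation (high BMI,
waist, blood pressure and blood sugar travel together) that makes the
blood-sugar grade predictable from the other items, as the screening-
economics demonstration requires. Continuous measurements are truncated
normals (out-of-range draws are resampled, not clipped); urinalysis
categories come from a probit link on the latent factor; booleans are
Bernoulli. Follow-up visits reuse each subject's latent factor and add
the configured visit effect plus fresh measurement noise.
"""

from __future__ import annotations

import math
from typing import Dict, Literal, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort_io import CohortTable
from .stratification import Grade, RuleTable, grade_cohort_frame

__all__ = [
    "MeasurementParams",
    "CategoricalParams",
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "generate_frame",
    "calibrate_config",
    "CalibrationError",
]

STRATA = ("rural_male", "rural_female", "urban_male", "urban_female")

#: first-checkup head counts by (area, sex) used for the default weights
STRATUM_COUNTS = {
    "rural_male": 2844,
    "rural_female": 4588,
    "urban_male": 6299,
    "urban_female": 3010,
}
TOTAL_SUBJECTS = 16741

AGE_BOUNDS = (15.0, 90.0)


class MeasurementParams(BaseModel):
    """Distribution of one continuous measurement.

    ``value = mean + age_slope*(age - age_ref) + risk_loading*z + sd*eps``
    with ``z`` the subject's latent risk factor and ``eps`` standard
    normal, resampled until the value falls inside ``[lo, hi]``. ``sd`` is
    the residual scale; the marginal SD is ``sqrt(sd² + risk_loading²)``
    (age spread adds a little more when ``age_slope`` is nonzero).
    ``family="uniform"`` draws Uniform(lo, hi) instead.
    """

    model_config = ConfigDict(extra="forbid")

    mean: float = 0.0
    sd: float = 1.0
    risk_loading: float = 0.0
    age_slope: float = 0.0
    lo: float = -math.inf
    hi: float = math.inf
    family: Literal["normal", "uniform"] = "normal"

    @model_validator(mode="after")
    def _check(self) -> "MeasurementParams":
        if self.family == "normal" and self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not self.lo < self.hi:
            raise ValueError("lo must be < hi")
        return self


class CategoricalParams(BaseModel):
    """Ordered categorical (urinalysis) with a probit latent-risk link."""

    model_config = ConfigDict(extra="forbid")

    probs: Dict[str, float]  # marginal probabilities, risk-ordered keys
    risk_loading: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "CategoricalParams":
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.probs.values()):
            raise ValueError("category probabilities must be >= 0 and sum to 1")
        return self


class AgeParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean: float
    sd: float = Field(gt=0)


class CohortConfig(BaseModel):
    """All parameters of the synthetic population."""

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(default=TOTAL_SUBJECTS, gt=0)
    strata_weights: Dict[str, float]
    age_params: Dict[str, AgeParams]  # keyed by area
    age_ref: float = 35.8  # centre of the age slopes (cohort mean age)
    measurement_params: Dict[str, MeasurementParams]
    categorical_params: Dict[str, CategoricalParams] = {}
    binary_params: Dict[str, float] = {}  # field -> P(true)
    occupation_probs: Dict[str, float] = {}
    followup_effect: Dict[str, float] = {}  # additive mean shift at visit 2
    missingness_rates: Dict[str, float] = {}
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if set(self.strata_weights) != set(STRATA):
            raise ValueError(f"strata_weights must have keys {STRATA}")
        if abs(sum(self.strata_weights.values()) - 1.0) > 1e-12:
            raise ValueError("strata_weights must sum to 1")
        if any(w < 0 for w in self.strata_weights.values()):
            raise ValueError("strata_weights must be >= 0")
        for name, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0, 1]")
        for name, p in self.binary_params.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"binary probability for {name!r} outside [0, 1]")
        return self


def default_config(n_subjects: int = TOTAL_SUBJECTS, seed: int = 0) -> CohortConfig:
    """The default synthetic population.

    Stratum weights and age distributions equal the published cohort
    structure; systolic blood pressure is Normal(121, 17) marginally
    (loading 8 + residual 15) and shifts by −5 mmHg at the follow-up
    visit. The remaining measurement parameters are package choices of
    plausible adult values — the source study published no further
    moments — placed so that :func:`calibrate_config` can steer the
    per-item yellow-or-worse fractions onto the published targets.
    """
    weights = {k: v / TOTAL_SUBJECTS for k, v in STRATUM_COUNTS.items()}
    mp = {
        "height_cm": MeasurementParams(mean=160.0, sd=8.5, lo=120, hi=210),
        "weight_kg": MeasurementParams(mean=56.0, sd=8.0, risk_loading=5.0, lo=28, hi=160),
        "waist_cm": MeasurementParams(mean=80.0, sd=8.0, risk_loading=5.0, lo=45, hi=160),
        "hip_cm": MeasurementParams(mean=91.0, sd=6.0, risk_loading=2.0, lo=55, hi=170),
        # marginal SD sqrt(8^2 + 15^2) = 17, the published value
        "sbp_mmHg": MeasurementParams(
            mean=121.0, sd=15.0, risk_loading=8.0, age_slope=0.2, lo=60, hi=270
        ),
        "dbp_mmHg": MeasurementParams(
            mean=76.0, sd=9.0, risk_loading=6.0, age_slope=0.1, lo=35, hi=160
        ),
        "blood_sugar_mg_dl": MeasurementParams(
            mean=92.0, sd=13.0, risk_loading=14.0, lo=35, hi=600
        ),
        "hours_since_meal": MeasurementParams(lo=0.0, hi=16.0, family="uniform"),
        "pulse_bpm": MeasurementParams(mean=78.0, sd=10.0, risk_loading=2.0, lo=25, hi=220),
        "temperature_c": MeasurementParams(mean=36.4, sd=0.3, risk_loading=0.05, lo=34, hi=42),
        "spo2_pct": MeasurementParams(mean=98.0, sd=1.0, risk_loading=-0.3, lo=55, hi=100),
    }
    cp = {
        "urine_protein": CategoricalParams(
            probs={"negative": 0.62, "trace": 0.30, "positive": 0.08}, risk_loading=0.4
        ),
        "urine_sugar": CategoricalParams(
            probs={"negative": 0.95, "trace": 0.03, "positive": 0.02}, risk_loading=0.8
        ),
        "urine_urobilinogen": CategoricalParams(
            probs={"negative": 0.20, "trace": 0.79, "positive": 0.01}, risk_loading=0.1
        ),
    }
    return CohortConfig(
        n_subjects=n_subjects,
        strata_weights=weights,
        age_params={
            "rural": AgeParams(mean=43.6, sd=14.0),
            "urban": AgeParams(mean=29.6, sd=6.9),
        },
        measurement_params=mp,
        categorical_params=cp,
        binary_params={"smoker": 0.22, "arrhythmia": 0.01, "literate": 0.58},
        occupation_probs={
            "daily_labor": 0.22,
            "business": 0.14,
            "service": 0.34,
            "student": 0.06,
            "housewife": 0.18,
            "unemployed": 0.06,
        },
        followup_effect={"sbp_mmHg": -5.0},
        # blood sugar was measured in 15,705 of the 16,741 first-visit
        # subjects; other panels were near-complete
        missingness_rates={"blood_sugar_mg_dl": 1036 / TOTAL_SUBJECTS},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sampling


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: float,
    lo: float,
    hi: float,
    max_rounds: int = 200,
) -> np.ndarray:
    """Normal draws resampled (not clipped) into [lo, hi]."""
    values = mean + sd * rng.standard_normal(mean.shape)
    bad = (values < lo) | (values > hi)
    rounds = 0
    while bad.any() and rounds < max_rounds:
        values[bad] = mean[bad] + sd * rng.standard_normal(int(bad.sum()))
        bad = (values < lo) | (values > hi)
        rounds += 1
    if bad.any():  # pathological parameters; clamp the stragglers
        values = np.clip(values, lo, hi)
    return values


def generate_frame(config: CohortConfig, visit: int = 1) -> pd.DataFrame:
    """Draw the cohort as a raw DataFrame (fast path, no record validation).

    Visit 2 reuses the visit-1 subjects — same demographics and latent
    risk factors — and applies ``followup_effect`` plus fresh measurement
    noise, so visit-to-visit change analyses see genuinely paired data.
    """
    if visit not in (1, 2):
        raise ValueError("visit must be 1 or 2")
    # re-run the invariant checks: mutated/updated configs fail here,
    # before any sampling happens
    config = CohortConfig.model_validate(config.model_dump())
    n = config.n_subjects
    root = np.random.SeedSequence(config.seed)
    subject_ss, visit1_ss, visit2_ss = root.spawn(3)
    rng_subj = np.random.default_rng(subject_ss)
    visit_ss = visit1_ss if visit == 1 else visit2_ss

    # --- subject-level structure (shared across visits) ---
    strata = rng_subj.choice(
        len(STRATA), size=n, p=[config.strata_weights[s] for s in STRATA]
    )
    area = np.where(strata < 2, "rural", "urban")
    sex = np.where(strata % 2 == 0, "male", "female")
    age = np.empty(n)
    for a in ("rural", "urban"):
        mask = area == a
        params = config.age_params[a]
        age[mask] = _truncated_normal(
            rng_subj,
            np.full(int(mask.sum()), params.mean),
            params.sd,
            *AGE_BOUNDS,
        )
    age = np.floor(age).astype(int)
    z = rng_subj.standard_normal(n)  # latent risk factor

    occupations = list(config.occupation_probs) or ["service"]
    occ_probs = np.array(
        [config.occupation_probs.get(o, 1.0) for o in occupations], dtype=float
    )
    occ_probs /= occ_probs.sum()
    occupation = rng_subj.choice(occupations, size=n, p=occ_probs)

    subject_binaries = {}
    for name in ("smoker", "literate"):
        if name in config.binary_params:
            subject_binaries[name] = rng_subj.random(n) < config.binary_params[name]

    frame: dict[str, object] = {
        "subject_id": [f"S{i:06d}" for i in range(1, n + 1)],
        "age": age,
        "sex": sex,
        "area": area,
        "occupation": occupation,
        **subject_binaries,
    }

    # --- visit-level measurements ---
    # one independent child stream per field: calibration shifts of one
    # measurement's mean never perturb another measurement's draws
    field_names = (
        sorted(config.measurement_params)
        + sorted(config.categorical_params)
        + [b for b in sorted(config.binary_params) if b not in ("smoker", "literate")]
        + ["__missingness__"]
    )
    children = dict(zip(field_names, visit_ss.spawn(len(field_names))))

    for name in sorted(config.measurement_params):
        params = config.measurement_params[name]
        rng = np.random.default_rng(children[name])
        if params.family == "uniform":
            values = rng.uniform(params.lo, params.hi, size=n)
        else:
            mean = (
                params.mean
                + params.age_slope * (age - config.age_ref)
                + params.risk_loading * z
            )
            if visit == 2:
                mean = mean + config.followup_effect.get(name, 0.0)
            values = _truncated_normal(rng, mean, params.sd, params.lo, params.hi)
        frame[name] = values

    for name in sorted(config.categorical_params):
        params = config.categorical_params[name]
        rng = np.random.default_rng(children[name])
        cats = list(params.probs)
        cum = np.cumsum([params.probs[c] for c in cats])[:-1]
        scale = math.sqrt(1.0 + params.risk_loading**2)
        from scipy.stats import norm

        cuts = norm.ppf(cum) * scale
        u = params.risk_loading * z + rng.standard_normal(n)
        frame[name] = np.array(cats, dtype=object)[np.searchsorted(cuts, u)]

    for name in sorted(config.binary_params):
        if name in ("smoker", "literate"):
            continue
        rng = np.random.default_rng(children[name])
        frame[name] = rng.random(n) < config.binary_params[name]

    out = pd.DataFrame(frame)

    rng_miss = np.random.default_rng(children["__missingness__"])
    for name in sorted(config.missingness_rates):
        rate = config.missingness_rates[name]
        if name in out.columns and rate > 0:
            mask = rng_miss.random(n) < rate
            out.loc[mask, name] = np.nan
    return out


def generate_cohort(config: CohortConfig, visit: int = 1) -> CohortTable:
    """Generate a validated :class:`CohortTable` (reproducible per seed)."""
    frame = generate_frame(config, visit=visit)
    return CohortTable.from_frame(frame, visit_label=f"visit{visit}")


# ---------------------------------------------------------------------------
# calibration


class CalibrationError(RuntimeError):
    pass


#: which location parameter steers each item's yellow-or-worse fraction.
#: ``sign`` is the direction of the prevalence response to the knob.
CALIBRATION_KNOBS: Mapping[str, tuple[str, int]] = {
    "waist": ("waist_cm", +1),
    "waist_hip_ratio": ("hip_cm", -1),  # wider hips lower the ratio
    "bmi": ("weight_kg", +1),
    # systolic mean is pinned at the published 121 mmHg; steer diastolic
    "blood_pressure": ("dbp_mmHg", +1),
    "blood_sugar": ("blood_sugar_mg_dl", +1),
    "pulse": ("pulse_bpm", +1),
    "temperature": ("temperature_c", +1),
    "spo2": ("spo2_pct", -1),
}


def item_prevalence(
    frame: pd.DataFrame, item: str, rules: RuleTable, at_least: Grade = Grade.YELLOW
) -> float:
    """Fraction of *all* subjects graded at or above ``at_least`` on an item.

    Missing grades count toward the denominator, matching how the study
    reported item fractions against the full cohort size.
    """
    if item not in rules.items:
        raise KeyError(f"item {item!r} not in rule table")
    sub = RuleTable(
        items={item: rules.items[item]},
        fasting_cutoff_hours=rules.fasting_cutoff_hours,
    )
    grades = grade_cohort_frame(frame, sub)[f"grade_{item}"]
    order = {"green": 0, "yellow": 1, "orange": 2, "red": 3}
    hits = grades.map(lambda g: order.get(g, -1) if isinstance(g, str) else -1)
    return float((hits >= int(at_least)).mean())


def calibrate_config(
    config: CohortConfig,
    prevalence_targets: Mapping[str, float],
    rules: RuleTable,
    n_calib: int = 50_000,
    seed: Optional[int] = None,
    tol: float = 0.002,
    max_iter: int = 60,
) -> CohortConfig:
    """Tune per-item location parameters to hit target ≥YELLOW fractions.

    For each targeted item the associated location parameter (see
    ``CALIBRATION_KNOBS``) is adjusted by 1-D bisection until the
    simulated fraction graded yellow-or-worse, at ``n_calib`` draws with a
    fixed seed, is within ``tol`` of the target (default 0.2 percentage
    points, well inside the ±0.5-point contract). Raises
    :class:`CalibrationError` when a target cannot be bracketed within
    physiologic parameter bounds.
    """
    for item, target in prevalence_targets.items():
        if not 0.0 < target < 1.0:
            raise ValueError(f"target for {item!r} must lie in (0, 1)")
        if item not in CALIBRATION_KNOBS:
            raise CalibrationError(f"no calibration knob defined for item {item!r}")

    work = config.model_copy(deep=True)
    work.n_subjects = n_calib
    if seed is not None:
        work.seed = seed

    def prevalence(item: str) -> float:
        return item_prevalence(generate_frame(work, visit=1), item, rules)

    for item in sorted(prevalence_targets):
        target = prevalence_targets[item]
        field_name, sign = CALIBRATION_KNOBS[item]
        params = work.measurement_params[field_name]
        centre = params.mean
        # bracket: expand symmetric steps of the marginal scale
        scale = max(math.sqrt(params.sd**2 + params.risk_loading**2), 1e-6)
        lo_knob, hi_knob = None, None
        for width in (1, 2, 4, 8, 16):
            lo_try, hi_try = centre - width * scale, centre + width * scale
            params.mean = lo_try
            p_lo = prevalence(item)
            params.mean = hi_try
            p_hi = prevalence(item)
            if sign < 0:
                lo_try, hi_try, p_lo, p_hi = hi_try, lo_try, p_hi, p_lo
            if p_lo <= target <= p_hi:
                lo_knob, hi_knob = lo_try, hi_try
                break
        if lo_knob is None:
            params.mean = centre
            raise CalibrationError(
                f"target {target:.4f} for item {item!r} not reachable by moving "
                f"{field_name} within ±16 marginal SDs"
            )
        for _ in range(max_iter):
            mid = 0.5 * (lo_knob + hi_knob)
            params.mean = mid
            p_mid = prevalence(item)
            if abs(p_mid - target) <= tol:
                break
            if p_mid < target:
                lo_knob = mid
            else:
                hi_knob = mid
        else:
            raise CalibrationError(
                f"bisection for item {item!r} did not converge to ±{tol} "
                f"in {max_iter} iterations"
            )

    calibrated = work.model_copy(deep=True)
    calibrated.n_subjects = config.n_subjects
    calibrated.seed = config.seed if seed is None else seed
    return calibrated
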