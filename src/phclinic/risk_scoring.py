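"""Diabetes-risk labeling and a pluggable risk-scorer contract.

The screening-economics stage needs, per subject, a risk score in [0, 1]
for "blood-sugar grade would be orange or red", computed *without looking
at the blood-sugar measurement*. Any fitted classifier satisfying the
small :class:`RiskScorer` protocol can supply these scores; the built-in
:class:`ReferenceScorer` is a transparent additive log-odds (naive-Bayes
style weight-of-evidence) model over the non-glucose item grades and
demographics, so the pipeline carries no opaque ML dependency.

A feature-name blacklist enforces the no-leakage contract: nothing
derived from the blood-sugar measurement may enter the feature set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Protocol, Tuple, runtime_checkable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort_io import CohortTable
from .stratification import Grade, RuleTable, grade_cohort_frame

__all__ = [
    "LEAKAGE_BLACKLIST",
    "LabeledDataset",
    "RiskScorer",
    "ReferenceScorer",
    "make_labels",
    "make_features",
    "fit_reference_scorer",
    "predict_risk",
    "split_train_test",
]

#: columns that may never appear among the features (direct leakage of the
#: quantity being predicted)
LEAKAGE_BLACKLIST = frozenset({"blood_sugar_mg_dl", "grade_blood_sugar"})

#: age-band edges for the age feature (10-year bands)
AGE_BAND_EDGES = (25, 35, 45, 55, 65, 75)

_DEMOGRAPHIC_FEATURES = ("sex", "area", "occupation", "literate", "smoker")


def _age_band(age: float) -> str:
    prev = 0
    for edge in AGE_BAND_EDGES:
        if age < edge:
            return f"{prev}-{edge - 1}"
        prev = edge
    return f"{AGE_BAND_EDGES[-1]}+"


def make_features(cohort: CohortTable | pd.DataFrame, rules: RuleTable) -> pd.DataFrame:
    """Build the scorer's feature frame: item grades + binned demographics.

    Numeric measurements enter through their rule-table grade (i.e. binned
    at the stratification thresholds); age is binned into 10-year bands;
    categorical demographics pass through as-is. Everything connected to
    the blood-sugar test is excluded and the exclusion is asserted.
    """
    frame = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort
    grades = grade_cohort_frame(frame, rules)
    feat = pd.DataFrame(index=frame.index)
    feat["age_band"] = frame["age"].map(_age_band)
    for col in _DEMOGRAPHIC_FEATURES:
        if col in frame.columns:
            feat[col] = frame[col].map(
                lambda v: np.nan if pd.isna(v) else str(v).lower()
            )
    for col in grades.columns:
        if col == "overall_grade":  # aggregates the predicted item itself
            continue
        if col in LEAKAGE_BLACKLIST:
            continue
        feat[col] = grades[col]
    bad = set(feat.columns) & LEAKAGE_BLACKLIST
    assert not bad, f"leakage: blacklisted features {bad}"
    return feat


@dataclass
class LabeledDataset:
    """Feature rows plus the boolean blood-sugar-risk label."""

    features: pd.DataFrame
    labels: np.ndarray  # bool, aligned with features rows
    subject_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            subject_ids=[self.subject_ids[i] for i in idx] if self.subject_ids else [],
        )


def make_labels(cohort: CohortTable | pd.DataFrame, rules: RuleTable) -> LabeledDataset:
    """Label eligible subjects: blood-sugar grade orange-or-red.

    Subjects without a blood-sugar measurement (hence no blood-sugar
    grade) are excluded — they could never have been labeled either way.
    """
    frame = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort
    grades = grade_cohort_frame(frame, rules)
    if "grade_blood_sugar" not in grades.columns:
        raise ValueError("rule table lacks a blood_sugar item; cannot label")
    bs = grades["grade_blood_sugar"]
    eligible = bs.notna().to_numpy()
    if not eligible.any():
        raise ValueError("no subject has a gradable blood-sugar measurement")
    labels = (
        bs[eligible]
        .map(lambda g: Grade.from_name(g) >= Grade.ORANGE)
        .to_numpy(dtype=bool)
    )
    features = make_features(frame.loc[eligible], rules).reset_index(drop=True)
    ids = (
        frame.loc[eligible, "subject_id"].astype(str).tolist()
        if "subject_id" in frame.columns
        else []
    )
    return LabeledDataset(features=features, labels=labels, subject_ids=ids)


@runtime_checkable
class RiskScorer(Protocol):
    """Anything that deterministically maps feature rows to scores in [0, 1]."""

    def score_frame(self, features: pd.DataFrame) -> np.ndarray: ...


@dataclass
class ReferenceScorer:
    """Additive log-odds scorer over binned features.

    Each feature bin carries a smoothed weight of evidence
    ``log P(bin|pos) − log P(bin|neg)`` (Laplace pseudo-count per bin);
    a subject's score is ``logistic(prior log-odds + Σ bin weights +
    calibration offset)``. Missing or unseen feature values contribute
    weight 0. The offset is fitted once so that the mean predicted risk
    on the training data equals the label prevalence
    (calibration-in-the-large).
    """

    prior_log_odds: float
    weights: Dict[str, Dict[str, float]]  # feature -> bin value -> weight
    calibration_offset: float = 0.0
    rules: Optional[RuleTable] = None

    def raw_log_odds(self, features: pd.DataFrame) -> np.ndarray:
        total = np.full(len(features), self.prior_log_odds)
        for col, table in self.weights.items():
            if col not in features.columns:
                continue
            w = features[col].map(
                lambda v: 0.0 if pd.isna(v) else table.get(str(v), 0.0)
            )
            total += w.to_numpy(dtype=float)
        return total

    def score_frame(self, features: pd.DataFrame) -> np.ndarray:
        return expit(self.raw_log_odds(features) + self.calibration_offset)


def fit_reference_scorer(
    data: LabeledDataset,
    smoothing: float = 1.0,
    rules: Optional[RuleTable] = None,
) -> ReferenceScorer:
    """Fit the additive log-odds reference scorer.

    ``smoothing`` is the Laplace pseudo-count added to every bin of every
    feature (default 1), which keeps weights finite in empty bins. Needs
    at least two examples of each label.
    """
    if smoothing <= 0:
        raise ValueError("smoothing pseudo-count must be > 0")
    y = data.labels
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 examples of each label to fit")

    weights: Dict[str, Dict[str, float]] = {}
    for col in data.features.columns:
        series = data.features[col]
        observed = series[series.notna()].astype(str)
        bins = sorted(observed.unique())
        if len(bins) < 2:
            continue  # constant feature carries no evidence
        k = len(bins)
        y_obs = y[observed.index.to_numpy()]
        table: Dict[str, float] = {}
        for b in bins:
            in_bin = (observed == b).to_numpy()
            c_pos = int(y_obs[in_bin].sum())
            c_all = int(in_bin.sum())
            c_neg = c_all - c_pos
            table[b] = math.log(
                (c_pos + smoothing) / (n_pos + smoothing * k)
            ) - math.log((c_neg + smoothing) / (n_neg + smoothing * k))
        weights[col] = table

    scorer = ReferenceScorer(
        prior_log_odds=math.log(n_pos / n_neg),
        weights=weights,
        rules=rules,
    )
    raw = scorer.raw_log_odds(data.features)
    target = n_pos / (n_pos + n_neg)

    def gap(delta: float) -> float:
        return float(expit(raw + delta).mean() - target)

    lo, hi = -30.0, 30.0
    if gap(lo) * gap(hi) < 0:
        scorer.calibration_offset = float(brentq(gap, lo, hi, xtol=1e-10))
    return scorer


def predict_risk(
    scorer: RiskScorer,
    cohort: CohortTable | pd.DataFrame,
    rules: Optional[RuleTable] = None,
) -> np.ndarray:
    """Score every record of a cohort with a fitted scorer.

    ``rules`` defaults to the rule table stored on the scorer at fit
    time. Scores are deterministic and row-wise independent.
    """
    if rules is None:
        rules = getattr(scorer, "rules", None)
    if rules is None:
        raise ValueError("a rule table is needed to featurize the cohort")
    features = make_features(cohort, rules)
    scores = np.asarray(scorer.score_frame(features), dtype=float)
    if not np.all(np.isfinite(scores)) or scores.min() < 0 or scores.max() > 1:
        raise ValueError("scorer produced scores outside [0, 1]")
    return scores


def split_train_test(
    data: LabeledDataset, train_fraction: float = 0.6, seed: int = 0
) -> Tuple[LabeledDataset, LabeledDataset]:
    """Random split without replacement (evaluation-harness protocol)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(data)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return data.subset(perm[:n_train]), data.subset(perm[n_train:])
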