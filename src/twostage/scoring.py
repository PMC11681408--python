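"""Prescreening risk scores: unweighted 0-3 point systems and weighted variants.

Three scoring systems summarise a participant's prescreen burden on a 0-3
scale, graded none (0) / mild (1) / moderate (2) / severe (3):

* **retinal** — retinopathy counts 3 points (it represents end-stage retinal
  disease, usually preceded by the other signs), arteriovenous nicking, focal
  arteriolar narrowing and generalized arteriolar narrowing 1 point each; the
  sum is truncated at 3.
* **clinical** — one point each for age at/above the cutoff (60 y in late
  midlife, 78 y in late life), hypertension, and diabetes.
* **combined** — clinical + retinal, truncated at 3.

The weighted variant replaces the fixed point table with data-driven weights
from an L2-regularized logistic regression of significant-WMH status on the
standardized binary predictors; absolute coefficients are normalized to mean
1 across the predictor set and the maximum attainable weighted sum is
rescaled to 3, so weighted scores live on the same 0-3 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .cohort import (
    DEFAULT_CHS_CUTOFF,
    DEFAULT_VOLUME_CUTOFF_CM3,
    SEVERITY_LABELS,
    ParticipantRecord,
    classify_wmh,
)

__all__ = [
    "ScoreDefinition",
    "ScoreResult",
    "WeightedScoreModel",
    "RETINAL_FEATURES",
    "CLINICAL_FEATURES",
    "COMBINED_FEATURES",
    "retinal_score",
    "clinical_score",
    "combined_score",
    "score",
    "fit_weighted_model",
    "weighted_score",
]

RETINAL_FEATURES = ("retinopathy", "av_nicking", "focal_narrowing",
                    "generalized_narrowing")
CLINICAL_FEATURES = ("age_at_or_above_cutoff", "hypertension", "diabetes")
COMBINED_FEATURES = RETINAL_FEATURES + CLINICAL_FEATURES

_DEFAULT_POINTS = {
    "retinal": {"retinopathy": 3, "av_nicking": 1, "focal_narrowing": 1,
                "generalized_narrowing": 1},
    "clinical": {"age_at_or_above_cutoff": 1, "hypertension": 1, "diabetes": 1},
}

ScoreKind = Literal["retinal", "clinical", "combined"]


@dataclass(frozen=True)
class ScoreDefinition:
    """Point table and cutoffs for one unweighted scoring system."""

    kind: ScoreKind
    feature_points: Mapping[str, int] = field(default_factory=dict)
    age_cutoff_years: float = 60.0
    age_comparison: Literal["ge", "gt"] = "ge"
    max_score: int = 3

    def __post_init__(self) -> None:
        points = dict(self.feature_points)
        if not points:
            if self.kind == "retinal":
                points = dict(_DEFAULT_POINTS["retinal"])
            elif self.kind == "clinical":
                points = dict(_DEFAULT_POINTS["clinical"])
            elif self.kind == "combined":
                points = {**_DEFAULT_POINTS["retinal"], **_DEFAULT_POINTS["clinical"]}
            else:
                raise ValueError(f"unknown score kind {self.kind!r}")
        if any(p <= 0 for p in points.values()):
            raise ValueError("all feature points must be positive")
        if self.max_score < max(points.values()):
            raise ValueError("max_score must cover the largest single-feature points")
        object.__setattr__(self, "feature_points", points)

    def age_positive(self, age_years: float) -> bool:
        if self.age_comparison == "ge":
            return age_years >= self.age_cutoff_years
        return age_years > self.age_cutoff_years

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_points": dict(self.feature_points),
            "age_cutoff_years": self.age_cutoff_years,
            "age_comparison": self.age_comparison,
            "max_score": self.max_score,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreDefinition":
        return cls(**d)


@dataclass(frozen=True)
class ScoreResult:
    """An integer 0-3 score with its severity category."""

    score: int
    category: str
    kind: str
    raw_value: float | None = None  # pre-binning value for weighted scores


def _categorize(score: int) -> str:
    return SEVERITY_LABELS[score]


def _feature_value(record: ParticipantRecord, feature: str,
                   definition: ScoreDefinition) -> bool:
    if feature == "age_at_or_above_cutoff":
        return definition.age_positive(record.age_years)
    value = getattr(record, feature)
    if value is None:
        raise ValueError(f"record {record.id!r}: prescreen feature {feature!r} "
                         "is unresolved")
    return bool(value)


def _points_score(record: ParticipantRecord, definition: ScoreDefinition) -> int:
    total = sum(points for feature, points in definition.feature_points.items()
                if _feature_value(record, feature, definition))
    return min(definition.max_score, total)


def retinal_score(record: ParticipantRecord,
                  definition: ScoreDefinition | None = None) -> ScoreResult:
    """Sum the retinal sign points (retinopathy 3, others 1), truncated at 3."""
    definition = definition or ScoreDefinition(kind="retinal")
    s = _points_score(record, definition)
    return ScoreResult(s, _categorize(s), "retinal")


def clinical_score(record: ParticipantRecord,
                   definition: ScoreDefinition | None = None) -> ScoreResult:
    """One point each for age at/above cutoff, hypertension, diabetes (0-3)."""
    definition = definition or ScoreDefinition(kind="clinical")
    s = _points_score(record, definition)
    return ScoreResult(s, _categorize(s), "clinical")


def combined_score(record: ParticipantRecord,
                   definition: ScoreDefinition | None = None) -> ScoreResult:
    """Clinical + retinal score, truncated at the shared 0-3 cap."""
    definition = definition or ScoreDefinition(kind="combined")
    retinal_def = ScoreDefinition(
        kind="retinal",
        feature_points={k: v for k, v in definition.feature_points.items()
                        if k in RETINAL_FEATURES},
        age_cutoff_years=definition.age_cutoff_years,
        age_comparison=definition.age_comparison,
        max_score=definition.max_score,
    )
    clinical_def = ScoreDefinition(
        kind="clinical",
        feature_points={k: v for k, v in definition.feature_points.items()
                        if k in CLINICAL_FEATURES},
        age_cutoff_years=definition.age_cutoff_years,
        age_comparison=definition.age_comparison,
        max_score=definition.max_score,
    )
    s = min(definition.max_score,
            _points_score(record, retinal_def) + _points_score(record, clinical_def))
    return ScoreResult(s, _categorize(s), "combined")


_SCORERS = {"retinal": retinal_score, "clinical": clinical_score,
            "combined": combined_score}


def score(record: ParticipantRecord, kind: str,
          definition: ScoreDefinition | None = None) -> ScoreResult:
    """Dispatch to the scorer for ``kind`` (retinal/clinical/combined)."""
    try:
        scorer = _SCORERS[kind]
    except KeyError:
        raise ValueError(f"unknown score kind {kind!r}; "
                         f"expected one of {sorted(_SCORERS)}") from None
    return scorer(record, definition)


@dataclass(frozen=True)
class WeightedScoreModel:
    """Data-driven feature weights rescaled onto the 0-3 severity scale.

    ``normalized_weights`` are absolute ridge-logistic coefficients scaled to
    mean 1 over the predictor set; ``rescale_factor`` maps the maximum
    attainable weighted sum (all features present) to ``max_score``; binning
    to severity categories rounds the rescaled score half-up to the nearest
    integer.
    """

    kind: str
    normalized_weights: Mapping[str, float]
    rescale_factor: float
    max_score: int = 3
    age_cutoff_years: float = 60.0
    age_comparison: Literal["ge", "gt"] = "ge"
    regularization_lambda: float = 1.0

    def __post_init__(self) -> None:
        weights = dict(self.normalized_weights)
        if any(w < 0 for w in weights.values()):
            raise ValueError("normalized weights must be non-negative")
        object.__setattr__(self, "normalized_weights", weights)

    def bin_score(self, raw: float) -> int:
        # round half-up, clipped to [0, max_score]
        binned = int(np.floor(raw + 0.5))
        return max(0, min(self.max_score, binned))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "normalized_weights": dict(self.normalized_weights),
            "rescale_factor": self.rescale_factor,
            "max_score": self.max_score,
            "age_cutoff_years": self.age_cutoff_years,
            "age_comparison": self.age_comparison,
            "regularization_lambda": self.regularization_lambda,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightedScoreModel":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "WeightedScoreModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _predictor_matrix(records: Sequence[ParticipantRecord], features: tuple[str, ...],
                      definition: ScoreDefinition) -> np.ndarray:
    return np.array(
        [[_feature_value(r, f, definition) for f in features] for r in records],
        dtype=float,
    )


def fit_weighted_model(
    records: Sequence[ParticipantRecord],
    predictor_set: ScoreKind = "retinal",
    *,
    wmh_basis: Literal["auto", "chs", "volume"] = "auto",
    chs_cutoff: int = DEFAULT_CHS_CUTOFF,
    volume_cutoff_cm3: float = DEFAULT_VOLUME_CUTOFF_CM3,
    age_cutoff_years: float = 60.0,
    age_comparison: Literal["ge", "gt"] = "ge",
    regularization_lambda: float = 1.0,
    max_score: int = 3,
    min_records: int = 50,
    seed: int | None = 0,
) -> WeightedScoreModel:
    """Fit the weighted scoring model for one predictor set.

    Significant-WMH status is regressed on the set's standardized binary
    predictors with an L2 penalty (strength ``regularization_lambda``, fixed
    rather than cross-validated so the fit is deterministic); weights are the
    absolute coefficients normalized to mean 1. Requires at least
    ``min_records`` classified records with both outcome classes present, and
    refuses constant or collinear predictor columns rather than silently
    dropping them.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    features = {"retinal": RETINAL_FEATURES, "clinical": CLINICAL_FEATURES,
                "combined": COMBINED_FEATURES}.get(predictor_set)
    if features is None:
        raise ValueError(f"unknown predictor set {predictor_set!r}")
    if len(records) < min_records:
        raise ValueError(f"need >= {min_records} records to fit a weighted model, "
                         f"got {len(records)}")

    definition = ScoreDefinition(kind="clinical", age_cutoff_years=age_cutoff_years,
                                 age_comparison=age_comparison)
    X = _predictor_matrix(records, features, definition)
    y = np.array(
        [classify_wmh(r, basis=wmh_basis, chs_cutoff=chs_cutoff,
                      volume_cutoff_cm3=volume_cutoff_cm3).significant
         for r in records],
        dtype=int,
    )
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit weights")
    constant = [f for f, col in zip(features, X.T) if np.ptp(col) == 0]
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("collinear predictor design; refusing to fit")

    Xs = StandardScaler().fit_transform(X)
    model = LogisticRegression(  # default penalty is L2; strength via C
        C=1.0 / regularization_lambda, solver="lbfgs",
        max_iter=1000, random_state=seed,
    ).fit(Xs, y)
    coefs = np.abs(model.coef_.ravel())
    if coefs.sum() == 0:
        raise ValueError("all coefficients shrank to zero; cannot normalize weights")
    weights = coefs / coefs.mean()  # normalized to mean 1 across the set
    rescale = max_score / weights.sum()  # max attainable sum -> max_score
    return WeightedScoreModel(
        kind=predictor_set,
        normalized_weights=dict(zip(features, weights.tolist())),
        rescale_factor=float(rescale),
        max_score=max_score,
        age_cutoff_years=age_cutoff_years,
        age_comparison=age_comparison,
        regularization_lambda=regularization_lambda,
    )


def weighted_score(record: ParticipantRecord,
                   model: WeightedScoreModel) -> ScoreResult:
    """Rescaled weighted sum in [0, 3], binned to a severity category."""
    definition = ScoreDefinition(
        kind="clinical", age_cutoff_years=model.age_cutoff_years,
        age_comparison=model.age_comparison,
    )
    raw = sum(
        w * _feature_value(record, f, definition)
        for f, w in model.normalized_weights.items()
    ) * model.rescale_factor
    binned = model.bin_score(raw)
    return ScoreResult(binned, _categorize(binned), f"weighted_{model.kind}",
                       raw_value=float(raw))
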