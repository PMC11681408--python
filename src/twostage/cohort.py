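"""Participant-level cohort table: records, CSV I/O, WMH classification, cross-tabulation.

The cohort schema mirrors what a two-stage recruitment analysis needs: four
binary retinal microvascular signs graded from fundus photographs
(retinopathy, arteriovenous nicking, focal and generalized arteriolar
narrowing), two clinical risk factors (hypertension, diabetes), age in years,
and white-matter-hyperintensity (WMH) burden on either an ordinal CHS
(Cardiovascular Health Study) grade or a FLAIR-derived volume in cm^3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantRecord",
    "WmhStatus",
    "CrossTab",
    "ExclusionReport",
    "CohortSchemaError",
    "COHORT_COLUMNS",
    "FEATURE_COLUMNS",
    "SEVERITY_LABELS",
    "load_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
    "classify_wmh",
    "cross_tabulate",
    "DEFAULT_CHS_CUTOFF",
    "DEFAULT_VOLUME_CUTOFF_CM3",
]

#: Significant WMH burden on the ordinal CHS scale: grade strictly above this.
DEFAULT_CHS_CUTOFF = 2
#: Late-life volumetric equivalent of CHS grade > 2 (cm^3, ICV-standardized).
DEFAULT_VOLUME_CUTOFF_CM3 = 9.3

SEVERITY_LABELS = ("none", "mild", "moderate", "severe")

FEATURE_COLUMNS = (
    "retinopathy",
    "av_nicking",
    "focal_narrowing",
    "generalized_narrowing",
    "hypertension",
    "diabetes",
)

COHORT_COLUMNS = (
    "id",
    "age_years",
    *FEATURE_COLUMNS,
    "chs_grade",
    "wmh_volume_cm3",
    "followup_wmh_volume_cm3",
)

_BOOL_TOKENS = {
    "0": False, "1": True,
    "true": True, "false": False,
    "yes": True, "no": False,
}


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV violates the documented schema."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's prescreen features and WMH measurements.

    Boolean fields are ``None`` while missing; records entering scoring or
    classification must have them resolved (see :func:`load_cohort` policies).
    """

    id: str
    age_years: float
    retinopathy: bool | None = None
    av_nicking: bool | None = None
    focal_narrowing: bool | None = None
    generalized_narrowing: bool | None = None
    hypertension: bool | None = None
    diabetes: bool | None = None
    chs_grade: int | None = None
    wmh_volume_cm3: float | None = None
    followup_wmh_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"record {self.id!r}: negative age {self.age_years}")
        for name in ("wmh_volume_cm3", "followup_wmh_volume_cm3"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"record {self.id!r}: negative {name} {v}")

    def missing_features(self) -> tuple[str, ...]:
        return tuple(f for f in FEATURE_COLUMNS if getattr(self, f) is None)


@dataclass(frozen=True)
class WmhStatus:
    """Binary significant-WMH classification and the scale it was made on."""

    significant: bool
    basis: Literal["chs_threshold", "volume_threshold"]


@dataclass
class ExclusionReport:
    """Rows dropped during loading, with the reason per row."""

    n_input: int = 0
    n_retained: int = 0
    reasons: dict[str, int] = field(default_factory=dict)
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    def add(self, record_id: str, reason: str) -> None:
        self.reasons[reason] = self.reasons.get(reason, 0) + 1
        self.excluded_ids.append(record_id)


def _parse_bool(token: object, *, row: int, column: str) -> bool | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    if isinstance(token, (bool, np.bool_)):
        return bool(token)
    text = str(token).strip().lower()
    if text in ("", "nan"):
        return None
    if text.endswith(".0") and text[:-2] in ("0", "1"):  # pandas float-casts 0/1 columns with blanks
        text = text[:-2]
    if text not in _BOOL_TOKENS:
        raise CohortSchemaError(
            f"row {row}, column {column!r}: {token!r} is not an accepted "
            "boolean coding (accepted: 0/1, true/false, yes/no)"
        )
    return _BOOL_TOKENS[text]


def _parse_optional_number(token: object, cast=float):
    if token is None:
        return None
    if isinstance(token, float) and math.isnan(token):
        return None
    text = str(token).strip()
    if text == "" or text.lower() == "nan":
        return None
    return cast(float(text))


def frame_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    """Convert a schema-conformant DataFrame to records (no exclusion policy)."""
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        records.append(
            ParticipantRecord(
                id=str(d["id"]),
                age_years=float(d["age_years"]),
                **{f: _parse_bool(d[f], row=i, column=f) for f in FEATURE_COLUMNS},
                chs_grade=_parse_optional_number(d.get("chs_grade"), cast=int),
                wmh_volume_cm3=_parse_optional_number(d.get("wmh_volume_cm3")),
                followup_wmh_volume_cm3=_parse_optional_number(
                    d.get("followup_wmh_volume_cm3")
                ),
            )
        )
    return records


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {f.name: getattr(r, f.name) for f in fields(r)}
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return df


def load_cohort(
    path: str | Path,
    *,
    missing_policy: Literal["exclude", "impute_mode"] = "exclude",
) -> tuple[list[ParticipantRecord], ExclusionReport]:
    """Read a cohort CSV, returning valid records plus an exclusion report.

    ``missing_policy`` governs records with unresolved binary prescreen
    features: ``"exclude"`` drops and counts them (the default, matching the
    usual handling of ungradable fundus photographs); ``"impute_mode"`` fills
    each missing feature with the cohort mode. Rows are returned in input
    order. Unknown columns raise a warning; absent mandatory columns are a
    hard error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortSchemaError(f"missing mandatory columns: {missing_cols}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)

    records = frame_to_records(df)
    report = ExclusionReport(n_input=len(records))

    if missing_policy == "impute_mode":
        modes: dict[str, bool] = {}
        for f in FEATURE_COLUMNS:
            vals = [getattr(r, f) for r in records if getattr(r, f) is not None]
            # tie or empty -> False (absence is the safer imputation for a risk sign)
            modes[f] = sum(vals) * 2 > len(vals) if vals else False
        records = [
            replace(r, **{f: modes[f] for f in r.missing_features()}) for r in records
        ]
    elif missing_policy != "exclude":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    retained = []
    for r in records:
        missing = r.missing_features()
        if missing:
            report.add(r.id, f"missing prescreen feature(s): {', '.join(missing)}")
        else:
            retained.append(r)
    report.n_retained = len(retained)
    return retained, report


def write_cohort(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    """Write records as a schema-conformant CSV (booleans as 0/1, missing as empty)."""
    df = records_to_frame(records)
    for f in FEATURE_COLUMNS:
        df[f] = df[f].map(lambda v: "" if v is None else str(int(v)))
    df["chs_grade"] = df["chs_grade"].map(lambda v: "" if v is None else str(int(v)))
    for c in ("wmh_volume_cm3", "followup_wmh_volume_cm3"):
        df[c] = df[c].map(lambda v: "" if v is None else repr(float(v)))
    df.to_csv(path, index=False)


def classify_wmh(
    record: ParticipantRecord,
    *,
    basis: Literal["auto", "chs", "volume"] = "auto",
    chs_cutoff: int = DEFAULT_CHS_CUTOFF,
    volume_cutoff_cm3: float = DEFAULT_VOLUME_CUTOFF_CM3,
) -> WmhStatus:
    """Classify significant WMH burden.

    On the CHS scale, significant means grade strictly greater than
    ``chs_cutoff`` (default > 2); on the volumetric scale, volume at or above
    ``volume_cutoff_cm3`` (default 9.3 cm^3). ``basis="auto"`` prefers the CHS
    grade when present.
    """
    if basis in ("auto", "chs") and record.chs_grade is not None:
        return WmhStatus(record.chs_grade > chs_cutoff, "chs_threshold")
    if basis in ("auto", "volume") and record.wmh_volume_cm3 is not None:
        return WmhStatus(record.wmh_volume_cm3 >= volume_cutoff_cm3, "volume_threshold")
    raise ValueError(
        f"record {record.id!r}: no WMH measurement available for basis {basis!r}"
    )


@dataclass(frozen=True)
class CrossTab:
    """Severity-category x WMH-status contingency table (4 x 2).

    Rows are the score severity categories none/mild/moderate/severe
    (scores 0/1/2/3); columns are WMH status (no/low burden, significant
    burden). Marginals are always derived from ``counts``, never cached.
    """

    counts: np.ndarray  # shape (4, 2), non-negative ints
    score_kind: str = "unspecified"
    row_labels: tuple[str, ...] = SEVERITY_LABELS
    col_labels: tuple[str, str] = ("no_low_wmh", "significant_wmh")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (4, 2):
            raise ValueError(f"counts must be 4x2, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_significant(self) -> int:
        return int(self.counts[:, 1].sum())

    def in_range(self, min_score: int) -> tuple[int, int]:
        """(total, significant) counts among categories with score >= min_score."""
        sel = self.counts[min_score:, :]
        return int(sel.sum()), int(sel[:, 1].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def to_dict(self) -> dict:
        return {
            "score_kind": self.score_kind,
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "counts": self.counts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossTab":
        return cls(
            counts=np.asarray(d["counts"], dtype=np.int64),
            score_kind=d.get("score_kind", "unspecified"),
            row_labels=tuple(d.get("row_labels", SEVERITY_LABELS)),
            col_labels=tuple(d.get("col_labels", ("no_low_wmh", "significant_wmh"))),
        )


def cross_tabulate(
    records: Sequence[ParticipantRecord],
    score_kind: str = "clinical",
    *,
    wmh_basis: Literal["auto", "chs", "volume"] = "auto",
    chs_cutoff: int = DEFAULT_CHS_CUTOFF,
    volume_cutoff_cm3: float = DEFAULT_VOLUME_CUTOFF_CM3,
    definition=None,
) -> CrossTab:
    """Score every record and tabulate severity category against WMH status.

    ``score_kind`` is one of ``retinal``, ``clinical``, ``combined``; an
    explicit :class:`~twostage.scoring.ScoreDefinition` may be passed to
    override the default point tables/cutoffs. The counts partition the
    cohort: every classified record lands in exactly one cell.
    """
    if not records:
        raise ValueError("cannot cross-tabulate an empty cohort")
    from . import scoring  # deferred: scoring depends on this module's types

    counts = np.zeros((4, 2), dtype=np.int64)
    for r in records:
        result = scoring.score(r, score_kind, definition=definition)
        status = classify_wmh(
            r, basis=wmh_basis, chs_cutoff=chs_cutoff,
            volume_cutoff_cm3=volume_cutoff_cm3,
        )
        counts[result.score, int(status.significant)] += 1
    return CrossTab(counts=counts, score_kind=score_kind)
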