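"""CHS-grade to WMH-volume conversion and significant-burden thresholds.

Ordinal CHS (Cardiovascular Health Study) grades and volumetric WMH measures
(cm^3, standardized to a 1500 cm^3 intracranial volume) coexist in
longitudinal cohorts whose earlier scans were only visually graded. A
quadratic regression of volume on grade, fitted where both measures exist,
converts baseline grades to estimated volumes so 10-year volume change can
be computed. When no fitted map is available, the fixed volumetric
equivalent of "significant WMH" (CHS grade > 2) is 9.3 cm^3. Volumes are
assumed pre-standardized; no re-standardization is performed here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import DEFAULT_CHS_CUTOFF, DEFAULT_VOLUME_CUTOFF_CM3, ParticipantRecord

__all__ = [
    "QuadraticMap",
    "fit_chs_volume_map",
    "grade_to_volume",
    "volume_threshold_equivalent",
    "ten_year_progression",
]


@dataclass(frozen=True)
class QuadraticMap:
    """volume = a0 + a1*grade + a2*grade^2, with fit diagnostics.

    Predictions are clipped at zero (volumes are physical quantities); grades
    outside the fitted range trigger an extrapolation warning.
    """

    a0: float
    a1: float
    a2: float
    r_squared: float
    n: int
    grade_min: int
    grade_max: int

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a0, self.a1, self.a2)

    def is_monotone_nondecreasing(self) -> bool:
        """True when the fitted parabola is non-decreasing over the fitted range."""
        # derivative a1 + 2*a2*g >= 0 at both endpoints suffices for a parabola;
        # small negative tolerance absorbs least-squares round-off
        tol = -1e-9 * max(1.0, abs(self.a0), abs(self.a1), abs(self.a2))
        d_lo = self.a1 + 2 * self.a2 * self.grade_min
        d_hi = self.a1 + 2 * self.a2 * self.grade_max
        return d_lo >= tol and d_hi >= tol

    def to_dict(self) -> dict:
        return {"a0": self.a0, "a1": self.a1, "a2": self.a2,
                "r_squared": self.r_squared, "n": self.n,
                "grade_min": self.grade_min, "grade_max": self.grade_max}

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticMap":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "QuadraticMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_chs_volume_map(pairs: Sequence[tuple[float, float]]) -> QuadraticMap:
    """Ordinary least-squares quadratic fit of WMH volume on CHS grade.

    Requires at least three distinct grades (else the quadratic is not
    identifiable) and non-negative volumes. Deterministic.
    """
    if not pairs:
        raise ValueError("no (grade, volume) pairs supplied")
    grades = np.asarray([p[0] for p in pairs], dtype=float)
    volumes = np.asarray([p[1] for p in pairs], dtype=float)
    if (volumes < 0).any():
        raise ValueError("volumes must be non-negative")
    if len(np.unique(grades)) < 3:
        raise ValueError("need >= 3 distinct CHS grades to fit a quadratic")
    # polynomial.Polynomial.fit works on a shifted domain; request raw coefs
    coefs = np.polynomial.polynomial.polyfit(grades, volumes, deg=2)
    fitted = np.polynomial.polynomial.polyval(grades, coefs)
    ss_res = float(np.sum((volumes - fitted) ** 2))
    ss_tot = float(np.sum((volumes - volumes.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    fit = QuadraticMap(
        a0=float(coefs[0]), a1=float(coefs[1]), a2=float(coefs[2]),
        r_squared=r2, n=len(pairs),
        grade_min=int(np.floor(grades.min())), grade_max=int(np.ceil(grades.max())),
    )
    if not fit.is_monotone_nondecreasing():
        warnings.warn(
            "fitted grade->volume map is not monotone over the fitted grade "
            "range; check the input pairs", stacklevel=2)
    return fit


def grade_to_volume(map_: QuadraticMap, grade: float) -> float:
    """Predicted WMH volume (cm^3) at a CHS grade, clipped at zero."""
    if grade < map_.grade_min or grade > map_.grade_max:
        warnings.warn(
            f"grade {grade} lies outside the fitted range "
            f"[{map_.grade_min}, {map_.grade_max}]; extrapolating", stacklevel=2)
    value = map_.a0 + map_.a1 * grade + map_.a2 * grade * grade
    return max(0.0, value)


def volume_threshold_equivalent(map_: QuadraticMap | None = None,
                                chs_cutoff: int = DEFAULT_CHS_CUTOFF) -> float:
    """Volumetric cutoff equivalent to significant WMH on the CHS scale.

    Significant means grade strictly above ``chs_cutoff``, so the equivalent
    volume is the predicted volume at the smallest significant grade
    (``chs_cutoff + 1``). Without a fitted map the published late-life
    default of 9.3 cm^3 is returned.
    """
    if map_ is None:
        return DEFAULT_VOLUME_CUTOFF_CM3
    return grade_to_volume(map_, chs_cutoff + 1)


def ten_year_progression(
    records: Iterable[ParticipantRecord], map_: QuadraticMap,
) -> tuple[pd.DataFrame, int]:
    """Per-record WMH volume change: follow-up volume minus mapped baseline grade.

    Records missing either the baseline CHS grade or the follow-up volume are
    skipped; the skipped count is returned alongside the change table.
    """
    rows = []
    n_skipped = 0
    for r in records:
        if r.chs_grade is None or r.followup_wmh_volume_cm3 is None:
            n_skipped += 1
            continue
        baseline = grade_to_volume(map_, r.chs_grade)
        rows.append({
            "id": r.id,
            "baseline_grade": r.chs_grade,
            "baseline_volume_cm3": baseline,
            "followup_volume_cm3": r.followup_wmh_volume_cm3,
            "volume_change_cm3": r.followup_wmh_volume_cm3 - baseline,
        })
    return (pd.DataFrame(rows, columns=["id", "baseline_grade",
                                        "baseline_volume_cm3",
                                        "followup_volume_cm3",
                                        "volume_change_cm3"]),
            n_skipped)
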