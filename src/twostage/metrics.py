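"""Screening performance of a prescreen score threshold against WMH status.

Collapsing the 4x2 severity-by-WMH crosstab at a score threshold yields a
2x2 confusion table: prescreen-positive participants with significant WMH are
true positives, positives without it false positives. Sensitivity (TP rate)
and the FP rate explain why cheap, permissive thresholds need many MRI scans;
PPV is by construction the ``p_wmh_given_positive`` the recruitment
calculator uses for the same range.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CrossTab
from .recruitment import SEVERITY_RANGES

__all__ = ["MetricReport", "metrics_at_threshold", "metrics_at_range",
           "threshold_sweep"]


def _safe_ratio(num: int, den: int) -> float | None:
    """A rate, or ``None`` when the denominator is empty (explicitly undefined)."""
    return num / den if den else None


@dataclass(frozen=True)
class MetricReport:
    """2x2 screening counts and the derived rates for one score threshold.

    Rates are held at full precision; ``None`` marks a rate whose denominator
    is empty. Round only at presentation.
    """

    threshold: int
    range_label: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def tp_rate(self) -> float | None:
        """Sensitivity: TP / (TP + FN)."""
        return _safe_ratio(self.tp, self.tp + self.fn)

    @property
    def fp_rate(self) -> float | None:
        """FP / (FP + TN)."""
        return _safe_ratio(self.fp, self.fp + self.tn)

    @property
    def ppv(self) -> float | None:
        return _safe_ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _safe_ratio(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "range": self.range_label,
            "threshold": self.threshold,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "tp_rate": self.tp_rate, "fp_rate": self.fp_rate,
            "ppv": self.ppv, "npv": self.npv,
        }


def metrics_at_threshold(crosstab: CrossTab, threshold: int,
                         range_label: str | None = None) -> MetricReport:
    """Screening metrics treating score >= ``threshold`` as prescreen-positive.

    ``threshold=0`` accepts everyone (TP rate and FP rate both 1 whenever
    defined).
    """
    if not 0 <= threshold <= 3:
        raise ValueError(f"threshold must lie in 0..3, got {threshold}")
    in_total, in_sig = crosstab.in_range(threshold)
    total_sig = crosstab.n_significant
    total = crosstab.total
    tp = in_sig
    fp = in_total - in_sig
    fn = total_sig - in_sig
    tn = (total - total_sig) - fp
    return MetricReport(threshold=threshold,
                        range_label=range_label or f"score>={threshold}",
                        tp=tp, fp=fp, fn=fn, tn=tn)


def metrics_at_range(crosstab: CrossTab, severity_range: str) -> MetricReport:
    """Metrics for a named severity range (severe / moderate_severe / mild_severe)."""
    if severity_range not in SEVERITY_RANGES:
        raise ValueError(f"unknown severity range {severity_range!r}")
    return metrics_at_threshold(crosstab, SEVERITY_RANGES[severity_range],
                                range_label=severity_range)


def threshold_sweep(crosstab: CrossTab) -> pd.DataFrame:
    """Metrics at every threshold 0..3, one row per threshold (ROC-style table)."""
    return pd.DataFrame([metrics_at_threshold(crosstab, t).to_dict()
                         for t in range(4)])
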