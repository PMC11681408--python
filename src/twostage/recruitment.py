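"""Recruitment sample-size and cost calculator for one- and two-stage designs.

The design problem: a trial needs ``target_n`` enrollees with significant
white-matter-hyperintensity (WMH) burden, but WMH status is only observable
on an expensive MRI. In the MRI-only design everyone recruited is scanned, so
the recruitment size is ``target_n`` divided by the population prevalence of
significant WMH. In the two-stage design a cheap prescreen (retinal
photograph at ~$32.50, or clinical chart review at $0) selects a
score-positive subgroup, and only that subgroup is scanned:

    n_prescreen = ceil( target_n / (p_prescreen * p_wmh_given_positive * (1 - attrition)) )
    n_mri       = ceil( p_prescreen * n_prescreen )

where ``p_prescreen`` is the fraction of the population scoring in the chosen
severity range and ``p_wmh_given_positive`` the fraction of those with
significant WMH on MRI. Rounding is ceiling at both stages — the conservative
rule that never under-recruits. All currency is held in integer cents so cost
totals are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

from .cohort import CrossTab

__all__ = [
    "DesignInputs",
    "DesignEstimate",
    "TwoGroupEstimate",
    "InfeasibleDesignError",
    "SEVERITY_RANGES",
    "DEFAULT_TARGET_N",
    "DEFAULT_COST_PRESCREEN_USD",
    "DEFAULT_COST_MRI_USD",
    "usd_to_cents",
    "round_proportion",
    "mri_only_design",
    "two_stage_design",
    "apply_attrition",
    "design_from_crosstab",
    "two_group_design",
    "cost_of_stages",
]

DEFAULT_TARGET_N = 646
DEFAULT_COST_PRESCREEN_USD = 32.50
DEFAULT_COST_MRI_USD = 650.0

#: Severity range label -> minimum positive score.
SEVERITY_RANGES = {"severe": 3, "moderate_severe": 2, "mild_severe": 1}


class InfeasibleDesignError(ValueError):
    """The requested design cannot yield any eligible participants."""


def usd_to_cents(usd: float | str | Decimal) -> int:
    """Convert a dollar amount to integer cents, exactly."""
    cents = (Decimal(str(usd)) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    return int(cents)


def round_proportion(p: float, mode: Literal["exact", "paper"] = "exact") -> float:
    """Apply the proportion precision policy.

    ``"exact"`` uses the full-precision value. ``"paper"`` rounds to two
    significant figures, the precision at which summary proportions are
    conventionally printed (e.g. 94/1311 = 0.0717 -> 0.072; 16/94 = 0.170 ->
    0.17), so published tables can be reproduced from their printed numbers.
    """
    if mode == "exact":
        return p
    if mode != "paper":
        raise ValueError(f"unknown precision mode {mode!r}")
    if p == 0:
        return 0.0
    d = Decimal(str(p))
    shift = d.adjusted()  # exponent of the leading significant digit
    quantum = Decimal(1).scaleb(shift - 1)  # keep two significant digits
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DesignInputs:
    """Parameters of one two-stage recruitment design."""

    target_n: int = DEFAULT_TARGET_N
    p_prescreen: float = 1.0
    p_wmh_given_positive: float = 0.099
    cost_prescreen_usd: float = DEFAULT_COST_PRESCREEN_USD
    cost_mri_usd: float = DEFAULT_COST_MRI_USD
    attrition: float = 0.0

    def __post_init__(self) -> None:
        if self.target_n <= 0:
            raise ValueError(f"target_n must be positive, got {self.target_n}")
        for name in ("p_prescreen", "p_wmh_given_positive"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise InfeasibleDesignError(
                    f"{name} must lie in (0, 1], got {p}")
        for name in ("cost_prescreen_usd", "cost_mri_usd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.attrition < 1:
            raise ValueError(f"attrition must lie in [0, 1), got {self.attrition}")


@dataclass(frozen=True)
class DesignEstimate:
    """Per-stage sample sizes and costs for one recruitment design."""

    n_prescreen: int
    cost_prescreen_cents: int
    n_mri: int
    cost_mri_cents: int
    expected_eligible: float
    inputs: DesignInputs

    @property
    def cost_total_cents(self) -> int:
        return self.cost_prescreen_cents + self.cost_mri_cents

    @property
    def cost_prescreen_usd(self) -> float:
        return self.cost_prescreen_cents / 100

    @property
    def cost_mri_usd(self) -> float:
        return self.cost_mri_cents / 100

    @property
    def cost_total_usd(self) -> float:
        return self.cost_total_cents / 100

    def to_dict(self) -> dict:
        return {
            "target_n": self.inputs.target_n,
            "p_prescreen": self.inputs.p_prescreen,
            "p_wmh_given_positive": self.inputs.p_wmh_given_positive,
            "attrition": self.inputs.attrition,
            "n_prescreen": self.n_prescreen,
            "cost_prescreen_cents": self.cost_prescreen_cents,
            "n_mri": self.n_mri,
            "cost_mri_cents": self.cost_mri_cents,
            "cost_total_cents": self.cost_total_cents,
            "expected_eligible": self.expected_eligible,
        }


def two_stage_design(inputs: DesignInputs) -> DesignEstimate:
    """Compute the two-stage prescreen -> MRI design estimate.

    The proportion with significant WMH among all recruited is
    ``p_prescreen * p_wmh_given_positive``; its inverse (deflated further by
    attrition) times the trial target gives the prescreening sample, whose
    prescreen-positive fraction proceeds to MRI. Ceiling at both stages.
    """
    yield_fraction = (inputs.p_prescreen * inputs.p_wmh_given_positive
                      * (1 - inputs.attrition))
    if yield_fraction <= 0:
        raise InfeasibleDesignError("expected eligible fraction is zero")
    n_prescreen = math.ceil(inputs.target_n / yield_fraction)
    n_mri = math.ceil(inputs.p_prescreen * n_prescreen)
    return DesignEstimate(
        n_prescreen=n_prescreen,
        cost_prescreen_cents=n_prescreen * usd_to_cents(inputs.cost_prescreen_usd),
        n_mri=n_mri,
        cost_mri_cents=n_mri * usd_to_cents(inputs.cost_mri_usd),
        expected_eligible=n_prescreen * yield_fraction,
        inputs=inputs,
    )


def mri_only_design(
    target_n: int = DEFAULT_TARGET_N,
    p_wmh: float = 0.099,
    cost_mri_usd: float = DEFAULT_COST_MRI_USD,
    *,
    attrition: float = 0.0,
) -> DesignEstimate:
    """Single-stage design: scan everyone recruited.

    Equivalent to a two-stage design with a free prescreen that everyone
    passes (``p_prescreen = 1``, prescreen cost 0).
    """
    return two_stage_design(DesignInputs(
        target_n=target_n, p_prescreen=1.0, p_wmh_given_positive=p_wmh,
        cost_prescreen_usd=0.0, cost_mri_usd=cost_mri_usd, attrition=attrition,
    ))


def apply_attrition(inputs: DesignInputs,
                    rates: Sequence[float]) -> list[DesignEstimate]:
    """Re-estimate the design under each attrition rate.

    Attrition multiplies the eligible-yield fraction by the retention
    proportion (1 - rate) before the trial target is divided by it, so a 30%
    attrition rate inflates the prescreening sample by 1/0.7.
    """
    estimates = []
    for rate in rates:
        if not 0 <= rate < 1:
            raise ValueError(f"attrition rate must lie in [0, 1), got {rate}")
        estimates.append(two_stage_design(replace(inputs, attrition=rate)))
    return estimates


def design_from_crosstab(
    crosstab: CrossTab,
    severity_range: str,
    *,
    target_n: int = DEFAULT_TARGET_N,
    cost_prescreen_usd: float = DEFAULT_COST_PRESCREEN_USD,
    cost_mri_usd: float = DEFAULT_COST_MRI_USD,
    attrition: float = 0.0,
    precision: Literal["exact", "paper"] = "exact",
) -> DesignEstimate:
    """Derive the design proportions from a severity x WMH crosstab.

    ``p_prescreen`` is the fraction of the tabulated cohort scoring in the
    severity range (severe: score 3; moderate-severe: 2-3; mild-severe: 1-3)
    and ``p_wmh_given_positive`` the significant-WMH fraction within that
    range. ``precision="paper"`` rounds both to two significant figures
    before use (see :func:`round_proportion`).
    """
    if severity_range not in SEVERITY_RANGES:
        raise ValueError(f"unknown severity range {severity_range!r}; "
                         f"expected one of {sorted(SEVERITY_RANGES)}")
    if crosstab.total == 0:
        raise InfeasibleDesignError("empty crosstab")
    in_range, significant = crosstab.in_range(SEVERITY_RANGES[severity_range])
    if in_range == 0 or significant == 0:
        raise InfeasibleDesignError(
            f"severity range {severity_range!r} has no eligible participants")
    p_prescreen = round_proportion(in_range / crosstab.total, precision)
    p_wmh = round_proportion(significant / in_range, precision)
    return two_stage_design(DesignInputs(
        target_n=target_n, p_prescreen=p_prescreen, p_wmh_given_positive=p_wmh,
        cost_prescreen_usd=cost_prescreen_usd, cost_mri_usd=cost_mri_usd,
        attrition=attrition,
    ))


@dataclass(frozen=True)
class TwoGroupEstimate:
    """Balanced two-group design: per-group estimates plus combined totals.

    Each group receives its own two-stage computation toward its own
    MRI-eligible enrollment target; the group with the lower prescreen
    prevalence necessarily requires the larger prescreening sample, which is
    how equal representation at the MRI stage is maintained.
    """

    groups: dict[str, DesignEstimate]

    @property
    def n_prescreen_total(self) -> int:
        return sum(e.n_prescreen for e in self.groups.values())

    @property
    def n_mri_total(self) -> int:
        return sum(e.n_mri for e in self.groups.values())

    @property
    def cost_total_cents(self) -> int:
        return sum(e.cost_total_cents for e in self.groups.values())


def two_group_design(
    targets: dict[str, int],
    p_prescreen: dict[str, float],
    p_wmh_given_positive: dict[str, float],
    *,
    cost_prescreen_usd: float = DEFAULT_COST_PRESCREEN_USD,
    cost_mri_usd: float = DEFAULT_COST_MRI_USD,
    attrition: float = 0.0,
) -> TwoGroupEstimate:
    """Two-stage design run separately for two groups (e.g. male vs female)."""
    keys = sorted(targets)
    if len(keys) != 2 or sorted(p_prescreen) != keys or \
            sorted(p_wmh_given_positive) != keys:
        raise ValueError("exactly two groups with matching keys are required")
    groups = {
        k: two_stage_design(DesignInputs(
            target_n=targets[k], p_prescreen=p_prescreen[k],
            p_wmh_given_positive=p_wmh_given_positive[k],
            cost_prescreen_usd=cost_prescreen_usd, cost_mri_usd=cost_mri_usd,
            attrition=attrition,
        ))
        for k in keys
    }
    return TwoGroupEstimate(groups=groups)


def cost_of_stages(n_prescreen: int, n_mri: int,
                   cost_prescreen_usd: float = DEFAULT_COST_PRESCREEN_USD,
                   cost_mri_usd: float = DEFAULT_COST_MRI_USD) -> int:
    """Total cost in cents of given stage sizes (for externally fixed designs)."""
    return (n_prescreen * usd_to_cents(cost_prescreen_usd)
            + n_mri * usd_to_cents(cost_mri_usd))
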