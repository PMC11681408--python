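"""Synthetic cohort generator emulating the published joint structure.

The restricted cohort behind the published summary tables cannot be
redistributed, so this module simulates cohorts with the same marginal
structure: significant-WMH status drawn at the published prevalence (9.9% in
late midlife) and each binary prescreen feature drawn from its published
WMH-conditional prevalence. Features are conditionally independent given WMH
status by default — the published tables give only margins, not
co-occurrence — with an optional exchangeable Gaussian-copula correlation.
Baseline CHS grade is assigned consistently with WMH status (grade > 2 iff
significant), baseline volume through a fixed reference quadratic grade map,
and follow-up volume adds a severity-dependent 10-year progression effect
plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from . import scoring
from .cohort import ParticipantRecord, cross_tabulate
from .recruitment import (
    DEFAULT_COST_MRI_USD,
    DEFAULT_COST_PRESCREEN_USD,
    DEFAULT_TARGET_N,
    SEVERITY_RANGES,
    DesignEstimate,
    DesignInputs,
    design_from_crosstab,
    two_stage_design,
)
from .reference import MIDLIFE_FEATURE_PREVALENCE

__all__ = [
    "SyntheticCohortConfig",
    "RecoveryResult",
    "REFERENCE_GRADE_MAP_COEFFICIENTS",
    "simulate_cohort",
    "analytic_category_distribution",
    "analytic_design_proportions",
    "recover_design",
    "simulate_grade_volume_pairs",
    "noise_sd_for_target_r2",
]

#: Reference grade -> volume quadratic used when simulating volumes
#: (chosen so grade > 2 corresponds exactly to volume >= 9.3 cm^3).
REFERENCE_GRADE_MAP_COEFFICIENTS = (0.8, 1.0, 0.65)

_GRADE_PROBS = {
    # within-status ordinal grade distributions (a free modelling choice;
    # only the status-consistency of the grade is identified by the margins)
    False: ((0, 1, 2), (0.35, 0.45, 0.20)),
    True: ((3, 4, 5), (0.60, 0.30, 0.10)),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Prevalences and effect sizes defining one simulated cohort.

    ``feature_prevalence`` maps each binary feature to
    ``(P(present | no/low WMH), P(present | significant WMH))``; defaults are
    the published late-midlife values. ``age_cutoff_years`` is the scoring
    age threshold the ``age_at_or_above_cutoff`` prevalences refer to.
    ``progression_effects_cm3`` gives the mean 10-year WMH volume increase per
    severity category of ``progression_score_kind``. The seed is mandatory:
    identical config + seed reproduces the cohort byte for byte.
    """

    n: int = 1311
    seed: int = 0
    p_wmh: float = 0.099
    feature_prevalence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(MIDLIFE_FEATURE_PREVALENCE))
    age_cutoff_years: float = 60.0
    feature_correlation: float = 0.0  # exchangeable copula correlation
    progression_score_kind: str = "clinical"
    progression_effects_cm3: Mapping[str, float] = field(
        default_factory=lambda: {"none": 1.0, "mild": 1.5,
                                 "moderate": 2.5, "severe": 4.0})
    progression_noise_sd_cm3: float = 2.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if not 0 <= self.p_wmh <= 1:
            raise ValueError(f"p_wmh must lie in [0, 1], got {self.p_wmh}")
        for f, (p0, p1) in self.feature_prevalence.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValueError(f"feature {f!r}: probabilities must lie in [0, 1]")
        if not -1 < self.feature_correlation < 1:
            raise ValueError("feature_correlation must lie in (-1, 1)")


def _correlated_bernoulli(rng: np.random.Generator, probs: np.ndarray,
                          rho: float) -> np.ndarray:
    """Row-wise Bernoulli draws with exchangeable Gaussian-copula correlation.

    ``probs`` has one column per feature; ``rho = 0`` reduces to independent
    draws. A one-factor construction (z_ij = sqrt(rho)*u_i + sqrt(1-rho)*e_ij)
    gives pairwise latent correlation rho.
    """
    n, k = probs.shape
    if rho == 0.0:
        return rng.random((n, k)) < probs
    common = rng.standard_normal((n, 1))
    z = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal((n, k))
    return stats.norm.cdf(z) < probs


def _grade_map_volume(grades: np.ndarray) -> np.ndarray:
    a0, a1, a2 = REFERENCE_GRADE_MAP_COEFFICIENTS
    return a0 + a1 * grades + a2 * grades ** 2


def simulate_cohort(config: SyntheticCohortConfig) -> list[ParticipantRecord]:
    """Draw a cohort of ``config.n`` participants.

    WMH status ~ Bernoulli(p_wmh); features from their status-conditional
    prevalences; age from status-conditional uniforms chosen so the
    age-at-or-above-cutoff indicator matches its configured prevalence;
    baseline CHS grade consistent with status; baseline volume through the
    reference grade map; follow-up volume adds the severity-category
    progression effect and Gaussian noise (clipped at zero).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    significant = rng.random(n) < config.p_wmh

    feats = list(config.feature_prevalence)
    prev = np.array([config.feature_prevalence[f] for f in feats])  # (k, 2)
    probs = prev[:, significant.astype(int)].T  # (n, k)
    draws = _correlated_bernoulli(rng, probs, config.feature_correlation)
    feature_values = dict(zip(feats, draws.T))

    # age: indicator already drawn; place the age on the matching side of the cutoff
    cutoff = config.age_cutoff_years
    age_hi = feature_values.pop("age_at_or_above_cutoff")
    ages = np.where(age_hi,
                    cutoff + rng.uniform(0.0, 10.0, n),
                    cutoff - rng.uniform(0.5, 10.0, n))
    ages = np.maximum(ages, 45.0)

    grades = np.empty(n, dtype=int)
    for status, (support, weights) in _GRADE_PROBS.items():
        mask = significant == status
        grades[mask] = rng.choice(support, size=int(mask.sum()), p=weights)
    volumes = _grade_map_volume(grades)

    records = []
    for i in range(n):
        records.append(ParticipantRecord(
            id=f"S{i + 1:06d}",
            age_years=float(round(ages[i], 1)),
            retinopathy=bool(feature_values["retinopathy"][i]),
            av_nicking=bool(feature_values["av_nicking"][i]),
            focal_narrowing=bool(feature_values["focal_narrowing"][i]),
            generalized_narrowing=bool(feature_values["generalized_narrowing"][i]),
            hypertension=bool(feature_values["hypertension"][i]),
            diabetes=bool(feature_values["diabetes"][i]),
            chs_grade=int(grades[i]),
            wmh_volume_cm3=float(round(volumes[i], 3)),
        ))

    # follow-up volume: severity-dependent 10-year progression
    effects = config.progression_effects_cm3
    noise = rng.normal(0.0, config.progression_noise_sd_cm3, n)
    for i, r in enumerate(records):
        category = scoring.score(r, config.progression_score_kind).category
        follow = volumes[i] + effects[category] + noise[i]
        records[i] = replace(r, followup_wmh_volume_cm3=float(round(max(0.0, follow), 3)))
    return records


def _enumerate_category_probs(features: Sequence[str],
                              point_of: Mapping[str, int],
                              probs: Mapping[str, float],
                              max_score: int = 3) -> np.ndarray:
    """P(severity category) for independent Bernoulli features, by enumeration."""
    out = np.zeros(max_score + 1)
    k = len(features)
    for mask in range(1 << k):
        p = 1.0
        total = 0
        for j, f in enumerate(features):
            if mask >> j & 1:
                p *= probs[f]
                total += point_of[f]
            else:
                p *= 1 - probs[f]
        out[min(max_score, total)] += p
    return out


def analytic_category_distribution(config: SyntheticCohortConfig,
                                   kind: str) -> dict[bool, np.ndarray]:
    """Closed-form severity-category distribution implied by the config.

    Valid because the generator draws features conditionally independently
    given WMH status (``feature_correlation = 0``); returns
    ``{False: P(cat | no/low), True: P(cat | significant)}`` as length-4
    arrays over none/mild/moderate/severe.
    """
    if config.feature_correlation != 0.0:
        raise ValueError("closed form requires conditionally independent features")
    definition = scoring.ScoreDefinition(kind=kind)
    features = tuple(definition.feature_points)
    out = {}
    for status in (False, True):
        probs = {f: config.feature_prevalence[f][int(status)] for f in features}
        out[status] = _enumerate_category_probs(
            features, definition.feature_points, probs, definition.max_score)
    return out


def analytic_design_proportions(config: SyntheticCohortConfig, kind: str,
                                severity_range: str) -> tuple[float, float]:
    """(p_prescreen, p_wmh_given_positive) implied by the generator config."""
    threshold = SEVERITY_RANGES[severity_range]
    cat = analytic_category_distribution(config, kind)
    pos_given_no = cat[False][threshold:].sum()
    pos_given_sig = cat[True][threshold:].sum()
    p_pos = (1 - config.p_wmh) * pos_given_no + config.p_wmh * pos_given_sig
    if p_pos == 0:
        raise ValueError(f"severity range {severity_range!r} has probability zero")
    p_wmh_given_pos = config.p_wmh * pos_given_sig / p_pos
    return float(p_pos), float(p_wmh_given_pos)


@dataclass(frozen=True)
class RecoveryResult:
    """End-to-end generator validation: pipeline estimate vs analytic truth."""

    pipeline: DesignEstimate
    analytic: DesignEstimate

    @property
    def relative_error(self) -> float:
        return abs(self.pipeline.n_prescreen - self.analytic.n_prescreen) \
            / self.analytic.n_prescreen


def recover_design(
    config: SyntheticCohortConfig,
    n_large: int,
    severity_range: str,
    *,
    target_n: int = DEFAULT_TARGET_N,
    cost_prescreen_usd: float = DEFAULT_COST_PRESCREEN_USD,
    cost_mri_usd: float = DEFAULT_COST_MRI_USD,
) -> RecoveryResult:
    """Simulate a large cohort, run the full pipeline, compare with the closed form.

    The pipeline path is cohort -> scores -> crosstab -> design (exact
    precision); the analytic path plugs the config's implied proportions into
    the same design formula. Requires ``n_large >= 1e5`` so Monte-Carlo error
    in the proportions stays well under the 5% validation tolerance.
    """
    if n_large < 100_000:
        raise ValueError(f"n_large must be >= 100000 for recovery, got {n_large}")
    kind = config.progression_score_kind
    cohort = simulate_cohort(replace(config, n=n_large))
    crosstab = cross_tabulate(cohort, kind)
    pipeline = design_from_crosstab(
        crosstab, severity_range, target_n=target_n,
        cost_prescreen_usd=cost_prescreen_usd, cost_mri_usd=cost_mri_usd,
        precision="exact")
    p_pos, p_wmh_pos = analytic_design_proportions(config, kind, severity_range)
    analytic = two_stage_design(DesignInputs(
        target_n=target_n, p_prescreen=p_pos, p_wmh_given_positive=p_wmh_pos,
        cost_prescreen_usd=cost_prescreen_usd, cost_mri_usd=cost_mri_usd))
    return RecoveryResult(pipeline=pipeline, analytic=analytic)


def simulate_grade_volume_pairs(
    n: int, seed: int,
    coefficients: tuple[float, float, float] = REFERENCE_GRADE_MAP_COEFFICIENTS,
    noise_sd: float = 0.0,
    grade_range: tuple[int, int] = (0, 5),
) -> list[tuple[int, float]]:
    """(grade, volume) pairs from a quadratic plus Gaussian noise, volumes >= 0."""
    rng = np.random.default_rng(seed)
    a0, a1, a2 = coefficients
    grades = rng.integers(grade_range[0], grade_range[1] + 1, size=n)
    volumes = a0 + a1 * grades + a2 * grades ** 2 + rng.normal(0, noise_sd, n)
    return [(int(g), float(max(0.0, v))) for g, v in zip(grades, volumes)]


def noise_sd_for_target_r2(
    target_r2: float,
    coefficients: tuple[float, float, float] = REFERENCE_GRADE_MAP_COEFFICIENTS,
    grade_range: tuple[int, int] = (0, 5),
) -> float:
    """Noise sigma giving a fit with expected R^2 = target, for uniform grades.

    R^2 = var(signal) / (var(signal) + sigma^2), so
    sigma = sqrt(var(signal) * (1 - R^2) / R^2).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target R^2 must lie in (0, 1)")
    a0, a1, a2 = coefficients
    grades = np.arange(grade_range[0], grade_range[1] + 1, dtype=float)
    signal = a0 + a1 * grades + a2 * grades ** 2
    var_signal = signal.var()
    return float(np.sqrt(var_signal * (1 - target_r2) / target_r2))
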