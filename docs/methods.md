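# Methods

## The design problem

A phase-2 trial of white-matter-hyperintensity (WMH) progression must enroll
participants who already carry significant WMH burden, but WMH status is only
observable on MRI (~$650 per research scan). In late midlife only ~9.9% of a
community cohort carries significant burden (CHS grade > 2), so MRI-only
screening scans ~10 people per enrollee. The calculator quantifies the
alternative: a cheap first-stage prescreen — a retinal fundus photograph
(~$32.50) scored for microvascular signs, or clinical chart features at $0 —
selects a score-positive subgroup enriched for WMH, and only that subgroup is
scanned.

With `p_pre` the fraction of the population scoring in the chosen severity
range and `p_wmh|+` the significant-WMH fraction among them, a trial target
`T` and attrition rate `a`:

```
n_prescreen = ceil( T / (p_pre · p_wmh|+ · (1 − a)) )
n_mri       = ceil( p_pre · n_prescreen )
cost        = n_prescreen · c_pre + n_mri · c_mri
```

The MRI-only design is the degenerate case `p_pre = 1, c_pre = 0`, which the
implementation reduces to exactly (property-tested). The balanced two-group
option runs the same computation per group toward per-group MRI-stage
targets; the group with lower prescreen prevalence automatically receives the
larger prescreening sample.

## Scoring systems

Unweighted scores are integer point sums truncated at 3 and graded
none/mild/moderate/severe for 0/1/2/3:

* retinal: retinopathy = 3 points (end-stage retinal disease; the other
  signs usually precede it), arteriovenous nicking, focal arteriolar
  narrowing, generalized arteriolar narrowing = 1 each;
* clinical: age at/above the cutoff, hypertension, diabetes = 1 each;
* combined: clinical + retinal, truncated at 3.

The age cutoff defaults to 60 years in late midlife and 78 in late life (the
follow-up visit sits ~18 years after baseline). The cutoff is compared with
`>=` by default; published descriptions alternate between "older than 60"
and "age >= 60", so the comparison operator is configurable
(`age_comparison="gt"`). At integer-valued ages the choice only moves
exactly-60-year-olds.

### Weighted variant

The weighted scores replace the fixed point table with data-driven weights:
an L2-regularized logistic regression of significant-WMH status on the
standardized binary predictors of one predictor set (fitted per set, not
jointly). "Normalized weights" are absolute coefficients scaled to mean 1
across the set — consistent with published weights clustering around 1 — and
the maximum attainable weighted sum is rescaled to 3 so weighted and
unweighted scores share a scale. Severity binning rounds the rescaled score
half-up to the nearest integer in 0..3. Regularization strength is a fixed
λ = 1.0 (no cross-validation) so the fit is deterministic; both λ and the
binning are config-overridable. The exact published normalization/binning
procedure is not public, so this scheme is this package's documented
interpretation, validated by its properties (association-strength ordering
is reflected in weight ordering; monotonicity; cap attainment) rather than
by coefficient reproduction — the original participant-level data are
restricted, so the published weight values themselves are out of reach.

A note on null behaviour: when no feature is associated with the outcome,
the normalized weights are ratios of |coefficient| noise, and the largest
weight exceeds twice the mean in roughly a third of replicates (for k = 4
roughly-independent coefficients this is what the half-normal ratio
distribution predicts). Null tests therefore assert boundedness (weights in
[0, k], mean exactly 1) and that no feature systematically wins the
max-weight slot, not a small max/mean ratio.

## Rounding and precision policy

The published tables are reproducible only under two specific conventions,
both adopted here:

* **Ceiling at both stages.** `n_prescreen` and `n_mri` are rounded up to
  whole participants (3800.02 → 3801, 2808.75 → 2809). Ceiling is the only
  rule consistent with every published row and is conservative — the
  pre-rounding expected eligible count already meets the target, and
  rounding up only adds margin.
* **Two-significant-figure proportions (`precision="paper"`).** Summary
  proportions are printed at two significant figures (94/1311 → 0.072,
  16/94 → 0.17), and the published sample sizes derive from the printed
  values (646/0.099 → 6526, not 646/(130/1311) → 6515). Default mode is
  `"exact"` (full-precision count ratios); `"paper"` mode exists to
  reproduce printed tables and for comparability with them.

One published row (combined clinical-retinal, mild–severe) is internally
inconsistent: its overall columns (6751 participants, $4,037,508 total)
match this implementation's output exactly (we compute $4,037,507.50), but
its printed stage columns (6750 prescreened, 5873 scanned) disagree with its
own overall columns by one participant. The package reproduces the overall
figures and makes no guess about the stage-column discrepancy.

Currency is held in integer cents; stage costs are `n × unit cost` with no
floating-point drift, converted to dollars only at presentation.

### A ceiling-slack caveat on monotonicity

Total cost is exactly non-increasing in `p_wmh|+`. In `p_pre` the
*continuous* (pre-rounding) cost is non-increasing, but the rounded cost can
rise by at most one MRI scan: `n_mri = ceil(p_pre · ceil(T/(p_pre·p_wmh|+)))`
and the inner ceiling's slack can tip the outer one (e.g. T = 646,
p_wmh|+ = 0.1: p_pre 0.5 → 6460 scans, p_pre 0.6 → 6461). Tests assert
monotonicity with exactly this one-scan slack.

## Screening metrics

Collapsing the 4×2 severity-by-WMH crosstab at a threshold yields the 2×2
confusion table; sensitivity (TP rate), FP rate, PPV and NPV follow. Rates
are held at full precision with two-decimal presentation rounding, and the
counts are always carried so nothing is lost to rounding. A rate with an
empty denominator is `None`, never NaN. PPV at a range is definitionally
identical to the `p_wmh|+` the design module derives from the same crosstab
(exact identity, tested). Of note, the published mild–severe combined-score
sensitivity is printed as 0.99 while the published counts give 128/130 =
0.98; this package reports the count-derived value. Threshold sweeps (0..3)
are provided as a table; no AUC is computed.

## CHS-grade ↔ volume mapping

Visually graded (CHS 0–9 ordinal) and volumetric (cm³, standardized to a
1500 cm³ intracranial volume) WMH measures are linked by an OLS quadratic
`volume = a0 + a1·g + a2·g²`, fitted where both coexist (≥ 3 distinct grades
required). Predictions are clipped at 0; extrapolation beyond the fitted
grade range warns; a non-monotone fitted parabola triggers a diagnostics
warning. The published conversion's coefficients are not public, so the
package ships the fitting routine plus a JSON slot for externally supplied
coefficients; only the grade→volume direction is implemented (the direction
progression analysis needs). Without a map, the significant-burden
volumetric cutoff defaults to the published late-life equivalence of
9.3 cm³; with a map, the equivalent cutoff is the predicted volume at the
smallest significant grade (cutoff + 1). Volumes are assumed
pre-standardized; no re-standardization is performed.

## Longitudinal comparison

Ten-year volume change (follow-up volume minus mapped baseline grade) is
compared across severity categories with a tie-corrected Kruskal–Wallis test
(chi-square reference). The planned post hoc contrasts compare each elevated
category against "none" by two-sided rank-sum tests with Bonferroni
adjustment over the contrasts performed; the published analysis does not
name its post hoc method or reference structure, so this default is an
interpretation and an all-pairwise variant is provided. An all-identical
sample is reported as the degenerate H = 0, p = 1 with a flag rather than an
error. Type-I error calibration (4 null groups × 50, α = 0.05, 1000
replicates) is asserted to lie in [0.035, 0.065].

## Synthetic cohort generator

The generator emulates the published late-midlife joint structure: WMH
status ~ Bernoulli(0.099); each binary feature drawn from its published
status-conditional prevalence (e.g. retinopathy 17% | significant vs
6.2% | no/low; hypertension 66% vs 45%; age ≥ 60 82% vs 63%); age uniform
within 10 years on the side of the cutoff its indicator selects; CHS grade
ordinal and consistent with status (grades {3,4,5} with probabilities
{0.6, 0.3, 0.1} when significant, {0,1,2} with {0.35, 0.45, 0.2} otherwise —
a free choice, since only status-consistency is identified by the published
margins); baseline volume through a fixed reference quadratic
(0.8 + 1.0·g + 0.65·g²), chosen so grade > 2 coincides exactly with volume
≥ 9.3 cm³; follow-up volume adds a severity-category progression effect
(defaults 1.0/1.5/2.5/4.0 cm³ for none/mild/moderate/severe — magnitudes in
the range reported for 10-year progression in community cohorts) plus
N(0, 2.0 cm³) noise, clipped at zero.

Features are conditionally independent given WMH status — the published
tables give margins only, no co-occurrence — with an optional exchangeable
Gaussian-copula correlation (one-factor construction; margins are preserved,
tested). Because of conditional independence, the implied severity-category
distribution has a closed form by enumerating feature combinations; this
closed form is the oracle for end-to-end recovery tests
(`recover_design`: pipeline estimate within 5% of the analytic value at
n ≥ 10⁵). Passing these tests shows the pipeline is self-consistent at the
published margins; it does not show that real cohorts are conditionally
independent, and real feature co-occurrence (e.g. hypertension–retinopathy)
would move the combined-score proportions.

## Problem sizes and numerical choices

Tests use cohorts of 1311 (the published analytic sample size) and 10⁵ for
margin-recovery checks; weighted-model property tests use N = 5000 with 10–20
seeded replicates; the Kruskal–Wallis calibration uses 1000 replicates in
the end-to-end suite and 300 in the unit suite. Random draws all flow
through `numpy.random.default_rng` with explicit seeds; hypothesis profiles
are derandomized. Binomial tolerances are 3·√(np(1−p)).

## Known limitations

* The weighted-score normalization/binning is an interpretation (see above);
  published weight values are unverifiable without the restricted data.
* The generator's conditional-independence default understates real feature
  clustering; the copula hook is a coarse remedy.
* No trial power calculation: the target N = 646 is an input taken from
  prior work, not recomputed.
* No cost discounting, site modelling, per-visit breakdowns, or
  identification/contact costs; cost estimates are US-specific.
* No confidence intervals on screening rates.
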