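"""Sample-size and cost arithmetic for MRI-only and two-stage designs."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from twostage.recruitment import (
    DesignInputs,
    InfeasibleDesignError,
    apply_attrition,
    design_from_crosstab,
    mri_only_design,
    round_proportion,
    two_group_design,
    two_stage_design,
    usd_to_cents,
)
from twostage.reference import MIDLIFE_CROSSTABS

valid_inputs = st.builds(
    DesignInputs,
    target_n=st.integers(min_value=1, max_value=5000),
    p_prescreen=st.floats(min_value=0.001, max_value=1.0),
    p_wmh_given_positive=st.floats(min_value=0.001, max_value=1.0),
    cost_prescreen_usd=st.decimals(min_value=0, max_value=1000,
                                   places=2).map(float),
    cost_mri_usd=st.decimals(min_value=0, max_value=5000, places=2).map(float),
    attrition=st.floats(min_value=0.0, max_value=0.9),
)


class TestMriOnly:
    def test_midlife_published_numbers(self):
        est = mri_only_design(646, 0.099, 650)
        assert est.n_mri == 6526
        assert est.cost_total_usd == 4_241_900

    def test_trivial_full_prevalence(self):
        est = mri_only_design(10, 1.0, 650)
        assert (est.n_mri, est.cost_total_usd) == (10, 6500)

    def test_late_life_published_numbers(self):
        est = mri_only_design(646, 0.60, 650)
        assert est.n_mri == 1077
        assert est.cost_total_usd == 700_050

    def test_zero_prevalence_is_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            mri_only_design(646, 0.0, 650)


class TestTwoStage:
    @pytest.mark.parametrize(
        "p_pre,p_wmh,cost_pre,n_pre,cost_pre_usd,n_mri,cost_mri_usd,total_usd",
        [
            (0.075, 0.23, 32.50, 37_450, 1_217_125, 2_809, 1_825_850, 3_042_975),
            (0.072, 0.17, 0.0, 52_778, 0, 3_801, 2_470_650, 2_470_650),
            (0.28, 0.17, 32.50, 13_572, 441_090, 3_801, 2_470_650, 2_911_740),
        ],
        ids=["retinal-severe", "clinical-severe", "combined-severe"],
    )
    def test_published_severe_rows(self, p_pre, p_wmh, cost_pre, n_pre,
                                   cost_pre_usd, n_mri, cost_mri_usd, total_usd):
        est = two_stage_design(DesignInputs(
            target_n=646, p_prescreen=p_pre, p_wmh_given_positive=p_wmh,
            cost_prescreen_usd=cost_pre, cost_mri_usd=650))
        assert est.n_prescreen == n_pre
        assert est.cost_prescreen_usd == cost_pre_usd
        assert est.n_mri == n_mri
        assert est.cost_mri_usd == cost_mri_usd
        assert est.cost_total_usd == total_usd

    def test_degenerate_prescreen_reduces_to_mri_only(self):
        two = two_stage_design(DesignInputs(
            target_n=646, p_prescreen=1.0, p_wmh_given_positive=0.099,
            cost_prescreen_usd=0.0, cost_mri_usd=650))
        one = mri_only_design(646, 0.099, 650)
        assert two.n_mri == one.n_mri
        assert two.cost_total_cents == one.cost_total_cents

    def test_zero_proportion_is_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            DesignInputs(p_prescreen=0.0, p_wmh_given_positive=0.2)

    def test_attrition_of_one_is_rejected(self):
        with pytest.raises(ValueError):
            DesignInputs(p_prescreen=0.5, p_wmh_given_positive=0.2, attrition=1.0)


@given(valid_inputs)
def test_staged_computation_matches_one_line_oracle(inputs):
    """The staged path equals a direct brute-force formula evaluation."""
    est = two_stage_design(inputs)
    n_pre = math.ceil(
        inputs.target_n
        / (inputs.p_prescreen * inputs.p_wmh_given_positive
           * (1 - inputs.attrition)))
    n_mri = math.ceil(inputs.p_prescreen * n_pre)
    assert est.n_prescreen == n_pre
    assert est.n_mri == n_mri
    assert est.cost_total_cents == (
        n_pre * usd_to_cents(inputs.cost_prescreen_usd)
        + n_mri * usd_to_cents(inputs.cost_mri_usd))


@given(valid_inputs)
def test_expected_eligible_meets_target(inputs):
    """Ceiling feasibility: pre-rounding expected eligible count >= target."""
    est = two_stage_design(inputs)
    assert est.expected_eligible >= inputs.target_n * (1 - 1e-12)
    assert est.n_mri <= est.n_prescreen


@given(valid_inputs, st.floats(min_value=0.001, max_value=1.0))
def test_costs_monotone_in_each_proportion(inputs, p_new):
    """Raising either proportion never raises any stage size or the cost."""
    from dataclasses import replace

    base = two_stage_design(inputs)
    if p_new >= inputs.p_wmh_given_positive:
        better = two_stage_design(replace(inputs, p_wmh_given_positive=p_new))
        assert better.n_prescreen <= base.n_prescreen
        assert better.cost_total_cents <= base.cost_total_cents
    if p_new >= inputs.p_prescreen:
        better = two_stage_design(replace(inputs, p_prescreen=p_new))
        assert better.n_prescreen <= base.n_prescreen


class TestAttrition:
    def test_zero_rate_is_identity(self):
        inputs = DesignInputs(p_prescreen=0.075, p_wmh_given_positive=0.23)
        assert apply_attrition(inputs, [0.0])[0] == two_stage_design(inputs)

    def test_hand_oracle_mri_only_10_percent(self):
        inputs = DesignInputs(target_n=646, p_prescreen=1.0,
                              p_wmh_given_positive=0.099,
                              cost_prescreen_usd=0.0)
        est = apply_attrition(inputs, [0.10])[0]
        assert est.n_prescreen == math.ceil(646 / (0.099 * 0.9)) == 7251

    def test_hand_oracle_retinal_severe_30_percent(self):
        inputs = DesignInputs(target_n=646, p_prescreen=0.075,
                              p_wmh_given_positive=0.23)
        est = apply_attrition(inputs, [0.30])[0]
        assert est.n_prescreen == math.ceil(646 / (0.075 * 0.23) / 0.7) == 53_499

    def test_rate_of_one_rejected(self):
        with pytest.raises(ValueError):
            apply_attrition(DesignInputs(p_prescreen=0.5,
                                         p_wmh_given_positive=0.5), [1.0])

    @given(valid_inputs)
    def test_attrition_identity_with_inflated_target(self, inputs):
        """estimate(rate r) equals the rate-0 estimate at target/(1-r),
        to within one unit of ceiling slack."""
        from dataclasses import replace

        if inputs.attrition == 0:
            return
        direct = two_stage_design(inputs)
        inflated_target = inputs.target_n / (1 - inputs.attrition)
        inflated = math.ceil(
            inflated_target
            / (inputs.p_prescreen * inputs.p_wmh_given_positive))
        assert abs(direct.n_prescreen - inflated) <= 1


class TestDesignFromCrosstab:
    def test_clinical_severe_row_in_paper_precision(self):
        est = design_from_crosstab(MIDLIFE_CROSSTABS["clinical"], "severe",
                                   cost_prescreen_usd=0.0, precision="paper")
        assert est.n_prescreen == 52_778
        assert est.cost_total_usd == 2_470_650

    def test_retinal_severe_row_in_paper_precision(self):
        est = design_from_crosstab(MIDLIFE_CROSSTABS["retinal"], "severe",
                                   precision="paper")
        assert est.cost_total_usd == 3_042_975

    def test_exact_precision_uses_full_count_ratios(self):
        est = design_from_crosstab(MIDLIFE_CROSSTABS["retinal"], "severe",
                                   precision="exact")
        # 98/1311 and 23/98 full precision: 646 / (23/1311) = 36821.6 -> 36822
        assert est.n_prescreen == math.ceil(646 / (23 / 1311)) == 36_822

    def test_mild_severe_range_excludes_category_none(self):
        est = design_from_crosstab(MIDLIFE_CROSSTABS["clinical"], "mild_severe",
                                   precision="exact")
        assert est.inputs.p_prescreen == pytest.approx(1074 / 1311)

    def test_empty_range_is_infeasible(self):
        import numpy as np

        from twostage.cohort import CrossTab

        ct = CrossTab(counts=np.array([[5, 1], [3, 1], [0, 0], [0, 0]]))
        with pytest.raises(InfeasibleDesignError):
            design_from_crosstab(ct, "severe")


class TestRoundProportion:
    @pytest.mark.parametrize("value,expected", [
        (94 / 1311, 0.072), (16 / 94, 0.17), (130 / 1311, 0.099),
        (98 / 1311, 0.075), (1074 / 1311, 0.82), (0.5, 0.5),
    ])
    def test_paper_mode_keeps_two_significant_figures(self, value, expected):
        assert round_proportion(value, "paper") == expected

    def test_exact_mode_is_identity(self):
        assert round_proportion(0.123456, "exact") == 0.123456


class TestTwoGroup:
    def test_identical_groups_give_identical_estimates(self):
        result = two_group_design(
            targets={"a": 323, "b": 323},
            p_prescreen={"a": 0.1, "b": 0.1},
            p_wmh_given_positive={"a": 0.2, "b": 0.2})
        assert result.groups["a"] == result.groups["b"]
        assert result.n_prescreen_total == 2 * result.groups["a"].n_prescreen

    def test_lower_prevalence_group_needs_double_the_sample(self):
        result = two_group_design(
            targets={"a": 323, "b": 323},
            p_prescreen={"a": 0.10, "b": 0.05},
            p_wmh_given_positive={"a": 0.2, "b": 0.2})
        n_a = result.groups["a"].n_prescreen
        n_b = result.groups["b"].n_prescreen
        assert n_b >= n_a  # more recruited where prevalence is lower
        assert abs(n_b - 2 * n_a) <= 1  # ceiling slack only

    def test_zero_prevalence_group_is_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            two_group_design(
                targets={"a": 323, "b": 323},
                p_prescreen={"a": 0.1, "b": 0.0},
                p_wmh_given_positive={"a": 0.2, "b": 0.2})

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            two_group_design(targets={"a": 1, "b": 1},
                             p_prescreen={"a": 0.1, "c": 0.1},
                             p_wmh_given_positive={"a": 0.2, "b": 0.2})
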