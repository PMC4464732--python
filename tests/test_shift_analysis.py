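import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avrecal.experiment_design import (
    GROUP_LIGHT_LEFT,
    GROUP_LIGHT_RIGHT,
    DesignConfig,
    build_schedule,
)
from avrecal.shift_analysis import (
    block_time_course,
    colocalization_rate,
    compute_shift,
    condition_summaries,
    conditional_shift_by_position,
    one_sample_t,
    property_shift_correlations,
    shifts_by_sequence_type,
    single_discrepant_summary,
)
from avrecal.sequence_features import property_matrix
from avrecal.experiment_design import enumerate_sequence_types


class TestComputeShift:
    def test_light_right_group_direct_subtraction(self):
        assert compute_shift(12, 14.5, GROUP_LIGHT_RIGHT) == 2.5

    def test_light_left_group_sign_flipped(self):
        assert compute_shift(12, 9.5, GROUP_LIGHT_LEFT) == 2.5

    def test_identity_response_zero_shift(self):
        assert compute_shift(-17.2, -17.2, GROUP_LIGHT_LEFT) == 0.0

    def test_missing_value_errors(self):
        with pytest.raises(ValueError):
            compute_shift(np.nan, 3.0, GROUP_LIGHT_RIGHT)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(-32, 32, allow_nan=False),
        st.floats(-40, 40, allow_nan=False),
    )
    def test_mirror_invariance(self, pos, resp):
        # negating all azimuths and flipping group leaves the shift unchanged
        assert compute_shift(pos, resp, GROUP_LIGHT_RIGHT) == pytest.approx(
            compute_shift(-pos, -resp, GROUP_LIGHT_LEFT)
        )


class TestShiftsBySequenceType:
    def test_noiseless_matches_generative_predictor(self, noiseless_table):
        shifts = shifts_by_sequence_type(noiseless_table)
        P = property_matrix(enumerate_sequence_types(), ("SQ5", "D")).to_numpy()
        expected = P @ np.array([0.88, 3.42])
        assert np.allclose(shifts["mean_shift"].to_numpy(), expected)

    def test_default_schedule_has_nine_obs_per_type(self, default_study):
        one_subject = default_study[default_study["subject_id"] == 1]
        shifts = shifts_by_sequence_type(one_subject)
        assert (shifts["n"] == 9).all()

    def test_missing_type_is_named(self, noiseless_table):
        truncated = noiseless_table[noiseless_table["sequence_id"] != 17]
        with pytest.raises(ValueError, match="17"):
            shifts_by_sequence_type(truncated)


class TestConditionalByPosition:
    def test_noiseless_closed_form_differences(self, noiseless_table):
        table = conditional_shift_by_position(noiseless_table)
        diff = table["discrepant"] - table["matching"]
        assert diff.loc[5] == pytest.approx(0.88 + 3.42 * 0.2)
        for k in range(1, 5):
            assert diff.loc[k] == pytest.approx(3.42 * 0.2)

    def test_constant_table_equal_columns(self, noiseless_table):
        constant = noiseless_table.copy()
        probes = constant["modality"] == "A"
        constant.loc[probes, "auditory_resp"] = constant.loc[probes, "auditory_pos"]
        table = conditional_shift_by_position(constant)
        assert np.allclose(table["discrepant"], table["matching"])

    def test_degenerate_single_type_errors(self, noiseless_table):
        only_disc = noiseless_table[noiseless_table["sequence_id"] == 31]
        with pytest.raises(ValueError):
            conditional_shift_by_position(only_disc)


class TestSingleDiscrepant:
    def test_noiseless_closed_form(self, noiseless_table):
        means = single_discrepant_summary(noiseless_table)
        assert means.loc[5] == pytest.approx(0.88 + 3.42 * 0.2)
        for k in range(1, 5):
            assert means.loc[k] == pytest.approx(3.42 * 0.2)

    def test_empty_selection_errors(self, noiseless_table):
        without = noiseless_table[noiseless_table["sequence_id"] != 8]  # (0,1,0,0,0)
        with pytest.raises(ValueError, match="2"):
            single_discrepant_summary(without)


class TestBlockTimeCourse:
    def test_stationary_observer_small_f(self, default_study):
        result = block_time_course(default_study, n_blocks=4)
        assert len(result.block_means) == 4
        assert result.p > 0.05  # no time trend by construction

    def test_shifted_block_detected(self, default_study):
        table = default_study.copy()
        probes = table["modality"] == "A"
        first_block = probes & (table["sequence_index"] <= 72)
        toward_light = np.where(
            table.loc[first_block, "group"] == GROUP_LIGHT_RIGHT, 30.0, -30.0
        )
        table.loc[first_block, "auditory_resp"] += toward_light
        result = block_time_course(table, n_blocks=4)
        assert result.p < 0.05

    def test_non_divisible_count_errors(self, default_study):
        with pytest.raises(ValueError):
            block_time_course(default_study, n_blocks=5)

    def test_single_block_errors(self, default_study):
        with pytest.raises(ValueError):
            block_time_course(default_study, n_blocks=1)


class TestOneSampleT:
    @pytest.mark.parametrize(
        "mean,sd,n,expected_t",
        [(1.28, 2.18, 11, 1.9474), (0.067, 0.73, 11, 0.3044)],
    )
    def test_summary_statistics_reproduce_t(self, mean, sd, n, expected_t):
        result = one_sample_t(mean, sd, n)
        assert result.t == pytest.approx(expected_t, abs=5e-5)
        assert result.df == n - 1

    def test_zero_mean_gives_zero_t(self):
        assert one_sample_t(0.0, 2.0, 10).t == 0.0

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError):
            one_sample_t(1.0, 0.0, 10)


class TestPropertyCorrelations:
    def test_perfect_linear_relation(self):
        P = property_matrix(enumerate_sequence_types(), ("D",))
        shifts = pd.Series(3.42 * P["D"].to_numpy(), index=range(32))
        table = property_shift_correlations(shifts)
        assert table.loc["D", "r"] == pytest.approx(1.0)

    def test_permuted_shifts_average_zero_correlation(self, rng):
        P = property_matrix(enumerate_sequence_types(), ("D",))
        base = 3.42 * P["D"].to_numpy()
        rs = []
        for _ in range(300):
            shifts = pd.Series(rng.permutation(base), index=range(32))
            rs.append(property_shift_correlations(shifts).loc["D", "r"])
        assert abs(np.mean(rs)) < 0.05

    def test_constant_property_flagged_undefined(self):
        # restrict to all-discrepant-start types so SQ1 is constant
        ids = [i for i in range(16, 32)]
        shifts = pd.Series(np.arange(16, dtype=float), index=ids)
        table = property_shift_correlations(shifts, names=("SQ1", "D"))
        assert bool(table.loc["SQ1", "undefined"])
        assert np.isnan(table.loc["SQ1", "r"])
        assert not table.loc["D", "undefined"]


class TestColocalization:
    def _table(self, vis_resp, aud_resp):
        n = len(vis_resp)
        return pd.DataFrame(
            {
                "modality": ["AV"] * n,
                "visual_pos": [0.0] * n,
                "auditory_pos": [12.0] * n,
                "visual_resp": vis_resp,
                "auditory_resp": aud_resp,
            }
        )

    def test_all_identical(self):
        assert colocalization_rate(self._table([3, 3], [3, 3])) == 1.0

    def test_none_identical(self):
        assert colocalization_rate(self._table([3, 4], [5, 6])) == 0.0

    def test_fractional_count(self):
        vis = [0] * 10
        aud = [0, 0, 0] + [9] * 7
        assert colocalization_rate(self._table(vis, aud)) == pytest.approx(0.3)

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            colocalization_rate(self._table([1], [1]), trial_filter="matching")


class TestConditionSummaries:
    def test_default_observer_reproduces_condition_structure(self, default_study):
        table = condition_summaries(default_study)
        assert list(table.index) == ["unimodal", "discrepant", "matching"]
        # visual estimates unbiased, auditory bias strongest in discrepant AV
        assert abs(table.loc["unimodal", "mean_visual"]) < 0.15
        assert table.loc["discrepant", "mean_auditory"] == pytest.approx(4.2, abs=0.4)
        assert table.loc["matching", "mean_auditory"] == pytest.approx(0.0, abs=0.4)
        assert (table["n_subjects"] == 11).all()
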