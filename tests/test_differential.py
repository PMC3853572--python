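"""Detection filtering, fold-change selection, normalization, counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floralnet.differential import (
    FilterMode,
    NormalizedMatrix,
    filter_detected,
    fold_change_select,
    normalize,
    stage_updown_counts,
)
from floralnet.synthetic import SyntheticConfig, generate_expression

from conftest import make_matrix


class TestFilterDetected:
    @pytest.mark.parametrize(
        "calls, in_discard, in_require",
        [
            ("AAAAAAAA", False, False),
            ("AAAAAAAP", True, True),
            ("MMMMMMMM", True, False),  # marginal: not absent, not present
            ("PPPPPPPP", True, True),
            ("AMAMAMAM", True, False),
        ],
    )
    def test_call_patterns(self, calls, in_discard, in_require):
        m = make_matrix({"g": [10] * 8, "anchor": [20] * 8}, calls={"g": calls})
        kept_d = filter_detected(m, FilterMode.discard_all_absent).gene_ids
        kept_r = filter_detected(m, FilterMode.require_one_present).gene_ids
        assert ("g" in kept_d) is in_discard
        assert ("g" in kept_r) is in_require

    def test_require_one_present_is_subset_of_discard(self, default_fixture):
        _, matrix, _, _ = default_fixture
        d = set(filter_detected(matrix, FilterMode.discard_all_absent).gene_ids)
        r = set(filter_detected(matrix, FilterMode.require_one_present).gene_ids)
        assert r <= d

    def test_no_planted_absent_gene_survives(self, default_fixture):
        _, matrix, truth, _ = default_fixture
        for mode in FilterMode:
            kept = set(filter_detected(matrix, mode).gene_ids)
            assert not (kept & truth.planted_absent)


class TestFoldChange:
    def test_boundary_ratio_four_selected(self):
        m = make_matrix({"g": [100, 100, 100, 100, 100, 100, 100, 400]})
        assert fold_change_select(m) == {"g"}

    def test_below_threshold_not_selected(self):
        m = make_matrix({"g": [50, 60, 70, 80, 90, 100, 110, 149]})
        assert fold_change_select(m) == set()

    def test_floor_applied_before_ratio(self):
        # 0.2 floors to 1.0; max 3.9 / 1.0 = 3.9 < 4
        m = make_matrix({"g": [0.2, 3.9, 2.0, 2.0, 2.0, 2.0, 2.0, 3.9]})
        assert fold_change_select(m) == set()
        assert fold_change_select(m, threshold=3.9) == {"g"}

    def test_monotone_in_threshold(self, default_fixture):
        _, matrix, _, _ = default_fixture
        assert fold_change_select(matrix, 4.0) <= fold_change_select(matrix, 3.0)

    def test_threshold_must_exceed_one(self):
        m = make_matrix({"g": [1] * 8})
        with pytest.raises(ValueError, match="threshold"):
            fold_change_select(m, threshold=1.0)

    def test_noiseless_selection_is_exact(self):
        """With zero noise the selected set is exactly the planted ≥4-fold
        archetypes, including the boundary."""
        shapes = {
            "flat": (0.0,) * 8,  # ratio 1
            "boundary": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0),  # exactly 4x
            "below": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.9),  # < 4x
            "strong": (-2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0),  # 16x
        }
        cfg = SyntheticConfig(
            n_genes=40,
            archetypes=shapes,
            genes_per_archetype={k: 10 for k in shapes},
            noise_sd=0.0,
            n_core=0,
            n_flower_cores=0,
            partners_per_core=0,
            absent_fraction=0.0,
            seed=5,
        )
        matrix, truth = generate_expression(cfg)
        expected = {
            g for g, a in truth.archetype_of.items() if a in ("boundary", "strong")
        }
        assert fold_change_select(matrix) == expected


class TestNormalize:
    def test_constant_profile_is_all_zero(self):
        m = make_matrix({"g": [2] * 8})
        nm = normalize(m)
        np.testing.assert_allclose(nm.value, 0.0, atol=1e-12)

    def test_two_stage_hand_computation(self):
        m = make_matrix({"g": [1, 3]})
        nm = normalize(m)
        np.testing.assert_allclose(nm.value[0], [-1.0, np.log2(1.5)], atol=1e-12)
        assert nm.value[0][1] == pytest.approx(0.5849625007211562)

    def test_mean_ratio_identity(self, default_fixture):
        """For every gene the across-stage mean of 2^value is 1."""
        _, matrix, _, _ = default_fixture
        nm = normalize(matrix)
        means = np.power(2.0, nm.value).mean(axis=1)
        np.testing.assert_allclose(means, 1.0, atol=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        profile=st.lists(
            st.floats(min_value=0.5, max_value=1e4), min_size=2, max_size=12
        ),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, profile, scale):
        m1 = make_matrix({"g": profile})
        m2 = make_matrix({"g": [scale * v for v in profile]})
        np.testing.assert_allclose(
            normalize(m1).value, normalize(m2).value, atol=1e-12
        )

    def test_nonpositive_signal_rejected(self):
        m = make_matrix({"g": [1, 0, 2, 2, 2, 2, 2, 2]})
        with pytest.raises(ValueError, match="non-positive"):
            normalize(m)


class TestStageCounts:
    def test_constant_profiles_count_nothing(self):
        nm = NormalizedMatrix(["a", "b"], [f"S{i}" for i in range(1, 9)],
                              np.zeros((2, 8)))
        assert all(u == 0 and d == 0 for _, u, d in stage_updown_counts(nm))

    def test_single_spike(self):
        value = np.zeros((1, 8))
        value[0, 1] = 2.0
        nm = NormalizedMatrix(["g"], [f"S{i}" for i in range(1, 9)], value)
        counts = stage_updown_counts(nm)
        assert counts[0] == ("S1", 0, 0)
        assert counts[1] == ("S2", 1, 0)
        assert all(u == 0 and d == 0 for _, u, d in counts[2:])

    def test_planted_late_rise_counted(self):
        """Ten planted late-rise genes (≥ 2 log2 rise at S5–S8) are all
        counted up at those stages."""
        shapes = {"late": (-1.0, -1.0, -1.0, -1.0, 1.2, 1.2, 1.2, 1.2),
                  "flat": (0.0,) * 8}
        cfg = SyntheticConfig(
            n_genes=20, archetypes=shapes,
            genes_per_archetype={"late": 10, "flat": 10},
            noise_sd=0.0, n_core=0, n_flower_cores=0, partners_per_core=0,
            absent_fraction=0.0, seed=2,
        )
        matrix, truth = generate_expression(cfg)
        nm = normalize(matrix)
        counts = dict(
            (s, (u, d)) for s, u, d in stage_updown_counts(nm, call_threshold=1.0)
        )
        for stage in ("S5", "S6", "S7", "S8"):
            assert counts[stage][0] >= 10

    def test_previous_baseline(self):
        value = np.array([[0.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0]])
        nm = NormalizedMatrix(["g"], [f"S{i}" for i in range(1, 9)], value)
        counts = stage_updown_counts(nm, baseline="previous")
        assert counts[1] == ("S2", 1, 0)
        assert counts[2] == ("S3", 0, 0)  # no change vs previous stage

    def test_unknown_selected_gene_rejected(self):
        nm = NormalizedMatrix(["g"], ["S1", "S2"], np.zeros((1, 2)))
        with pytest.raises(ValueError, match="absent from matrix"):
            stage_updown_counts(nm, selected={"nope"})
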