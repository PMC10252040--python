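"""Transform chain, rank test, selection and PCA."""

import numpy as np
import pytest

import sweatvoc as sv
from sweatvoc.core import StateError, ValidationError

from conftest import build_dataset


def two_group_dataset(library, pre_values, post_values):
    """One-descriptor-per-column dataset with given pre/post group values."""
    rows = [(f"p{i}", "hand", "pre", "column1", 1) for i in range(len(pre_values))]
    rows += [(f"q{i}", "hand", "post", "column1", 1) for i in range(len(post_values))]
    areas = np.array(pre_values + post_values, dtype=float).reshape(-1, 1)
    areas = np.repeat(areas, library.size, axis=1)
    return build_dataset(library, rows, areas)


class TestLogTransform:
    def test_values_and_state(self, tiny_dataset):
        logged = sv.log_transform(tiny_dataset)
        assert logged.transform_state == "logged"
        np.testing.assert_allclose(logged.areas, np.log1p(tiny_dataset.areas))
        assert logged.areas[0, 0] == 0.0  # absent stays absent

    def test_closed_form_point(self, tiny_library):
        ds = build_dataset(
            tiny_library,
            [("s", "hand", "pre", "column1", 1)],
            [[np.e - 1, 0.0, 1.0]],
        )
        logged = sv.log_transform(ds)
        np.testing.assert_allclose(logged.areas[0], [1.0, 0.0, np.log(2)])

    def test_monotone(self, tiny_dataset):
        logged = sv.log_transform(tiny_dataset)
        col = tiny_dataset.areas[:, 2]
        assert np.array_equal(np.argsort(col), np.argsort(logged.areas[:, 2]))

    def test_double_log_rejected(self, tiny_dataset):
        logged = sv.log_transform(tiny_dataset)
        with pytest.raises(StateError):
            sv.log_transform(logged)


class TestScaler:
    def test_frozen_three_point_example(self, tiny_library):
        ds = two_group_dataset(tiny_library, [1.0, 2.0], [3.0])
        logged = ds.with_areas(ds.areas, "logged")  # values used as-is
        state = sv.fit_scaler(logged, np.arange(3))
        scaled = sv.apply_scaler(logged, state)
        np.testing.assert_allclose(
            scaled.areas[:, 0], [-1.224744871391589, 0.0, 1.224744871391589]
        )

    def test_fit_rows_centered_unit_variance(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        rows = np.arange(0, logged.n, 2)
        state = sv.fit_scaler(logged, rows)
        scaled = sv.apply_scaler(logged, state)
        X = scaled.areas[rows][:, ~state.constant]
        assert np.abs(X.mean(axis=0)).max() < 1e-9
        assert np.abs(X.var(axis=0) - 1).max() < 1e-9

    def test_constant_descriptor_flagged_and_zeroed(self, tiny_library):
        ds = build_dataset(
            tiny_library,
            [("a", "hand", "pre", "column1", 1), ("b", "hand", "post", "column1", 1)],
            [[5.0, 1.0, 0.0], [5.0, 2.0, 1.0]],
        )
        logged = ds.with_areas(ds.areas, "logged")
        state = sv.fit_scaler(logged, np.arange(2))
        assert state.constant[0] and not state.constant[1]
        scaled = sv.apply_scaler(logged, state)
        np.testing.assert_array_equal(scaled.areas[:, 0], [0.0, 0.0])

    def test_heldout_rows_not_refit(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        state = sv.fit_scaler(logged, np.arange(10))
        scaled = sv.apply_scaler(logged, state)
        held = scaled.areas[10:]
        assert np.abs(held.mean(axis=0)).max() > 1e-6

    def test_empty_fit_subset_rejected(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        with pytest.raises(ValidationError):
            sv.fit_scaler(logged, np.array([], dtype=int))

    def test_raw_dataset_rejected(self, small_cohort):
        with pytest.raises(StateError):
            sv.fit_scaler(small_cohort, np.arange(4))


class TestMannWhitney:
    @pytest.mark.parametrize(
        "pre,post,expected_u,expected_p",
        [
            ([1, 2, 3], [4, 5, 6], 0.0, 0.1),  # fully separated, exact 2/20
            ([1, 4], [2, 3], 2.0, 1.0),  # modal U, enumeration gives 1.0
        ],
    )
    def test_exact_small_sample_pvalues(
        self, tiny_library, pre, post, expected_u, expected_p
    ):
        ds = two_group_dataset(tiny_library, list(map(float, pre)), list(map(float, post)))
        logged = ds.with_areas(ds.areas, "logged")
        ranked = sv.mannwhitney_rank(logged, np.arange(ds.n))
        row = ranked.frame.set_index("descriptor_id").loc["A"]
        assert row["U"] == expected_u
        assert row["p_value"] == pytest.approx(expected_p, abs=1e-12)

    def test_identical_groups_give_p_one(self, tiny_library):
        ds = two_group_dataset(tiny_library, [1.0, 2.0], [1.0, 2.0])
        logged = ds.with_areas(ds.areas, "logged")
        ranked = sv.mannwhitney_rank(logged, np.arange(ds.n))
        assert (ranked.frame["p_value"] == 1.0).all()

    def test_missing_status_rejected(self, tiny_library):
        ds = two_group_dataset(tiny_library, [1.0, 2.0], [3.0])
        logged = ds.with_areas(ds.areas, "logged")
        with pytest.raises(ValidationError):
            sv.mannwhitney_rank(logged, np.arange(2))  # pre rows only

    def test_rank_output_sorted_with_library_tie_break(self, tiny_library):
        # all three descriptors identical -> equal p, ranks follow library order
        ds = two_group_dataset(tiny_library, [1.0, 3.0], [2.0, 4.0])
        logged = ds.with_areas(ds.areas, "logged")
        ranked = sv.mannwhitney_rank(logged, np.arange(ds.n))
        assert list(ranked.frame["descriptor_id"]) == ["A", "B", "C"]
        assert list(ranked.frame["rank"]) == [1, 2, 3]
        assert ranked.frame["p_value"].is_monotonic_increasing


class TestSelection:
    @pytest.fixture
    def ranked(self, tiny_library):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "descriptor_id": ["A", "C", "B"],
                "U": [1.0, 2.0, 3.0],
                "p_value": [0.01, 0.04, 0.2],
                "rank": [1, 2, 3],
            }
        )
        return sv.RankedDescriptors(frame)

    def test_significance_threshold(self, ranked):
        assert sv.select_significant(ranked, 0.05) == ["A", "C"]

    def test_no_significant_warns_and_returns_empty(self, ranked):
        with pytest.warns(UserWarning):
            assert sv.select_significant(ranked, 0.001) == []

    def test_alpha_one_keeps_all(self, ranked):
        assert sv.select_significant(ranked, 1.0) == ["A", "C", "B"]

    def test_select_top_bounds(self, ranked):
        assert sv.select_top(ranked, 1) == ["A"]
        assert sv.select_top(ranked, 3) == ["A", "C", "B"]
        for bad in (0, 4):
            with pytest.raises(ValidationError):
                sv.select_top(ranked, bad)


class TestPCA:
    def test_collinear_points_give_single_axis(self, small_cohort):
        library = sv.DescriptorLibrary(("A", "B"), ("a", "b"))
        ds = build_dataset(
            library,
            [("a", "hand", "pre", "column1", 1), ("b", "hand", "post", "column1", 1)],
            [[-1.0, -1.0], [1.0, 1.0]],
            transform_state="standardized",
        )
        scores, explained = sv.pca_project(ds, ["A", "B"], k=1)
        assert explained[0] == pytest.approx(1.0)
        assert abs(scores[0, 0]) == pytest.approx(np.sqrt(2))

    def test_explained_variance_sorted_and_bounded(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        scaled = sv.apply_scaler(logged, sv.fit_scaler(logged, np.arange(logged.n)))
        subset = list(small_cohort.library.ids[:20])
        _, explained = sv.pca_project(scaled, subset, k=5)
        assert all(a >= b for a, b in zip(explained, explained[1:]))
        assert explained.sum() <= 1.0 + 1e-12

    def test_full_rank_projection_is_isometric(self, small_cohort):
        """With k = |subset| the scores preserve all pairwise distances."""
        logged = sv.log_transform(small_cohort)
        scaled = sv.apply_scaler(logged, sv.fit_scaler(logged, np.arange(logged.n)))
        subset = list(small_cohort.library.ids[:6])
        idx = scaled.library.indices(subset)
        X = scaled.areas[:12][:, idx]
        scores, _ = sv.pca_project(scaled.select_rows(np.arange(12)), subset, k=6)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(scores), pdist(X), atol=1e-9)

    def test_wrong_state_rejected(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        with pytest.raises(StateError):
            sv.pca_project(logged, list(small_cohort.library.ids[:5]), k=2)
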