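"""Feature-matrix algebra: padding, width identity, centering, fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petstage.features import (
    FeatureMatrix,
    assemble,
    assemble_wholebrain,
    concat_timepoints,
    mean_center,
    roi_max_lengths,
)
from petstage.parcellate import ROIVector
from petstage.volume import ImageVolume


def cohort_from_sizes(sizes_per_subject, rng=None):
    """Build ROI-vector dicts from a list of {roi: length} maps."""
    rng = rng or np.random.default_rng(0)
    cohort = []
    for sizes in sizes_per_subject:
        cohort.append(
            {roi: ROIVector(roi, rng.uniform(0, 1, n)) for roi, n in sizes.items()}
        )
    return cohort


class TestRoiMaxLengths:
    def test_elementwise_max(self):
        cohort = cohort_from_sizes([{"a": 3, "b": 5}, {"a": 4, "b": 2}])
        assert roi_max_lengths(cohort) == {"a": 4, "b": 5}

    def test_single_subject(self):
        cohort = cohort_from_sizes([{"a": 7, "b": 1}])
        assert roi_max_lengths(cohort) == {"a": 7, "b": 1}

    def test_missing_roi_raises(self):
        cohort = cohort_from_sizes([{"a": 3, "b": 5}, {"a": 4}])
        with pytest.raises(ValueError):
            roi_max_lengths(cohort)


class TestAssemble:
    def test_width_is_sum_of_maxima(self):
        cohort = cohort_from_sizes([{"a": 3, "b": 5}, {"a": 4, "b": 2}])
        fm = assemble(cohort)
        assert fm.width == 9

    def test_padding_positions_are_zero(self):
        cohort = cohort_from_sizes([{"a": 3, "b": 5}, {"a": 4, "b": 2}])
        fm = assemble(cohort)
        # subject 0 has 3 of 4 'a' voxels -> one pad at column 3
        assert fm.X[0, 3] == 0.0
        # subject 1 has 2 of 5 'b' voxels -> pads at columns 6..8
        assert np.all(fm.X[1, 6:9] == 0.0)

    def test_row_roundtrip_recovers_vectors(self):
        rng = np.random.default_rng(3)
        cohort = cohort_from_sizes([{"a": 3, "b": 5}, {"a": 4, "b": 2}], rng)
        fm = assemble(cohort)
        for j, vectors in enumerate(cohort):
            for roi, vec in vectors.items():
                lo, _ = fm.block_map[roi]
                np.testing.assert_array_equal(fm.X[j, lo:lo + len(vec)], vec.intensities)

    def test_oversized_vector_rejected(self):
        cohort = cohort_from_sizes([{"a": 5}])
        with pytest.raises(ValueError):
            assemble(cohort, k_max={"a": 3})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(min_value=1, max_value=12), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    def test_width_identity_property(self, size_rows):
        """D equals the sum over ROIs of the per-ROI maximum length."""
        rois = ["r0", "r1", "r2"]
        cohort = cohort_from_sizes([dict(zip(rois, row)) for row in size_rows])
        fm = assemble(cohort)
        expected = sum(max(row[i] for row in size_rows) for i in range(3))
        assert fm.width == expected


class TestWholeBrain:
    def test_column_count_is_union_support(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1.0; a[1, 1, 1] = 0.5
        b = np.zeros((4, 4, 4)); b[1, 1, 1] = 0.7; b[2, 2, 2] = 0.2
        fm = assemble_wholebrain([ImageVolume(a), ImageVolume(b)])
        assert fm.width == 3

    def test_multiregion_narrower_than_wholebrain(self, config32, atlas32):
        from petstage.parcellate import extract_masks, extract_subject_vectors
        from petstage.phantom import simulate_pet
        from petstage.normalize import normalize_volume

        pets = [
            normalize_volume(simulate_pet(atlas32, d, "FDG", "baseline", config32, seed=i)).volume
            for i, d in enumerate(("AD", "NC"))
        ]
        masks = extract_masks(atlas32)
        multi = assemble([extract_subject_vectors(p, masks) for p in pets])
        whole = assemble_wholebrain(pets)
        assert multi.width <= whole.width

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assemble_wholebrain([ImageVolume(np.ones((4, 4, 4))), ImageVolume(np.ones((5, 5, 5)))])


class TestMeanCenter:
    def test_fit_rows_have_zero_mean(self):
        rng = np.random.default_rng(0)
        fm = FeatureMatrix(rng.normal(size=(6, 4)), [f"s{i}" for i in range(6)])
        centered = mean_center(fm, fit_rows=[0, 1, 2])
        np.testing.assert_allclose(centered.X[:3].mean(axis=0), 0.0, atol=1e-10)

    def test_heldout_rows_generally_nonzero(self):
        X = np.array([[0.0, 2.0], [2.0, 4.0], [10.0, 20.0]])
        fm = FeatureMatrix(X, ["a", "b", "c"])
        centered = mean_center(fm, fit_rows=[0, 1])
        np.testing.assert_allclose(centered.X[2], [9.0, 17.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix(rng.normal(size=(5, 3)), [f"s{i}" for i in range(5)])
        once = mean_center(fm, fit_rows=[0, 1, 4])
        twice = mean_center(once, fit_rows=[0, 1, 4])
        np.testing.assert_allclose(once.X, twice.X, atol=1e-12)

    def test_empty_fit_rows_rejected(self):
        fm = FeatureMatrix(np.ones((2, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            mean_center(fm, fit_rows=[])


class TestConcatTimepoints:
    def test_equal_widths_double(self):
        rng = np.random.default_rng(0)
        cohort = cohort_from_sizes([{"a": 3, "b": 5}, {"a": 4, "b": 2}], rng)
        x1 = assemble(cohort)
        x2 = assemble(cohort_from_sizes([{"a": 4, "b": 5}, {"a": 2, "b": 3}], rng))
        fused = concat_timepoints(x1, x2)
        assert x1.width == x2.width == 9
        assert fused.width == 18

    def test_empty_second_matrix_is_identity(self):
        fm = FeatureMatrix(np.ones((2, 3)), ["a", "b"])
        empty = FeatureMatrix(np.empty((2, 0)), ["a", "b"])
        np.testing.assert_array_equal(concat_timepoints(fm, empty).X, fm.X)

    def test_subject_order_mismatch_rejected(self):
        x1 = FeatureMatrix(np.ones((2, 3)), ["a", "b"])
        x2 = FeatureMatrix(np.ones((2, 3)), ["b", "a"])
        with pytest.raises(ValueError):
            concat_timepoints(x1, x2)
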