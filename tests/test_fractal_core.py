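import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainfd import (
    BoxCountSeries,
    EmptyRoiError,
    ScaleSchedule,
    count_boxes,
    count_series,
    estimate_fd,
    fit_fd,
    generate_scale_schedule,
    linearity_flag,
)
from brainfd.fractal_core import (
    FRACTAL_OK,
    MULTIFRACTAL_SUSPECT,
    FitError,
    grid_bins,
)
from brainfd.phantoms import MENGER_FD

from .conftest import brute_force_count

# The 20 default box edge lengths, as independently tabulated.
TABULATED_SCALES = [
    "1.023292992280754",
    "1.146832521422478",
    "1.285286659943615",
    "1.440456010246376",
    "1.614358556826486",
    "1.809255910253820",
    "2.027682719521282",
    "2.272479635270844",
    "2.546830252585041",
    "2.854302513786581",
    "3.198895109691398",
    "3.585089482765549",
    "4.017908108489400",
    "4.502979812880891",
    "5.046612975635284",
    "5.655877570891540",
    "6.338697112569270",
    "7.103951700029557",
    "7.961593504173188",
    "8.922776195878269",
]


class TestScaleSchedule:
    def test_default_reproduces_tabulated_scales_to_printed_digits(self):
        # the tabulated strings are truncated (not rounded) doubles, so
        # agreement is asserted to one unit of the last printed place
        schedule = generate_scale_schedule()
        assert len(schedule) == 20
        for got, expected in zip(schedule.scales, TABULATED_SCALES):
            assert abs(got - float(expected)) <= 1e-15
        # the first, tenth and last scales agree digit for digit
        for idx in (0, 9, 19):
            assert f"{schedule.scales[idx]:.15f}" == TABULATED_SCALES[idx]

    def test_default_ratio_is_constant(self):
        scales = generate_scale_schedule().scales
        ratios = scales[1:] / scales[:-1]
        np.testing.assert_allclose(ratios, 10**0.0495, rtol=1e-12)

    def test_epsilon_is_reciprocal_of_scale(self):
        schedule = generate_scale_schedule()
        np.testing.assert_allclose(schedule.epsilons * schedule.scales, 1.0)

    def test_two_point_schedule(self):
        schedule = generate_scale_schedule(2, 0.01, 1.0)
        np.testing.assert_allclose(schedule.scales, [10**0.01, 10.0])

    @pytest.mark.parametrize("args", [(1, 0.01, 0.9), (5, 0.5, 0.5), (5, 0.5, 0.1)])
    def test_bad_parameters_rejected(self, args):
        with pytest.raises(ValueError):
            generate_scale_schedule(*args)

    def test_schedule_must_exceed_one_voxel(self):
        with pytest.raises(ValueError):
            ScaleSchedule(scales=np.array([1.0, 10.0]))


class TestCountBoxes:
    @pytest.mark.parametrize("s", [1.5, 2.7, 8.9])
    def test_single_voxel_occupies_one_box(self, s):
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[3, 7, 11] = True
        assert count_boxes(mask, s) == 1

    def test_filled_cube_integer_scale(self):
        # 8^3 cube at s=2: grid keeps ceil(8/2)-1 = 3 cells/axis, the
        # trailing column folds onto them -> 27 occupied cells
        mask = np.ones((8, 8, 8), dtype=bool)
        assert count_boxes(mask, 2) == 27
        assert count_boxes(mask, 7.9) == 1

    def test_grid_bins_definition(self):
        assert grid_bins((8, 8, 8), 2.0) == (3, 3, 3)
        assert grid_bins((64, 64, 1), 8.9) == (7, 7, 1)
        assert grid_bins((5, 5, 5), 6.0) == (1, 1, 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyRoiError):
            count_boxes(np.zeros((4, 4, 4), dtype=bool), 2.0)

    @pytest.mark.parametrize("s", [1.0, 0.5, -2.0])
    def test_degenerate_scale_rejected(self, s):
        with pytest.raises(ValueError):
            count_boxes(np.ones((4, 4, 4), dtype=bool), s)

    def test_matches_brute_force_oracle_on_random_masks(
        self, random_masks, default_schedule
    ):
        for mask in random_masks:
            for s in default_schedule:
                assert count_boxes(mask, s) == brute_force_count(mask, s), (
                    mask.shape,
                    s,
                )

    def test_scaling_bounds(self, random_masks, default_schedule):
        # 1 <= N(s) <= min(occupied voxels, number of grid cells)
        for mask in random_masks[:25]:
            occupied = int(mask.sum())
            for s in default_schedule:
                n = count_boxes(mask, s)
                assert 1 <= n <= min(occupied, int(np.prod(grid_bins(mask.shape, s))))

    def test_counts_non_increasing_on_blobs(self, default_schedule):
        # non-nested grids do not make monotonicity a theorem, but it holds
        # for masks comfortably larger than the coarsest box
        from brainfd.phantoms import random_blob

        for seed in range(5):
            series = count_series(random_blob(48, seed=seed), default_schedule)
            assert (np.diff(series.counts) <= 0).all()

    def test_counts_non_increasing_on_phantoms(self, default_schedule, menger4):
        for mask in (np.ones((64, 64, 64), dtype=bool), menger4):
            series = count_series(mask, default_schedule)
            assert (np.diff(series.counts) <= 0).all()


class TestFitFd:
    @pytest.mark.parametrize("dimension", [1.0, 2.0, 2.5, 3.0])
    def test_exact_power_law_recovered_to_float_precision(
        self, default_schedule, dimension
    ):
        log_n = 5.0 - dimension * np.log10(default_schedule.scales)
        series = BoxCountSeries.__new__(BoxCountSeries)
        object.__setattr__(series, "schedule", default_schedule)
        object.__setattr__(series, "counts", 10.0**log_n)
        result = fit_fd(series)
        assert result.fd == pytest.approx(dimension, abs=1e-12)
        assert result.rmse == pytest.approx(0.0, abs=1e-12)
        assert result.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_counts_give_zero_dimension(self, default_schedule):
        series = BoxCountSeries(
            schedule=default_schedule, counts=np.full(20, 7)
        )
        result = fit_fd(series)
        assert result.fd == pytest.approx(0.0, abs=1e-12)
        assert result.r2 == 0.0  # zero-variance response

    def test_fd_is_negative_slope(self, menger3, default_schedule):
        result = estimate_fd(menger3, default_schedule)
        assert result.fd == -result.slope
        assert result.n_points == len(result.series.counts) == 20

    def test_nonpositive_counts_rejected(self, default_schedule):
        with pytest.raises(FitError):
            fit_fd(
                BoxCountSeries(schedule=default_schedule, counts=np.zeros(20))
            )

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            ScaleSchedule(scales=np.array([2.0]))


class TestEstimateFd:
    def test_filled_cube_near_three(self, default_schedule):
        fd = estimate_fd(np.ones((64, 64, 64), dtype=bool), default_schedule).fd
        assert fd == pytest.approx(3.0, abs=0.05)

    def test_slab_near_two(self, default_schedule):
        fd = estimate_fd(np.ones((64, 64, 1), dtype=bool), default_schedule).fd
        assert fd == pytest.approx(2.0, abs=0.10)

    def test_line_near_one(self, default_schedule):
        fd = estimate_fd(np.ones((64, 1, 1), dtype=bool), default_schedule).fd
        assert fd == pytest.approx(1.0, abs=0.10)

    def test_menger_level4_near_similarity_dimension(
        self, menger4, default_schedule
    ):
        fd = estimate_fd(menger4, default_schedule).fd
        assert fd == pytest.approx(MENGER_FD, abs=0.15)

    def test_stored_series_is_the_counted_series(self, menger3, default_schedule):
        result = estimate_fd(menger3, default_schedule)
        recounted = count_series(menger3, default_schedule)
        np.testing.assert_array_equal(result.series.counts, recounted.counts)

    def test_translation_invariance_of_estimate(self, default_schedule):
        cube = np.ones((32, 32, 32), dtype=bool)
        padded = np.zeros((48, 48, 48), dtype=bool)
        padded[9:41, 9:41, 9:41] = True
        a = estimate_fd(cube, default_schedule)
        b = estimate_fd(padded, default_schedule)
        assert a.fd == b.fd
        np.testing.assert_array_equal(a.series.counts, b.series.counts)

    def test_default_schedule_used_when_omitted(self, menger3, default_schedule):
        assert estimate_fd(menger3).fd == estimate_fd(menger3, default_schedule).fd


class TestLinearityFlag:
    def test_thresholding(self, default_schedule):
        series = BoxCountSeries(schedule=default_schedule, counts=np.full(20, 7))
        result = fit_fd(series)  # rmse == 0
        assert linearity_flag(result) == FRACTAL_OK
        bent = fit_fd(
            BoxCountSeries(
                schedule=default_schedule,
                counts=np.logspace(4, 0, 20).astype(int) + np.arange(20) ** 2,
            )
        )
        if bent.rmse > 0.05:
            assert linearity_flag(bent) == MULTIFRACTAL_SUSPECT
        assert linearity_flag(bent, rmse_threshold=bent.rmse + 1) == FRACTAL_OK

    def test_exact_power_law_ok_at_any_threshold(self, default_schedule):
        counts = 10 ** (5.0 - 2.0 * np.log10(default_schedule.scales))
        series = BoxCountSeries.__new__(BoxCountSeries)
        object.__setattr__(series, "schedule", default_schedule)
        object.__setattr__(series, "counts", counts)
        result = fit_fd(series)
        for threshold in (1e-9, 0.05, 1.0):
            assert linearity_flag(result, threshold) == FRACTAL_OK

    def test_threshold_must_be_positive(self, default_schedule):
        result = fit_fd(
            BoxCountSeries(schedule=default_schedule, counts=np.full(20, 3))
        )
        with pytest.raises(ValueError):
            linearity_flag(result, 0.0)


class TestSerialization:
    def test_result_to_json_and_series_to_csv(self, tmp_path, menger3):
        result = estimate_fd(menger3)
        payload = result.to_dict()
        assert set(payload) >= {"fd", "slope", "rmse", "r2", "n_points", "scales"}
        result.to_json(tmp_path / "fd.json")
        assert (tmp_path / "fd.json").exists()
        result.series.to_csv(tmp_path / "series.csv")
        import pandas as pd

        frame = pd.read_csv(tmp_path / "series.csv")
        assert list(frame.columns) == ["scale", "n_boxes"]
        assert len(frame) == 20


@given(
    shift=st.tuples(
        st.integers(0, 3), st.integers(0, 3), st.integers(0, 3)
    )
)
@settings(max_examples=20, deadline=None)
def test_shifting_mask_inside_array_changes_counts_boundedly(shift):
    """count_boxes on a shifted compact mask moves N(s) only by cells that
    straddle grid lines; the change per scale is bounded by the count of
    boundary cells, never the bulk."""
    base = np.zeros((24, 24, 24), dtype=bool)
    base[2:10, 2:10, 2:10] = True
    shifted = np.roll(base, shift, axis=(0, 1, 2))
    for s in (2.3, 4.5):
        n0 = count_boxes(base, s)
        n1 = count_boxes(shifted, s)
        # an 8-cube spans at most (8/s + 1)^3 cells; boundary cells dominate
        # the worst-case difference
        bound = int(np.ceil(8 / s + 1)) ** 3 - int(np.floor(8 / s - 1)) ** 3
        assert abs(n1 - n0) <= bound
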