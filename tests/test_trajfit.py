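import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forestcc.grid import AnnualCube, GridSpec
from forestcc import scenegen, trajfit
from forestcc.trajfit import (
    LABEL_GAIN,
    LABEL_LOSS,
    LABEL_NONE,
    DetectorParams,
    SegmentFit,
    classify_trajectory,
    despike,
    detect_changes,
    fill_gaps,
    fit_trajectory,
    fit_trajectory_exhaustive,
)


class TestDespike:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([0.6, 0.6, 0.6], [0.6, 0.6, 0.6]),          # flat untouched
            ([0.6, 0.1, 0.6], [0.6, 0.6, 0.6]),          # one-year dip removed
            ([0.6, 0.3, 0.1], [0.6, 0.3, 0.1]),          # monotone step kept
            ([0.6, 0.6], [0.6, 0.6]),                    # too short: unchanged
        ],
    )
    def test_rule_on_hand_examples(self, series, expected):
        assert np.allclose(despike(series, 0.5), expected)

    def test_step_edge_point_is_preserved_under_noise(self):
        # the last pre-drop year pokes above both neighbours but the
        # neighbours disagree strongly: a step edge, not a spike
        series = [0.58, 0.576, 0.603, 0.142, 0.188]
        out = despike(series, 0.5)
        assert out[2] == 0.603

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=20))
    @settings(deadline=None)
    def test_endpoints_and_length_invariant(self, series):
        out = despike(np.array(series), 0.5)
        assert out.size == len(series)
        assert out[0] == series[0] and out[-1] == series[-1]


class TestFitTrajectory:
    def test_constant_series_single_flat_segment(self):
        fit = fit_trajectory([0.5] * 14)
        assert fit.n_segments == 1
        assert np.allclose(fit.slopes, 0.0, atol=1e-12)
        assert fit.sse < 1e-20

    def test_noiseless_ramp_single_segment_exact_slope(self):
        y = 0.2 + 0.05 * np.arange(14)
        fit = fit_trajectory(y)
        assert fit.n_segments == 1
        assert np.allclose(fit.slopes, [0.05])
        assert fit.sse < 1e-20

    def test_noiseless_step_isolated_and_optimal(self):
        y = np.array([0.6] * 6 + [0.16] * 8)
        fit = fit_trajectory(y, max_segments=3)
        oracle = fit_trajectory_exhaustive(y, max_segments=3)
        assert fit.sse <= oracle.sse + 1e-15
        # the drop is isolated between consecutive years 5 and 6
        drops = np.diff(fit.vertex_values)
        k = int(np.argmin(drops))
        assert (fit.vertex_years[k], fit.vertex_years[k + 1]) == (5, 6)
        assert np.isclose(drops[k], -0.44)

    def test_greedy_never_beats_exhaustive_and_matches_on_clean_input(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            y = rng.normal(0.4, 0.05, 14)
            g = fit_trajectory(y, max_segments=3, mse_improvement_min=0.0)
            e = fit_trajectory_exhaustive(y, max_segments=3)
            assert g.sse >= e.sse - 1e-12

    def test_slopes_consistent_with_vertices(self):
        y = np.array([0.6] * 6 + [0.16] * 8) + 0.01 * np.sin(np.arange(14))
        fit = fit_trajectory(y, max_segments=4)
        manual = np.diff(fit.vertex_values) / np.diff(fit.vertex_years)
        assert np.allclose(fit.slopes, manual, atol=1e-9)
        assert fit.vertex_years[0] == 0 and fit.vertex_years[-1] == 13
        assert (np.diff(fit.vertex_years) > 0).all()

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fit_trajectory([0.5, np.nan, 0.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_noiseless_piecewise_linear_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(0, 3)
        interior = np.sort(rng.choice(np.arange(1, 13), size=k, replace=False))
        vs = np.r_[0, interior, 13]
        vv = rng.choice([0.05, 0.2, 0.45, 0.6], size=len(vs))
        y = np.interp(np.arange(14), vs, vv)
        fit = fit_trajectory(y, max_segments=3, mse_improvement_min=0.0)
        assert fit.sse < 1e-18


class TestClassifyTrajectory:
    def _fit(self, years, values):
        return SegmentFit(np.asarray(years, float), np.asarray(values, float), 0.0)

    def test_flat_trajectory_is_no_change(self):
        fit = self._fit([2000, 2013], [0.5, 0.5])
        assert classify_trajectory(fit, DetectorParams()) == (LABEL_NONE, None, 0.0)

    def test_large_drop_from_forest_is_loss(self):
        fit = self._fit([2000, 2005, 2006, 2013], [0.6, 0.6, 0.16, 0.16])
        params = DetectorParams(change_threshold=0.2, forest_threshold=0.4)
        label, year, mag = classify_trajectory(fit, params)
        assert label == LABEL_LOSS
        assert year == 2006  # decisive segment's end
        assert np.isclose(mag, 0.44)

    def test_rise_to_forest_is_gain_but_not_if_it_stays_nonforest(self):
        fit = self._fit([2000, 2013], [0.10, 0.55])
        lo = DetectorParams(change_threshold=0.2, forest_threshold=0.4)
        hi = DetectorParams(change_threshold=0.2, forest_threshold=0.6)
        label, year, mag = classify_trajectory(fit, lo)
        assert (label, year) == (LABEL_GAIN, 2000)  # decisive segment's start
        assert np.isclose(mag, 0.45)
        assert classify_trajectory(fit, hi)[0] == LABEL_NONE

    def test_drop_not_starting_as_forest_is_none(self):
        fit = self._fit([2000, 2006, 2013], [0.3, 0.05, 0.05])
        params = DetectorParams(change_threshold=0.2, forest_threshold=0.4)
        assert classify_trajectory(fit, params)[0] == LABEL_NONE

    def test_largest_magnitude_segment_decides(self):
        # small early gain, bigger late loss -> loss wins
        fit = self._fit([2000, 2004, 2008, 2013], [0.40, 0.60, 0.60, 0.15])
        params = DetectorParams(change_threshold=0.15, forest_threshold=0.4)
        assert classify_trajectory(fit, params)[0] == LABEL_LOSS

    def test_sub_threshold_changes_are_none(self):
        fit = self._fit([2000, 2006, 2013], [0.5, 0.6, 0.5])
        params = DetectorParams(change_threshold=0.15)
        assert classify_trajectory(fit, params)[0] == LABEL_NONE


class TestFillGaps:
    def test_short_gap_interpolated(self):
        s = np.array([0.4, -9999.0, 0.6, 0.6])
        filled, ok = fill_gaps(s, s != -9999.0, max_gap=2)
        assert ok
        assert np.isclose(filled[1], 0.5)

    def test_long_gap_excludes_pixel(self):
        s = np.array([0.4, -1.0, -1.0, -1.0, 0.6])
        filled, ok = fill_gaps(s, s > 0, max_gap=2)
        assert not ok

    def test_missing_endpoint_excludes_pixel(self):
        s = np.array([-1.0, 0.5, 0.5, 0.5])
        _, ok = fill_gaps(s, s > 0, max_gap=2)
        assert not ok


class TestDetectChanges:
    def test_all_stable_noiseless_scene_is_all_none(self, grid10):
        truth = scenegen.make_truth(grid10, {"stable_forest": 1.0}, seed=0)
        nbr = scenegen.render_nbr(truth)
        res = detect_changes(nbr, DetectorParams())
        assert (res["label"] == LABEL_NONE).all()
        assert res["qa"].sum() == 0

    def test_noiseless_loss_scene_perfect_recovery(self, loss_scene, loss_mask):
        nbr = scenegen.render_nbr(loss_scene)
        res = detect_changes(nbr, DetectorParams(), loss_mask)
        truth_loss = loss_scene.kind == scenegen.EVENT_KINDS.index("abrupt_loss")
        pred_loss = res["label"] == LABEL_LOSS
        assert (pred_loss == truth_loss).all()  # recall = precision = 1
        assert np.all(res["year"][pred_loss] == 2006)

    def test_loss_outside_mask_suppressed_gain_kept(self, loss_scene):
        nbr = scenegen.render_nbr(loss_scene)
        empty_mask = np.zeros(loss_scene.grid.shape, dtype=bool)
        res = detect_changes(nbr, DetectorParams(), empty_mask)
        assert (res["label"] != LABEL_LOSS).all()

    def test_mask_filters_gain_flag(self, grid10):
        truth = scenegen.make_truth(grid10, {"gradual_gain": 1.0}, seed=1,
                                    ramp_rate=0.2, event_year=2002)
        nbr = scenegen.render_nbr(truth)
        empty_mask = np.zeros(grid10.shape, dtype=bool)
        keep = detect_changes(nbr, DetectorParams(), empty_mask)
        drop = detect_changes(
            nbr, DetectorParams(mask_filters_gain=True), empty_mask)
        assert (keep["label"] == LABEL_GAIN).any()
        assert (drop["label"] == LABEL_NONE).all()

    def test_grid_mismatch_rejected(self, loss_scene):
        nbr = scenegen.render_nbr(loss_scene)
        with pytest.raises(ValueError, match="mask shape"):
            detect_changes(nbr, DetectorParams(), np.ones((3, 3), dtype=bool))

    def test_unfillable_pixels_flagged_in_qa(self, grid10):
        truth = scenegen.make_truth(grid10, {"stable_forest": 1.0}, seed=0)
        nbr = scenegen.render_nbr(truth)
        vals = nbr.values.copy()
        vals[0:5, 0, 0] = -9999.0  # five missing years incl. an endpoint
        cube = AnnualCube(grid10, vals)
        res = detect_changes(cube, DetectorParams())
        assert res["qa"][0, 0] == 1
        assert res["label"][0, 0] == LABEL_NONE
        assert res["qa"].sum() == 1

    def test_raising_change_threshold_never_adds_labels(self, grid10):
        mix = {"stable_forest": 0.5, "abrupt_loss": 0.3, "gradual_gain": 0.2}
        truth = scenegen.make_truth(grid10, mix, seed=21)
        nbr = scenegen.render_nbr(truth, sigma=0.02, seed=22)
        mask = truth.cover(2000) >= 0.5
        counts = []
        for thr in [0.05, 0.15, 0.25, 0.35]:
            res = detect_changes(nbr, DetectorParams(change_threshold=thr), mask)
            counts.append(
                ((res["label"] == LABEL_LOSS).sum(),
                 (res["label"] == LABEL_GAIN).sum())
            )
        losses = [c[0] for c in counts]
        gains = [c[1] for c in counts]
        assert losses == sorted(losses, reverse=True)
        assert gains == sorted(gains, reverse=True)


def test_detector_params_validation():
    with pytest.raises(ValueError):
        DetectorParams(change_threshold=0.0)
    with pytest.raises(ValueError):
        DetectorParams(max_segments=0)
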