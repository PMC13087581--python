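import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nephelofit.plate_io import LayoutEntry, PlateLayout, WellTimeseries
from nephelofit.preprocess import (
    CurveId,
    GrowthCurve,
    average_replicates,
    blank_correct,
    clamp_pre_minimum,
    control_normalize,
    preprocess_pipeline,
    rebase_initial,
    savgol_smooth,
    savgol_window,
)

T10 = np.arange(10) / 6.0


def _well(values, well="A1", times=None):
    return WellTimeseries(well, T10 if times is None else times, values)


finite_values = arrays(
    float,
    st.integers(min_value=5, max_value=40),
    elements=st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
)


class TestBlankCorrect:
    def test_subtracts_mean_of_blanks(self):
        tr = _well(np.full(10, 0.50))
        blanks = [_well(np.full(10, 0.10), w) for w in ("B1", "B2", "B3")]
        out = blank_correct(tr, blanks)
        np.testing.assert_allclose(out.values, 0.40)

    def test_blanks_are_mean_centered_by_their_own_correction(self, rng):
        blanks = [_well(rng.normal(5, 1, 10), w) for w in ("B1", "B2", "B3")]
        corrected = [blank_correct(b, blanks) for b in blanks]
        total = np.sum([c.values for c in corrected], axis=0)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_grid_mismatch_is_an_error(self):
        tr = _well(np.ones(10))
        blank = WellTimeseries("B1", np.arange(10.0), np.ones(10))  # 60-min grid
        with pytest.raises(ValueError, match="grid"):
            blank_correct(tr, [blank])

    def test_no_blanks_is_an_error(self):
        with pytest.raises(ValueError, match="no blank"):
            blank_correct(_well(np.ones(10)), [])


class TestControlNormalize:
    def test_subtracts_control_mean(self):
        tr = _well(np.full(10, 0.80))
        ctrl = [_well(np.full(10, 0.05), "C1")]
        out = control_normalize(tr, ctrl, medium="citrulline")
        np.testing.assert_allclose(out.values, 0.75)

    def test_controls_center_to_zero_against_their_own_mean(self, rng):
        ctrls = [_well(rng.normal(2, 0.5, 10), w) for w in ("C1", "C2", "C3")]
        normed = [control_normalize(c, ctrls, medium="citrulline") for c in ctrls]
        total = np.sum([c.values for c in normed], axis=0)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_non_test_medium_is_a_warning_noop(self):
        tr = _well(np.full(10, 0.80))
        ctrl = [_well(np.full(10, 0.05), "C1")]
        with pytest.warns(UserWarning, match="ammonium"):
            out = control_normalize(tr, ctrl, medium="ammonium")
        np.testing.assert_array_equal(out.values, tr.values)

    def test_empty_control_set_is_an_error(self):
        with pytest.raises(ValueError, match="control"):
            control_normalize(_well(np.ones(10)), [], medium="citrulline")


class TestClampRebase:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([5, 3, 2, 4, 9], [2, 2, 2, 4, 9]),
            ([1, 2, 3], [1, 2, 3]),
            ([4, 2, 5, 2, 7], [2, 2, 5, 2, 7]),  # clamp to FIRST occurrence of the min
        ],
    )
    def test_clamp_examples(self, values, expected):
        np.testing.assert_array_equal(clamp_pre_minimum(values), expected)

    @given(finite_values)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_clamp_is_idempotent(self, values):
        once = clamp_pre_minimum(values)
        np.testing.assert_array_equal(clamp_pre_minimum(once), once)

    @given(finite_values)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_clamp_minimum_attained_at_start(self, values):
        out = clamp_pre_minimum(values)
        assert out[0] == out.min()

    @pytest.mark.parametrize(
        "values,expected",
        [([2, 2, 2, 4, 9], [1, 1, 1, 3, 8]), ([1, 5], [1, 5])],
    )
    def test_rebase_examples(self, values, expected):
        np.testing.assert_array_equal(rebase_initial(values), expected)

    @given(finite_values)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_rebase_sets_first_value_to_one_and_preserves_differences(self, values):
        out = rebase_initial(values)
        assert out[0] == 1.0
        np.testing.assert_allclose(np.diff(out), np.diff(values), atol=1e-6)


class TestSavgol:
    @pytest.mark.parametrize("n,window", [(14, 5), (100, 11), (1008, 101), (1081, 109)])
    def test_window_rule(self, n, window):
        assert savgol_window(n) == window

    @pytest.mark.parametrize("n", [14, 100, 1008])
    def test_reproduces_quadratics_exactly(self, n):
        t = np.arange(n) / 6.0
        v = 3.0 - 0.2 * t + 0.01 * t**2
        out = savgol_smooth(v, t)
        np.testing.assert_allclose(out, v, rtol=1e-9)

    def test_linearity(self, rng):
        t = np.arange(60) / 6.0
        x, y = rng.normal(size=60), rng.normal(size=60)
        a, b = 2.5, -1.25
        lhs = savgol_smooth(a * x + b * y, t)
        rhs = a * savgol_smooth(x, t) + b * savgol_smooth(y, t)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_irregular_grid_is_an_error(self):
        t = np.array([0, 1, 2, 3, 10.0])
        with pytest.raises(ValueError, match="grid"):
            savgol_smooth(np.ones(5), t)

    def test_too_short_is_an_error(self):
        with pytest.raises(ValueError, match=">= 5"):
            savgol_smooth([1, 2, 3], [0, 1, 2])


def _curve(values, bio=1, tech=None):
    t = np.arange(len(values), dtype=float)
    return GrowthCurve(CurveId("AtLHT1", "citrulline", bio, tech), t, np.asarray(values, float))


class TestAverageReplicates:
    def test_mean_is_idempotent_on_identical_curves(self):
        c = _curve([1.0, 2, 3, 4])
        out = average_replicates([c, c, c])
        np.testing.assert_array_equal(out.values, c.values)

    def test_pointwise_mean(self):
        out = average_replicates([_curve([1.0, 3.0]), _curve([3.0, 1.0])])
        np.testing.assert_array_equal(out.values, [2.0, 2.0])

    def test_single_curve_unchanged(self):
        c = _curve([1.0, 2, 3])
        np.testing.assert_array_equal(average_replicates([c]).values, c.values)

    def test_mixed_bio_replicates_rejected(self):
        with pytest.raises(ValueError, match="biological"):
            average_replicates([_curve([1.0, 2]), _curve([1.0, 2], bio=2)])

    def test_averaged_curve_drops_tech_identity(self):
        out = average_replicates([_curve([1.0, 2], tech=1), _curve([3.0, 4], tech=2)])
        assert out.curve_id.tech_replicate is None
        assert "averaged" in out.stages


class TestPipeline:
    def _plate(self, rng, n_bio=3, n_tech=3):
        from conftest import quiet_config
        from nephelofit.synthetic_data import GroupSpec, simulate_plate

        cfg = quiet_config(
            groups=[GroupSpec("AtLHT1", K=1000.0, r=0.1, max_slope_time=60.0,
                              n_bio=n_bio, n_tech=n_tech)],
            control_background=GroupSpec("ccdB", K=30.0, r=0.05, max_slope_time=60.0),
            noise_sd=0.01,
        )
        return simulate_plate(cfg, seed=11)

    def test_one_curve_per_bio_replicate_group(self, rng):
        traces, layout, _ = self._plate(rng)
        curves = preprocess_pipeline(traces, layout)
        # 3 bio AtLHT1 + 3 bio ccdB
        assert len(curves) == len(layout.groups()) == 6

    def test_all_blank_plate_yields_no_curves(self):
        t = np.arange(10) / 6
        traces = [WellTimeseries(w, t, np.ones(10)) for w in ("A1", "A2", "A3")]
        layout = PlateLayout(
            entries=[LayoutEntry(w, None, "citrulline", None, None, "blank")
                     for w in ("A1", "A2", "A3")]
        )
        assert preprocess_pipeline(traces, layout) == []

    def test_stage_provenance_recorded(self, rng):
        traces, layout, _ = self._plate(rng)
        curves = preprocess_pipeline(traces, layout)
        for c in curves:
            want = ["blank_corrected"]
            if c.curve_id.construct != "ccdB":
                want.append("control_normalized")
            want += ["clamped", "rebased", "smoothed", "averaged"]
            assert list(c.stages) == want

    def test_curves_start_near_one_unit(self, rng):
        # rebase pins values[0] to 1 exactly; the subsequent smoothing pass
        # re-estimates the end point from the terminal window, so on noisy
        # wells it moves by the order of the local noise (here sd 10 signal
        # units against K = 1000)
        traces, layout, _ = self._plate(rng)
        for c in preprocess_pipeline(traces, layout):
            assert c.values[0] == pytest.approx(1.0, abs=10.0)

    def test_unaveraged_pipeline_keeps_technical_replicates(self, rng):
        traces, layout, _ = self._plate(rng)
        curves = preprocess_pipeline(traces, layout, average=False)
        assert len(curves) == 18
        assert all(c.curve_id.tech_replicate is not None for c in curves)

    def test_missing_blank_medium_is_an_error(self):
        t = np.arange(10) / 6
        traces = [WellTimeseries("A1", t, np.ones(10))]
        layout = PlateLayout(entries=[LayoutEntry("A1", "AtLHT1", "ammonium", 1, 1)])
        with pytest.raises(ValueError, match="blank"):
            preprocess_pipeline(traces, layout, control_construct=None)
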