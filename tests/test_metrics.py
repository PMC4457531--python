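"""Response parameters: magnitude, peak, latency, duration, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dffpipe import (
    AnalysisWindow,
    compute_params,
    duration,
    latency,
    magnitude,
    normalize_per_animal,
    peak,
    response_start,
    total,
)


def win(onset=8, a=10, b=25, n=40):
    return AnalysisWindow(onset=onset, a=a, b=b, pre_start=0)


def trace_with(values, at, n=40, fill=0.0):
    r = np.full(n, fill)
    r[at : at + len(values)] = values
    return r


class TestMagnitude:
    def test_zero_response(self):
        assert magnitude(np.zeros(40), win()) == 0.0

    def test_constant_window_mean_convention(self):
        r = trace_with([0.01] * 16, at=10)
        assert magnitude(r, win()) == pytest.approx(0.01)

    def test_three_frame_mean(self):
        w = AnalysisWindow(onset=4, a=5, b=7, pre_start=0)
        r = trace_with([0.01, 0.03, 0.02], at=5, n=12)
        assert magnitude(r, w) == pytest.approx(0.02)
        assert total(r, w) == pytest.approx(0.06)
        assert magnitude(r, w) == pytest.approx(total(r, w) / 3)

    def test_sampling_rate_invariance(self):
        """Doubling the frame count of a piecewise-constant trace leaves the
        mean-based magnitude unchanged (the point of using a mean)."""
        w1 = AnalysisWindow(onset=4, a=6, b=11, pre_start=0)
        r1 = trace_with([0.01, 0.02, 0.03, 0.03, 0.02, 0.01], at=6, n=20)
        w2 = AnalysisWindow(onset=8, a=12, b=23, pre_start=0)
        r2 = trace_with(np.repeat(r1[6:12], 2), at=12, n=40)
        assert magnitude(r2, w2) == pytest.approx(magnitude(r1, w1))
        assert total(r2, w2) == pytest.approx(2 * total(r1, w1))


class TestPeak:
    def test_single_maximum(self):
        r = trace_with([0.1, 0.5, 0.2], at=12)
        assert peak(r, win()) == (0.5, 13)

    def test_tie_breaks_to_earlier_frame(self):
        r = trace_with([0.5, 0.1, 0.5], at=12)
        assert peak(r, win())[1] == 12

    def test_all_negative_still_returns_max(self):
        r = np.full(40, -1.0)
        r[15] = -0.2
        assert peak(r, win()) == (-0.2, 15)


class TestLatency:
    def test_interpolated_zero_crossing(self):
        # R(9) = -0.5, R(10) = +0.5, onset 8 -> start 9.5, latency 1.5
        w = AnalysisWindow(onset=8, a=10, b=20, pre_start=0)
        r = np.zeros(40)
        r[9], r[10:21] = -0.5, 0.5
        assert response_start(r, w) == pytest.approx(9.5)
        assert latency(r, w) == pytest.approx(1.5)

    def test_nonnegative_previous_frame_starts_there(self):
        w = AnalysisWindow(onset=8, a=10, b=20, pre_start=0)
        r = np.zeros(40)
        r[10:21] = 0.5  # R(9) = 0 exactly: start is frame 9
        assert response_start(r, w) == 9.0
        assert latency(r, w) == pytest.approx(1.0)

    def test_no_positive_frame_is_undefined_not_error(self):
        r = np.full(40, -0.1)
        assert latency(r, win()) is None

    def test_sub_frame_bounds(self):
        """Interpolated start always lies in [a-1, b]."""
        rng = np.random.default_rng(7)
        w = win()
        for _ in range(100):
            r = rng.normal(0, 1, 40)
            s = response_start(r, w)
            if s is not None:
                assert w.a - 1 <= s <= w.b


class TestDuration:
    def test_clean_pulse(self):
        # R = +1 on frames 15-22 between -1 neighbours: crossings at 14.5
        # and 22.5 give duration 8.0
        w = AnalysisWindow(onset=10, a=15, b=25, pre_start=0)
        r = np.zeros(40)
        r[14], r[15:23], r[23] = -1.0, 1.0, -1.0
        assert duration(r, w, 0.0) == pytest.approx(8.0)

    def test_never_falls_below_threshold_ends_at_b(self):
        w = AnalysisWindow(onset=10, a=15, b=25, pre_start=0)
        r = np.zeros(40)
        r[14] = -1.0
        r[15:26] = 1.0
        assert duration(r, w, 0.0) == pytest.approx(25 - 14.5)

    def test_no_response_is_undefined(self):
        assert duration(np.full(40, -0.1), win(), 0.0) is None

    def test_threshold_above_peak_rejected(self):
        w = AnalysisWindow(onset=10, a=15, b=25, pre_start=0)
        r = trace_with([0.2] * 5, at=15)
        with pytest.raises(ValueError, match="not below the peak"):
            duration(r, w, 0.5)

    def test_params_bundle(self):
        w = AnalysisWindow(onset=10, a=15, b=25, pre_start=0)
        r = np.zeros(40)
        r[14], r[15:23], r[23] = -1.0, 1.0, -1.0
        p = compute_params(r, w)
        assert p.peak_frame == 15 and p.latency == pytest.approx(4.5)
        assert p.duration == pytest.approx(8.0)
        assert p.magnitude == pytest.approx(total(r, w) / 11)


class TestNormalizePerAnimal:
    def test_five_point_example(self):
        out = normalize_per_animal([1, 2, 3, 4, 5])
        np.testing.assert_allclose(out, [-2, -1, 0, 1, 2])

    def test_idempotent_on_normalised_data(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        np.testing.assert_allclose(normalize_per_animal(x), x, atol=1e-9)

    def test_constant_list_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_per_animal([3.0, 3.0, 3.0, 3.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            normalize_per_animal([1.0, 2.0])

    def test_midhinge_convention(self):
        out = normalize_per_animal([1, 2, 3, 4, 5], convention="midhinge")
        np.testing.assert_allclose(out, [-2 / 3, -1 / 3, 0, 1 / 3, 2 / 3])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 2**16),
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 100),
    )
    def test_location_scale_invariance_and_zero_median(self, seed, shift, scale):
        x = np.random.default_rng(seed).normal(0, 1, 11)
        base = normalize_per_animal(x)
        assert np.median(base) == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(
            normalize_per_animal(x * scale + shift), base, atol=1e-7
        )
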