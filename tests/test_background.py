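"""Background estimators: examples, least-squares oracle, and invariants."""

import numpy as np
import pytest

from dffpipe import (
    AnalysisWindow,
    ImageSequence,
    compute_response,
    fit_constant,
    fit_linear,
    fit_lowpass,
    fit_polynomial,
    make_bleaching_curve,
    mask_from_reference,
    SurrogateConfig,
)
from dffpipe.background import fit_background


def normal_equations(t, y, deg):
    """Brute-force least-squares oracle on the raw (unscaled) frame axis."""
    X = np.vander(np.asarray(t, dtype=float), deg + 1, increasing=True)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))


T40 = np.arange(40, dtype=float)


class TestAnalysisWindow:
    def test_one_based_conversion(self):
        w = AnalysisWindow.from_one_based(onset=12, a=15, b=27, pre_start=7)
        assert (w.onset, w.a, w.b, w.pre_start) == (11, 14, 26, 6)

    def test_baseline_excludes_response(self, window):
        idx = window.baseline_frames(40)
        assert set(idx).isdisjoint(range(window.a, window.b + 1))
        assert idx.min() == window.pre_start and idx.max() == 39

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            AnalysisWindow(onset=5, a=10, b=9)
        with pytest.raises(ValueError):
            AnalysisWindow(onset=12, a=10, b=20)  # onset after window start
        with pytest.raises(ValueError):
            AnalysisWindow(onset=5, a=10, b=20, pre_start=10)

    def test_window_outside_sequence_rejected(self, window):
        with pytest.raises(ValueError):
            window.baseline_frames(20)


class TestConstant:
    def test_constant_trace_recovered(self, window):
        m = fit_constant(np.full(40, 3.7), window)
        np.testing.assert_allclose(m.predict(), 3.7)

    def test_mean_of_pre_onset_frames(self):
        win = AnalysisWindow(onset=3, a=5, b=8, pre_start=0, pre_average_width=3)
        trace = np.zeros(12)
        trace[0:3] = [1.0, 2.0, 3.0]  # frames i-n .. i-1
        m = fit_constant(trace, win)
        assert m.predict()[0] == pytest.approx(2.0)

    def test_onset_frame_not_leaked(self):
        win = AnalysisWindow(onset=3, a=5, b=8, pre_start=0, pre_average_width=3)
        trace = np.zeros(12)
        trace[0:3] = 2.0
        trace[3] = 1e6  # onset frame must not enter the average
        assert fit_constant(trace, win).predict()[0] == pytest.approx(2.0)

    def test_window_before_frame_zero_rejected(self):
        win = AnalysisWindow(onset=2, a=5, b=8, pre_start=0, pre_average_width=3)
        with pytest.raises(ValueError):
            fit_constant(np.zeros(12), win)


class TestLowpass:
    def test_constant_trace(self, window):
        m = fit_lowpass(np.full(40, 5.0), window)
        np.testing.assert_allclose(m.predict(), 5.0)

    def test_unit_step_trailing_average(self):
        win = AnalysisWindow(onset=3, a=5, b=8, pre_start=0, lowpass_width=2)
        trace = np.zeros(10)
        trace[5:] = 1.0
        fhat = fit_lowpass(trace, win).predict()
        np.testing.assert_allclose(fhat[:5], 0.0)
        assert fhat[5] == pytest.approx(0.5)
        np.testing.assert_allclose(fhat[6:], 1.0)

    def test_width_one_reproduces_trace(self, rng):
        win = AnalysisWindow(onset=3, a=5, b=8, pre_start=0, lowpass_width=1)
        trace = rng.uniform(0, 10, 12)
        np.testing.assert_array_equal(fit_lowpass(trace, win).predict(), trace)

    def test_prefix_uses_available_samples(self):
        win = AnalysisWindow(onset=3, a=5, b=8, pre_start=0, lowpass_width=4)
        trace = np.array([4.0, 8.0] + [0.0] * 8)
        fhat = fit_lowpass(trace, win).predict()
        assert fhat[0] == pytest.approx(4.0)  # only one sample available
        assert fhat[1] == pytest.approx(6.0)


class TestLinear:
    def test_exact_line_recovered(self, window):
        trace = 2.0 + 3.0 * T40
        m = fit_linear(trace, window)
        alpha, beta = m.coefficients
        assert alpha == pytest.approx(2.0, abs=1e-9)
        assert beta == pytest.approx(3.0, abs=1e-10)
        np.testing.assert_allclose(m.predict(), trace, rtol=1e-10)

    def test_three_point_example(self):
        # baseline y = {0, 1, 5} at t = {0, 1, 2}: OLS gives beta 2.5, alpha -0.5
        win = AnalysisWindow(onset=3, a=3, b=3, pre_start=0)
        trace = np.array([0.0, 1.0, 5.0, 99.0])
        m = fit_linear(trace, win)
        oracle = normal_equations([0, 1, 2], [0.0, 1.0, 5.0], 1)
        np.testing.assert_allclose(m.coefficients, oracle, atol=1e-12)
        assert m.coefficients[1] == pytest.approx(2.5)

    def test_two_points_interpolated(self):
        win = AnalysisWindow(onset=1, a=1, b=2, pre_start=0, pre_average_width=1)
        trace = np.array([1.0, 0.0, 0.0, 7.0])
        m = fit_linear(trace, win)  # baseline frames 0 and 3
        assert m.predict()[0] == pytest.approx(1.0, abs=1e-12)
        assert m.predict()[3] == pytest.approx(7.0, abs=1e-12)

    def test_too_few_baseline_samples(self):
        win = AnalysisWindow(onset=1, a=1, b=3, pre_start=0)
        with pytest.raises(ValueError, match="baseline samples"):
            fit_linear(np.zeros(4), win)


class TestPolynomial:
    def test_exact_cubic_recovered(self, window):
        coef = np.array([5.0, -0.3, 0.02, -1e-4])
        trace = coef[0] + coef[1] * T40 + coef[2] * T40**2 + coef[3] * T40**3
        m = fit_polynomial(trace, window)
        np.testing.assert_allclose(m.coefficients, coef, rtol=1e-8, atol=1e-10)
        idx = window.baseline_frames(40)
        resid = m.predict(idx) - trace[idx]
        assert np.abs(resid).max() <= 1e-8

    def test_double_exponential_fit_close_on_baseline(self, window):
        d = make_bleaching_curve(SurrogateConfig())
        trace = 1000.0 * d
        m = fit_polynomial(trace, window)
        idx = window.baseline_frames(40)
        rel = np.abs(m.predict(idx) - trace[idx]) / trace[idx]
        assert rel.max() < 0.01
        # ... but the generator is NOT in the cubic model class
        assert np.abs(m.predict(idx) - trace[idx]).max() > 0

    def test_too_few_baseline_samples(self):
        win = AnalysisWindow(onset=2, a=2, b=8, pre_start=0)
        with pytest.raises(ValueError, match="baseline samples"):
            fit_polynomial(np.zeros(10), win)


class TestLeastSquaresOracle:
    @pytest.mark.parametrize("deg,fitter", [(1, fit_linear), (3, fit_polynomial)])
    def test_matches_normal_equations_on_random_traces(self, deg, fitter, window, rng):
        idx = window.baseline_frames(40)
        for _ in range(50):
            trace = rng.normal(1000, 50, 40)
            m = fitter(trace, window)
            oracle = normal_equations(idx, trace[idx], deg)
            X = np.vander(T40, deg + 1, increasing=True)
            np.testing.assert_allclose(
                m.predict(), X @ oracle, rtol=1e-8, atol=1e-8 * 1000
            )

    def test_baseline_only_fitting(self, window, rng):
        """Arbitrary perturbation inside [a, b] leaves the fits unchanged."""
        trace = rng.normal(500, 20, 40)
        spiked = trace.copy()
        spiked[window.a : window.b + 1] += rng.uniform(-1e4, 1e4, window.b - window.a + 1)
        for fitter in (fit_constant, fit_linear, fit_polynomial):
            np.testing.assert_array_equal(
                fitter(trace, window).predict(), fitter(spiked, window).predict()
            )

    def test_nested_models_reduce_baseline_residual(self, window, rng):
        idx = window.baseline_frames(40)
        trace = rng.normal(800, 30, 40)
        mses = []
        for fitter in (fit_constant, fit_linear, fit_polynomial):
            fhat = fitter(trace, window).predict()
            mses.append(np.mean((trace[idx] - fhat[idx]) ** 2))
        assert mses[0] >= mses[1] >= mses[2]


class TestComputeResponse:
    @staticmethod
    def _flat_seq(value=100.0, shape=(40, 6, 6)):
        return ImageSequence(frames=np.full(shape, value))

    def test_background_equal_signal_gives_zero(self, window):
        seq = self._flat_seq()
        mask = mask_from_reference(np.arange(36, dtype=float).reshape(6, 6), 0.0)
        resp = compute_response(seq, mask, "constant", window)
        np.testing.assert_allclose(resp.r[:, mask.keep], 0.0, atol=1e-12)

    def test_one_percent_response(self, window):
        arr = np.full((40, 4, 4), 100.0)
        arr[20, 2, 2] = 101.0  # S = 101 over F = 100 -> R = 0.01
        seq = ImageSequence(frames=arr)
        mask = mask_from_reference(np.ones((4, 4)) + np.eye(4), 0.0)
        resp = compute_response(seq, mask, "constant", window)
        assert resp.r[20, 2, 2] == pytest.approx(0.01)

    def test_masked_pixels_are_nan(self, window, small_recording):
        seq, _ = small_recording
        from dffpipe import compute_mask, smooth

        mask = compute_mask(seq, 0.33)
        resp = compute_response(smooth(seq, 2.0), mask, "polynomial", window)
        assert np.isnan(resp.r[:, ~mask.keep]).all()
        assert np.isfinite(resp.r[:, resp.valid]).all()

    def test_nonpositive_background_excluded_and_logged(self, window):
        arr = np.full((40, 4, 4), 100.0)
        arr[:, 1, 3] = -5.0  # constant background -5 at pixel (x=3, y=1)
        seq = ImageSequence(frames=arr)
        mask = mask_from_reference(np.arange(16, dtype=float).reshape(4, 4), 0.0)
        resp = compute_response(seq, mask, "constant", window)
        assert resp.diagnostics["n_excluded_nonpositive_background"] == 1
        assert (3, 1) in resp.diagnostics["excluded_pixels_xy"]
        assert np.isnan(resp.r[:, 1, 3]).all()

    def test_unknown_method_rejected(self, window):
        with pytest.raises(ValueError, match="unknown background method"):
            fit_background(np.zeros(40), window, "spline")
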