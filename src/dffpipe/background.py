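"""Per-pixel background (photobleaching) estimation and ΔF/F extraction.

The fluorescence baseline F that would have been recorded without a neural
response must be estimated from the frames outside the window where a
response can occur.  Four estimators are provided, fitted independently in
every pixel:

constant
    F̂ is the mean of the ``pre_average_width`` frames immediately before
    stimulus onset (frames i-n .. i-1) and is predicted as that constant.
lowpass
    F̂(t) is the trailing moving average of the ``lowpass_width`` most recent
    samples ending at t; before enough samples exist the available prefix is
    averaged.  The response frames deliberately enter this filter — that is
    the reason the method underestimates responses.
linear
    F̂(t) = α + βt, ordinary least squares over the baseline samples only.
polynomial
    F̂(t) = α + βt + γt² + δt³, least squares over the baseline samples; the
    time axis is mapped to [-1, 1] before solving for conditioning and the
    coefficients are reported back in frame units.

Baseline samples are the pre-response frames from a configurable start
offset (the fast initial decay must be discarded) up to the frame before the
response window, plus all frames after it.  The mean conventions divide by
the number of summed terms.

Given F̂ the relative response is R(t) = (S(t) - F̂(t)) / F̂(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io import ImageSequence
from .preprocess import Mask

__all__ = [
    "AnalysisWindow",
    "BackgroundModel",
    "ResponseSequence",
    "fit_constant",
    "fit_lowpass",
    "fit_linear",
    "fit_polynomial",
    "fit_background",
    "compute_response",
    "METHODS",
]

METHODS = ("constant", "lowpass", "linear", "polynomial")


@dataclass(frozen=True)
class AnalysisWindow:
    """Stimulus timing and the frame regions used for background fitting.

    All indices are 0-based internally; use :meth:`from_one_based` for
    configuration values given in the 1-based frame-count convention.

    Parameters
    ----------
    onset
        Stimulus-onset frame index i.
    a, b
        Response window, inclusive on both ends; frames a..b never enter the
        constant/linear/polynomial fits.
    pre_start
        First frame of the pre-response baseline; frames before it (the fast
        initial bleaching decay) are discarded from fitting.
    lowpass_width
        Trailing window length n of the low-pass background, in frames.
    pre_average_width
        Number of pre-onset frames averaged by the constant background.
    """

    onset: int
    a: int
    b: int
    pre_start: int = 0
    lowpass_width: int = 5
    pre_average_width: int = 6

    def __post_init__(self) -> None:
        if not 0 <= self.pre_start:
            raise ValueError("pre_start must be >= 0")
        if not self.a <= self.b:
            raise ValueError("response window requires a <= b")
        if not 0 <= self.onset <= self.a:
            raise ValueError("stimulus onset must lie at or before the response window")
        if self.pre_start > self.a - 1:
            raise ValueError("pre-response baseline must end before the response window")
        if self.lowpass_width < 1:
            raise ValueError("lowpass_width must be >= 1")
        if self.pre_average_width < 1:
            raise ValueError("pre_average_width must be >= 1")

    @classmethod
    def from_one_based(
        cls,
        onset: int,
        a: int,
        b: int,
        pre_start: int = 1,
        **kwargs,
    ) -> "AnalysisWindow":
        """Build a window from 1-based frame numbers (acquisition convention)."""
        return cls(onset=onset - 1, a=a - 1, b=b - 1, pre_start=pre_start - 1, **kwargs)

    def validate_for(self, n_frames: int) -> None:
        if self.b >= n_frames:
            raise ValueError(
                f"response window end {self.b} outside sequence of {n_frames} frames"
            )

    def baseline_frames(self, n_frames: int) -> np.ndarray:
        """Indices of the pre/post-response baseline samples."""
        self.validate_for(n_frames)
        return np.r_[self.pre_start : self.a, self.b + 1 : n_frames]

    def response_frames(self) -> np.ndarray:
        return np.arange(self.a, self.b + 1)


def _scaled_time(n_frames: int) -> tuple[np.ndarray, float, float]:
    """Frame axis mapped affinely onto [-1, 1]: u = (t - c) / s."""
    c = (n_frames - 1) / 2.0
    s = max(c, 1.0)
    t = np.arange(n_frames, dtype=np.float64)
    return (t - c) / s, c, s


def _coef_to_frame_units(coef_scaled: np.ndarray, c: float, s: float) -> np.ndarray:
    """Rewrite p(u), u=(t-c)/s, as a polynomial in t (ascending coefficients)."""
    from math import comb

    deg = coef_scaled.shape[0] - 1
    out = np.zeros_like(coef_scaled)
    for k in range(deg + 1):
        ak = coef_scaled[k] / s**k
        for j in range(k + 1):
            out[j] += ak * comb(k, j) * (-c) ** (k - j)
    return out


class BackgroundModel:
    """A fitted per-pixel background with a method tag; predicts F̂(t).

    ``predict()`` returns F̂ at every frame of the fitted sequence with the
    same trailing (pixel) shape as the fitted traces; ``predict(t)`` at
    selected integer frames.
    """

    def __init__(
        self,
        method: str,
        n_frames: int,
        *,
        value: np.ndarray | float | None = None,
        coef_scaled: np.ndarray | None = None,
        center: float | None = None,
        scale: float | None = None,
        trace: np.ndarray | None = None,
        width: int | None = None,
    ) -> None:
        self.method = method
        self.n_frames = int(n_frames)
        self._value = value
        self._coef_scaled = coef_scaled
        self._center = center
        self._scale = scale
        self._trace = trace
        self.width = width

    @property
    def coefficients(self) -> np.ndarray:
        """Polynomial coefficients in frame units, ascending (α, β, γ, δ)."""
        if self._coef_scaled is None:
            raise AttributeError(f"{self.method} background has no coefficients")
        return _coef_to_frame_units(self._coef_scaled, self._center, self._scale)

    def predict(self, t: np.ndarray | None = None) -> np.ndarray:
        if t is None:
            t = np.arange(self.n_frames)
        t = np.asarray(t)
        if self.method == "constant":
            value = np.asarray(self._value)
            return np.broadcast_to(value, t.shape + value.shape).copy()
        if self.method == "lowpass":
            return _trailing_mean(self._trace, self.width)[t]
        # linear / polynomial: Horner on the scaled axis
        u = (t.astype(np.float64) - self._center) / self._scale
        coef = self._coef_scaled
        extra = (1,) * (coef.ndim - 1)
        u = u.reshape(u.shape + extra)
        out = np.zeros(u.shape[: t.ndim] + coef.shape[1:], dtype=np.float64)
        for k in range(coef.shape[0] - 1, -1, -1):
            out = out * u + coef[k]
        return out


def _trailing_mean(trace: np.ndarray, n: int) -> np.ndarray:
    """Mean of the up-to-n most recent samples ending at each t (prefix truncated)."""
    trace = np.asarray(trace, dtype=np.float64)
    if n == 1:
        return trace.copy()
    c = np.cumsum(trace, axis=0)
    T = trace.shape[0]
    t = np.arange(T)
    lo = np.maximum(t + 1 - n, 0)
    counts = (t + 1 - lo).astype(np.float64)
    shape = (T,) + (1,) * (trace.ndim - 1)
    sums = c - np.where((lo > 0).reshape(shape), c[np.maximum(lo - 1, 0)], 0.0)
    return sums / counts.reshape(shape)


def _as_time_major(trace: np.ndarray) -> np.ndarray:
    arr = np.asarray(trace, dtype=np.float64)
    if arr.ndim < 1:
        raise ValueError("trace must have a time axis")
    return arr


def fit_constant(trace: np.ndarray, win: AnalysisWindow) -> BackgroundModel:
    """Mean of the pre_average_width frames immediately before stimulus onset.

    Uses frames onset-n .. onset-1 — strictly pre-onset, so the onset frame
    never leaks into the baseline.
    """
    arr = _as_time_major(trace)
    n = win.pre_average_width
    if win.onset - n < 0:
        raise ValueError(
            f"pre-onset averaging window ({n} frames) extends before frame 0"
        )
    value = arr[win.onset - n : win.onset].mean(axis=0)
    return BackgroundModel("constant", arr.shape[0], value=value)


def fit_lowpass(trace: np.ndarray, win: AnalysisWindow) -> BackgroundModel:
    """Trailing moving average of the lowpass_width most recent samples."""
    arr = _as_time_major(trace)
    return BackgroundModel(
        "lowpass", arr.shape[0], trace=arr.copy(), width=win.lowpass_width
    )


def _fit_poly(trace: np.ndarray, win: AnalysisWindow, deg: int) -> BackgroundModel:
    arr = _as_time_major(trace)
    T = arr.shape[0]
    idx = win.baseline_frames(T)
    if idx.size < deg + 1:
        raise ValueError(
            f"degree-{deg} background needs >= {deg + 1} baseline samples, "
            f"got {idx.size}"
        )
    if np.unique(idx).size < deg + 1:
        raise ValueError("baseline samples at too few distinct time points")
    u, c, s = _scaled_time(T)
    X = np.vander(u[idx], deg + 1, increasing=True)
    y = arr[idx].reshape(idx.size, -1)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < deg + 1:
        raise ValueError("rank-deficient design: baseline times are degenerate")
    coef = coef.reshape((deg + 1,) + arr.shape[1:])
    method = "linear" if deg == 1 else "polynomial"
    return BackgroundModel(method, T, coef_scaled=coef, center=c, scale=s)


def fit_linear(trace: np.ndarray, win: AnalysisWindow) -> BackgroundModel:
    """Least-squares line over the pre/post-response baseline samples."""
    return _fit_poly(trace, win, 1)


def fit_polynomial(trace: np.ndarray, win: AnalysisWindow) -> BackgroundModel:
    """Least-squares cubic over the pre/post-response baseline samples."""
    return _fit_poly(trace, win, 3)


FITTERS: dict[str, Callable[[np.ndarray, AnalysisWindow], BackgroundModel]] = {
    "constant": fit_constant,
    "lowpass": fit_lowpass,
    "linear": fit_linear,
    "polynomial": fit_polynomial,
}


def fit_background(
    trace: np.ndarray, win: AnalysisWindow, method: str
) -> BackgroundModel:
    try:
        fitter = FITTERS[method]
    except KeyError:
        raise ValueError(f"unknown background method {method!r}; choose from {METHODS}")
    return fitter(trace, win)


@dataclass
class ResponseSequence:
    """Per-pixel ΔF/F traces R(t) with the mask of valid pixels.

    Masked pixels and pixels whose fitted background is non-positive at any
    frame carry NaN; the latter are counted in ``diagnostics``.
    """

    r: np.ndarray  # (t, h, w), NaN outside valid pixels
    mask: Mask
    window: AnalysisWindow
    method: str
    diagnostics: dict

    @property
    def valid(self) -> np.ndarray:
        """Pixels that are kept by the mask and have a positive background."""
        return self.mask.keep & ~np.isnan(self.r).any(axis=0)

    def roi_trace(self) -> np.ndarray:
        """Mean R(t) over all valid pixels (whole-image ROI)."""
        flat = self.r.reshape(self.r.shape[0], -1)
        v = self.valid.ravel()
        if not v.any():
            raise ValueError("no valid pixels to average")
        return flat[:, v].mean(axis=1)


def compute_response(
    seq: ImageSequence, mask: Mask, method: str, win: AnalysisWindow
) -> ResponseSequence:
    """ΔF/F per kept pixel: R(t) = (S(t) - F̂(t)) / F̂(t).

    Pixels where the fitted background is <= 0 at any frame are excluded and
    recorded in the diagnostics (never silently zeroed).
    """
    win.validate_for(seq.n_frames)
    T, h, w = seq.frames.shape
    if mask.keep.shape != (h, w):
        raise ValueError("mask shape does not match the sequence")
    flat = seq.frames.reshape(T, h * w)
    keep_idx = np.flatnonzero(mask.keep.ravel())
    traces = flat[:, keep_idx]
    model = fit_background(traces, win, method)
    fhat = model.predict()
    bad = (fhat <= 0).any(axis=0)
    r = np.full((T, h * w), np.nan)
    good = keep_idx[~bad]
    r[:, good] = (traces[:, ~bad] - fhat[:, ~bad]) / fhat[:, ~bad]
    bad_rc = np.unravel_index(keep_idx[bad], (h, w))
    diagnostics = {
        "method": method,
        "n_masked": int(h * w - keep_idx.size),
        "n_excluded_nonpositive_background": int(bad.sum()),
        "excluded_pixels_xy": [
            (int(x), int(y)) for y, x in zip(*bad_rc)
        ][:1000],
    }
    return ResponseSequence(
        r=r.reshape(T, h, w),
        mask=mask,
        window=win,
        method=method,
        diagnostics=diagnostics,
    )
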