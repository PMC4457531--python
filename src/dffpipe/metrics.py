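"""Scalar parameters of a ΔF/F response trace.

From R(t) and the response window [a, b] we reduce each trace (per pixel, or
averaged over an ROI) to: the magnitude A (mean ΔF/F over the window — a
mean rather than a sum so the value is independent of the sampling rate),
the peak value and frame, the latency from stimulus onset to response start,
and the duration from start to end.

Start and end are located at sub-frame resolution by linear interpolation:
if a* is the first frame in the window with R > 0 and R(a*-1) < 0, the start
is the zero crossing

    start = (a* - 1) - R(a* - 1) / (R(a*) - R(a* - 1)),

which lies between a*-1 and a*.  If R(a*-1) >= 0 the start is a*-1 exactly.
The end is the symmetric crossing where R first falls below the end
threshold θ after the peak.  A trace that never rises above zero inside the
window has no response: latency and duration are ``None``, not an error.

Per-animal normalisation subtracts the median and divides by the average of
the two quartile distances to the median, (Q3 - Q1)/2 — a robust scale that
is insensitive to outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .background import AnalysisWindow

__all__ = [
    "ResponseParams",
    "magnitude",
    "total",
    "peak",
    "response_start",
    "latency",
    "duration",
    "compute_params",
    "normalize_per_animal",
]


@dataclass
class ResponseParams:
    """The scalar parameters extracted from one response trace."""

    magnitude: float
    total: float
    peak_value: float
    peak_frame: int
    latency: float | None
    duration: float | None
    end_threshold: float


def _window_slice(r: np.ndarray, win: AnalysisWindow) -> np.ndarray:
    r = np.asarray(r, dtype=np.float64)
    win.validate_for(r.shape[0])
    return r[win.a : win.b + 1]


def magnitude(r: np.ndarray, win: AnalysisWindow) -> float | np.ndarray:
    """Mean ΔF/F over the response window (divisor = number of frames)."""
    return _window_slice(r, win).mean(axis=0)


def total(r: np.ndarray, win: AnalysisWindow) -> float | np.ndarray:
    """Summed ΔF/F over the response window (sampling-rate dependent)."""
    return _window_slice(r, win).sum(axis=0)


def peak(r: np.ndarray, win: AnalysisWindow) -> tuple[float, int]:
    """Maximum R inside the window and its frame; earliest frame on ties."""
    seg = _window_slice(r, win)
    i = int(np.argmax(seg))  # argmax returns the first maximum
    return float(seg[i]), win.a + i


def response_start(
    r: np.ndarray, win: AnalysisWindow
) -> float | None:
    """Sub-frame start of the response, or None when R <= 0 throughout."""
    r = np.asarray(r, dtype=np.float64)
    win.validate_for(r.shape[0])
    pos = np.flatnonzero(r[win.a : win.b + 1] > 0)
    if pos.size == 0:
        return None
    astar = win.a + int(pos[0])
    if astar == 0:
        return 0.0
    prev = r[astar - 1]
    if prev >= 0:
        return float(astar - 1)
    return (astar - 1) - prev / (r[astar] - prev)


def latency(
    r: np.ndarray, win: AnalysisWindow, onset: int | None = None
) -> float | None:
    """Frames from stimulus onset to response start (sub-frame), or None."""
    if onset is None:
        onset = win.onset
    if onset > win.a:
        raise ValueError("stimulus onset must not lie after the response window")
    start = response_start(r, win)
    if start is None:
        return None
    return start - onset


def duration(
    r: np.ndarray, win: AnalysisWindow, end_threshold: float = 0.0
) -> float | None:
    """Frames from response start to the first fall below θ after the peak.

    If R stays above θ to the end of the window the end is taken at b.
    Returns None when there is no response; raises when θ is at or above the
    peak (degenerate threshold).
    """
    if end_threshold < 0:
        raise ValueError("end threshold must be >= 0")
    r = np.asarray(r, dtype=np.float64)
    start = response_start(r, win)
    if start is None:
        return None
    peak_value, peak_frame = peak(r, win)
    if end_threshold >= peak_value:
        raise ValueError(
            f"end threshold {end_threshold} is not below the peak {peak_value}"
        )
    end = float(win.b)
    for t in range(peak_frame + 1, win.b + 1):
        if r[t] < end_threshold:
            prev = r[t - 1]
            end = (t - 1) + (prev - end_threshold) / (prev - r[t])
            break
    return end - start


def compute_params(
    r: np.ndarray,
    win: AnalysisWindow,
    *,
    end_threshold: float = 0.0,
    onset: int | None = None,
) -> ResponseParams:
    """All scalar parameters of one trace; latency/duration None if no response."""
    pv, pf = peak(r, win)
    lat = latency(r, win, onset)
    if lat is None or end_threshold >= pv:
        dur = None
    else:
        dur = duration(r, win, end_threshold)
    return ResponseParams(
        magnitude=float(magnitude(r, win)),
        total=float(total(r, win)),
        peak_value=pv,
        peak_frame=pf,
        latency=lat,
        duration=dur,
        end_threshold=float(end_threshold),
    )


def normalize_per_animal(
    values: np.ndarray, convention: str = "semi_iqr"
) -> np.ndarray:
    """Robust per-animal normalisation: (x - median) / s.

    ``convention`` selects the scale s: ``"semi_iqr"`` (default) uses
    (Q3 - Q1)/2, the average distance of the two quartiles from the median;
    ``"midhinge"`` uses (Q1 + Q3)/2.  Quartiles interpolate linearly between
    order statistics.  The output median is 0; the result is invariant to
    adding a constant and (for semi_iqr) to positive rescaling.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError("need at least 3 values from one animal")
    med = np.median(arr)
    q1, q3 = np.percentile(arr, [25, 75])
    if convention == "semi_iqr":
        s = (q3 - q1) / 2.0
    elif convention == "midhinge":
        s = (q1 + q3) / 2.0
    else:
        raise ValueError(f"unknown quartile convention {convention!r}")
    if s == 0:
        raise ValueError("degenerate distribution: zero spread")
    return (arr - med) / s
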