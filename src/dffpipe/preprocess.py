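"""Spatial smoothing and automatic tissue masking.

Each frame is convolved with a unit-sum Gaussian kernel; because the kernel
integrates to one, smoothing only redistributes intensity between pixels and
the per-frame total signal is conserved.  At image borders the frame is
extended by half-sample symmetric reflection, which keeps the conservation
exact for a symmetric kernel (per-pixel kernel renormalisation, a common
alternative, leaks mass at corners).

Masking removes pixels outside the neural tissue by thresholding the
normalised intensity of a reference image: a pixel S is kept iff

    (S - S_min) / (S_max - S_min) >= T,

with the extremes taken over the reference image.  The reference is the
temporal mean of the raw sequence, which is robust to single-frame noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .io import ImageSequence

__all__ = [
    "SmoothingConfig",
    "Mask",
    "smooth",
    "compute_mask",
    "mask_from_reference",
    "snr_vs_filter_width",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Gaussian smoothing parameters.

    ``sigma`` is the kernel standard deviation in pixels (0 = identity);
    ``truncate`` is the kernel support radius in units of sigma.
    """

    sigma: float = 2.0
    truncate: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.truncate <= 0:
            raise ValueError("truncate must be > 0")


@dataclass
class Mask:
    """Boolean grid of analysed pixels plus the thresholding provenance."""

    keep: np.ndarray  # bool, shape (h, w); True = analysed
    threshold: float
    s_min: float
    s_max: float

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def write_tiff(self, path: str | Path) -> Path:
        """Export as a single-page 8-bit TIFF (kept = 255)."""
        path = Path(path)
        tifffile.imwrite(
            path, (self.keep * np.uint8(255)), photometric="minisblack"
        )
        return path

    def write_csv(self, path: str | Path) -> Path:
        """Export as a 0/1 integer grid, one row per image row."""
        path = Path(path)
        np.savetxt(path, self.keep.astype(int), fmt="%d", delimiter=",")
        return path


def smooth(
    seq: ImageSequence, cfg: SmoothingConfig | float | None = None
) -> ImageSequence:
    """Convolve every frame with a unit-sum Gaussian kernel of width sigma.

    ``cfg`` may be a :class:`SmoothingConfig` or a bare sigma.  Sigma 0
    returns an identical copy.  Reflective boundary handling makes the
    per-frame total intensity exactly conserved.
    """
    if cfg is None:
        cfg = SmoothingConfig()
    elif not isinstance(cfg, SmoothingConfig):
        cfg = SmoothingConfig(sigma=float(cfg))
    if cfg.sigma == 0:
        return seq.copy_with(seq.frames.copy())
    out = ndimage.gaussian_filter(
        seq.frames,
        sigma=(0.0, cfg.sigma, cfg.sigma),
        mode="reflect",
        truncate=cfg.truncate,
    )
    return seq.copy_with(out)


def mask_from_reference(ref: np.ndarray, threshold: float = 0.33) -> Mask:
    """Threshold a normalised reference image: keep iff (S-min)/(max-min) >= T."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    ref = np.asarray(ref, dtype=np.float64)
    s_min = float(ref.min())
    s_max = float(ref.max())
    if s_max == s_min:
        raise ValueError("degenerate intensity range: reference image is flat")
    keep = (ref - s_min) / (s_max - s_min) >= threshold
    if not keep.any():
        raise ValueError("unusable recording: no pixel reaches the mask threshold")
    return Mask(keep=keep, threshold=float(threshold), s_min=s_min, s_max=s_max)


def compute_mask(seq: ImageSequence, threshold: float = 0.33) -> Mask:
    """Threshold the normalised temporal-mean image to exclude non-tissue.

    Raises on a flat reference image (``degenerate intensity range``) and on
    a mask that keeps no pixel (the recording is unusable).
    """
    return mask_from_reference(seq.frames.mean(axis=0), threshold)


def snr_vs_filter_width(
    seq: ImageSequence,
    sigmas: Sequence[float],
    window,
    *,
    pixel: tuple[int, int] | None = None,
    truncate: float = 3.0,
) -> list[tuple[float, float]]:
    """Signal-to-noise ratio of one pixel's response as a function of sigma.

    For each filter width the sequence is smoothed, the cubic-polynomial
    background is fitted to the pixel's baseline samples, and the SNR is the
    peak ΔF/F inside the response window divided by the standard deviation of
    the ΔF/F residual on the baseline frames.  A zero-variance residual is
    reported as ``inf``.

    ``pixel`` is (x, y) = (column, row); default is the image centre.
    """
    from .background import fit_polynomial  # local import to avoid a cycle

    if len(sigmas) == 0:
        raise ValueError("need at least one sigma")
    if pixel is None:
        pixel = (seq.w // 2, seq.h // 2)
    x, y = pixel
    out: list[tuple[float, float]] = []
    baseline = window.baseline_frames(seq.n_frames)
    resp = window.response_frames()
    for s in sigmas:
        sm = smooth(seq, SmoothingConfig(sigma=float(s), truncate=truncate))
        trace = sm.pixel_trace(x, y)
        model = fit_polynomial(trace, window)
        fhat = model.predict()
        r = (trace - fhat) / fhat
        peak = float(r[resp].max())
        sd = float(r[baseline].std())
        snr = float("inf") if sd == 0 else peak / sd
        out.append((float(s), snr))
    return out
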