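"""Synthetic wide-field recordings with known bleaching, response, and noise.

A surrogate recording mimics the structure of a real moth-brain sequence:

* a static anatomical background image B(x, y): a positive pedestal, one
  broad central "tissue" blob and a seeded scatter of smaller fluorescent
  blobs;
* multiplicative photobleaching D(t) = α₁ e^{λ₁ t̃} + α₂ e^{λ₂ t̃} over
  normalised time t̃ ∈ [0, 1], tuned so a fast component dies within the
  first second and a slow component removes a large part of the signal over
  the recording, normalised to D(0) = 1;
* an additive stimulus response: a Gaussian-in-time bump g(t) of width σ_r
  (in normalised time) centred at frame μ, injected inside a spatial disc
  and scaled by M × range, where range is the difference between the spatial
  means of the first and last noiseless frames;
* i.i.d. Gaussian pixel noise with σ_n = L × range.

Because the bleaching is a genuine double exponential it is *not* in the
cubic model class: the polynomial estimator shows a small but nonzero
baseline residual, which keeps the generator independent of the estimators
it is used to test.  Everything is driven by a single integer seed; the same
seed and config reproduce the recording bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import ImageSequence

__all__ = [
    "SurrogateConfig",
    "make_bleaching_curve",
    "make_response_profile",
    "make_background_image",
    "generate_recording",
    "generate_dataset",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Ground-truth parameters of one synthetic recording.

    ``bleach_rates`` are per unit normalised time (the whole recording maps
    to [0, 1]); both must be <= 0.  ``response_sigma`` is likewise in
    normalised time: 0.04 on a 40-frame recording is about 1.6 frames, i.e.
    a plausible sub-second calcium transient at 4 Hz.  ``magnitude`` M scales
    the response as M × range with range the drop of the spatial-mean
    intensity over the recording, and ``noise_level`` L sets the pixel noise
    to σ_n = L × range.
    """

    n_frames: int = 40
    width: int = 320
    height: int = 240
    frame_rate: float = 4.0
    bleach_amplitudes: tuple[float, float] = (0.05, 0.95)
    bleach_rates: tuple[float, float] = (-80.0, -0.45)
    response_center: int = 20
    response_sigma: float = 0.04
    magnitude: float = 0.02
    noise_level: float = 0.05
    region_radius: float | None = None  # pixels; default min(w, h) / 5
    pedestal: float = 1000.0
    tissue_amplitude: float = 1500.0
    n_blobs: int = 25
    blob_amplitude: tuple[float, float] = (200.0, 1200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if any(l > 0 for l in self.bleach_rates):
            raise ValueError("bleaching rates must be <= 0 (decay)")
        if self.response_sigma <= 0:
            raise ValueError("response_sigma must be > 0")
        if not 0 <= self.response_center < self.n_frames:
            raise ValueError("response centre must lie inside the recording")
        if self.magnitude < 0 or self.noise_level < 0:
            raise ValueError("magnitude and noise level must be >= 0")

    @property
    def radius(self) -> float:
        if self.region_radius is not None:
            return float(self.region_radius)
        return min(self.width, self.height) / 5.0


def make_bleaching_curve(cfg: SurrogateConfig) -> np.ndarray:
    """Double-exponential decay over the recording, normalised to D(0) = 1."""
    t = np.arange(cfg.n_frames) / (cfg.n_frames - 1)
    d = np.zeros(cfg.n_frames)
    for a, l in zip(cfg.bleach_amplitudes, cfg.bleach_rates):
        d += a * np.exp(l * t)
    if (d <= 0).any():
        raise ValueError("bleaching curve must be strictly positive")
    return d / d[0]


def make_response_profile(cfg: SurrogateConfig) -> np.ndarray:
    """Gaussian-in-time bump peaking (value 1) at the response-centre frame."""
    t = np.arange(cfg.n_frames) / (cfg.n_frames - 1)
    mu = cfg.response_center / (cfg.n_frames - 1)
    return np.exp(-((t - mu) ** 2) / (2 * cfg.response_sigma**2))


def make_background_image(
    cfg: SurrogateConfig, rng: np.random.Generator
) -> np.ndarray:
    """Static anatomical image: pedestal + central tissue blob + seeded blobs."""
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    s0 = 0.35 * min(w, h)
    img = cfg.pedestal + cfg.tissue_amplitude * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s0**2)
    )
    lo, hi = cfg.blob_amplitude
    for _ in range(cfg.n_blobs):
        bx = rng.uniform(0, w - 1)
        by = rng.uniform(0, h - 1)
        amp = rng.uniform(lo, hi)
        bs = rng.uniform(0.05, 0.2) * min(w, h)
        img += amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * bs**2))
    return img


def response_region(cfg: SurrogateConfig) -> np.ndarray:
    """Boolean (h, w) disc centred in the image where the response is injected."""
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= cfg.radius**2


def generate_recording(
    cfg: SurrogateConfig, rng: np.random.Generator | None = None
) -> tuple[ImageSequence, dict]:
    """One synthetic recording plus its full ground truth.

    frames(t) = B·D(t) + region·M·range·g(t) + ε,  ε ~ N(0, (L·range)²) iid.

    ``range`` is the spatial-mean drop between first and last *noiseless*
    frames.  Negative values from noise are kept in the working array (they
    are only ever clipped at 16-bit TIFF export).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    background = make_background_image(cfg, rng)
    d = make_bleaching_curve(cfg)
    g = make_response_profile(cfg)
    region = response_region(cfg)
    noiseless = background[None, :, :] * d[:, None, None]
    rng_range = float(noiseless[0].mean() - noiseless[-1].mean())
    response = (
        cfg.magnitude * rng_range * g[:, None, None] * region[None, :, :]
    )
    sigma_n = cfg.noise_level * rng_range
    frames = noiseless + response
    if sigma_n > 0:
        frames = frames + rng.normal(0.0, sigma_n, size=frames.shape)
    seq = ImageSequence(
        frames=frames,
        frame_rate=cfg.frame_rate,
        source_id=f"surrogate-seed{cfg.seed}",
    )
    ground_truth = {
        "config": cfg,
        "background": background,
        "bleaching": d,
        "response_profile": g,
        "region": region,
        "range": rng_range,
        "magnitude": cfg.magnitude,
        "noise_sigma": sigma_n,
        "true_dff": response / noiseless,
    }
    return seq, ground_truth


def generate_dataset(
    configs: Sequence[SurrogateConfig],
    labels: Sequence[str],
    n_per_class: int = 20,
    seed: int = 0,
    blank: bool = False,
):
    """A labelled multi-class set of recordings for the evaluation sweeps.

    One config per class; each recording gets a fresh sub-seed drawn from
    ``seed`` (reproducible), a unique recording id, and its own animal id.
    Returns a list of :class:`dffpipe.evaluate.LabeledRecording`.
    """
    from .evaluate import LabeledRecording

    if len(configs) != len(labels):
        raise ValueError("configs and labels must have the same length")
    master = np.random.default_rng(seed)
    out = []
    k = 0
    for cfg, label in zip(configs, labels):
        for _ in range(n_per_class):
            sub = int(master.integers(0, 2**31 - 1))
            rec_cfg = replace(cfg, seed=sub)
            seq, truth = generate_recording(rec_cfg)
            out.append(
                LabeledRecording(
                    seq=seq,
                    label=str(label),
                    animal_id=f"animal-{k:03d}",
                    recording_id=f"rec-{k:03d}",
                    blank=blank,
                    ground_truth=truth,
                )
            )
            k += 1
    return out
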