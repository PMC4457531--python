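"""Canonical surrogate experiments for the four-method comparison.

These are the reproducible, seeded experiments behind the package's own
evaluation of the background estimators:

* :func:`mse_ordering_experiment` — background-fit MSE of all methods on a
  set of blank (response-free) surrogate recordings run through the full
  pipeline (smooth, mask, fit), where the expected quality ordering is
  constant worst, then low-pass, then linear, then polynomial;
* :func:`magnitude_sweep_experiment` — stimulus-detection AUC of every
  method as the injected response magnitude M grows from undetectable to
  strong at fixed noise;
* :func:`noise_sweep_experiment` — background-fit MSE of every method as the
  noise level L grows over orders of magnitude.  The recordings are held
  fixed across noise levels (same seeds) and the pixel set is a fixed
  tissue mask computed from the ground-truth background image, so the sweep
  isolates the effect of the noise on the estimators from mask jitter;
* :func:`null_experiment` — AUC when the two "classes" are generated from
  identical configurations: every method should sit near chance;
* :func:`parameter_recovery_experiment` — with the ground truth known and
  no noise, how exactly the polynomial method recovers the response peak
  frame, onset and magnitude.

The default geometry for the batch experiments is 64×48 px × 40 frames, a
scaled-down version of the 320×240 recordings the generator defaults to;
the ΔF/F scale, bleaching and noise model are unchanged by the scaling.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .background import METHODS, AnalysisWindow, compute_response, fit_background
from .evaluate import background_fit_mse, compare_methods
from .metrics import compute_params
from .preprocess import compute_mask, mask_from_reference, smooth
from .surrogate import SurrogateConfig, generate_dataset, generate_recording

__all__ = [
    "DEFAULT_WINDOW",
    "SMALL_GEOMETRY",
    "mse_ordering_experiment",
    "magnitude_sweep_experiment",
    "noise_sweep_experiment",
    "null_experiment",
    "parameter_recovery_experiment",
]

#: Analysis window matching the surrogate defaults: stimulus onset at frame
#: 11 (0-based; frame 12 as acquired), response window 14..26 around the
#: frame-20 response peak, baseline from frame 6 (the fast initial decay of
#: the bleaching is discarded).
DEFAULT_WINDOW = AnalysisWindow(
    onset=11, a=14, b=26, pre_start=6, lowpass_width=5, pre_average_width=5
)

#: Scaled-down frame geometry for the batch experiments.
SMALL_GEOMETRY = {"width": 64, "height": 48}


def _base_config(**overrides) -> SurrogateConfig:
    kw = dict(SMALL_GEOMETRY)
    kw.update(overrides)
    return SurrogateConfig(**kw)


def mse_ordering_experiment(
    *,
    n_recordings: int = 40,
    noise_level: float = 0.05,
    seed: int = 0,
    win: AnalysisWindow = DEFAULT_WINDOW,
    sigma: float = 2.0,
) -> dict[str, float]:
    """Mean background-fit MSE per method on blank surrogate recordings.

    Full pipeline (smooth, per-recording mask, per-pixel fit); MSE over all
    frames since the recordings carry no response.  Returns method -> mean
    MSE in raw intensity units squared.
    """
    cfg = _base_config(magnitude=0.0, noise_level=noise_level)
    recs = generate_dataset([cfg], ["blank"], n_per_class=n_recordings,
                            seed=seed, blank=True)
    report = compare_methods(recs, win, sigma=sigma)
    return {
        m: report["methods"][m]["mse_no_stimulus"]["mean"] for m in METHODS
    }


def magnitude_sweep_experiment(
    *,
    magnitudes: Sequence[float] = (0.0, 0.02, 0.1, 0.5),
    noise_level: float = 0.02,
    n_per_class: int = 20,
    seed: int = 0,
    win: AnalysisWindow = DEFAULT_WINDOW,
    sigma: float = 2.0,
) -> dict[str, list[float]]:
    """Stimulus-detection AUC per method for each injected magnitude M.

    Each sweep point is a fresh two-class set (blank vs response of size M)
    at fixed noise; the stimulated class is the known positive.  Returns
    method -> list of AUCs aligned with ``magnitudes``.
    """
    blank = _base_config(magnitude=0.0, noise_level=noise_level)
    aucs: dict[str, list[float]] = {m: [] for m in METHODS}
    for M in magnitudes:
        recs = generate_dataset(
            [blank, replace(blank, magnitude=M)],
            ["blank", "stim"],
            n_per_class=n_per_class,
            seed=seed,
        )
        report = compare_methods(recs, win, sigma=sigma, positive_label="stim")
        for m in METHODS:
            aucs[m].append(report["methods"][m]["auc"])
    return aucs


def noise_sweep_experiment(
    *,
    noise_levels: Sequence[float] = (0.05, 0.25, 1.0, 5.0, 25.0),
    n_recordings: int = 12,
    seed: int = 0,
    win: AnalysisWindow = DEFAULT_WINDOW,
    sigma: float = 2.0,
    mask_threshold: float = 0.33,
) -> dict[str, list[float]]:
    """Mean background-fit MSE per method at each noise level L.

    The same blank recordings (identical sub-seeds, hence identical
    anatomy) are regenerated at every L; the evaluated pixel set is fixed
    per recording by masking the ground-truth background image, so only the
    noise term varies along the sweep.  Returns method -> list of mean MSEs
    aligned with ``noise_levels``.
    """
    out: dict[str, list[float]] = {m: [] for m in METHODS}
    for L in noise_levels:
        cfg = _base_config(magnitude=0.0, noise_level=L)
        master = np.random.default_rng(seed)
        acc: dict[str, list[float]] = {m: [] for m in METHODS}
        for _ in range(n_recordings):
            sub = int(master.integers(0, 2**31 - 1))
            seq, truth = generate_recording(replace(cfg, seed=sub))
            sm = smooth(seq, sigma)
            mask = mask_from_reference(truth["background"], mask_threshold)
            flat = sm.frames.reshape(sm.n_frames, -1)[:, mask.keep.ravel()]
            for m in METHODS:
                model = fit_background(flat, win, m)
                acc[m].append(
                    float(np.mean(background_fit_mse(flat, model, "no_stimulus", win)))
                )
        for m in METHODS:
            out[m].append(float(np.mean(acc[m])))
    return out


def null_experiment(
    *,
    n_recordings: int = 40,
    noise_level: float = 0.02,
    seed: int = 0,
    win: AnalysisWindow = DEFAULT_WINDOW,
    sigma: float = 2.0,
) -> dict[str, float]:
    """AUC per method when both classes are generated identically.

    ``n_recordings`` is the total (split evenly); labels are arbitrary, so
    a well-behaved method scores near 0.5.
    """
    cfg = _base_config(magnitude=0.0, noise_level=noise_level)
    recs = generate_dataset(
        [cfg, cfg], ["A", "B"], n_per_class=n_recordings // 2, seed=seed
    )
    report = compare_methods(recs, win, sigma=sigma, positive_label="B")
    return {m: report["methods"][m]["auc"] for m in METHODS}


def parameter_recovery_experiment(
    *,
    magnitude: float = 0.02,
    seed: int = 0,
    win: AnalysisWindow = DEFAULT_WINDOW,
    sigma: float = 2.0,
    config: SurrogateConfig | None = None,
) -> dict:
    """Polynomial-method parameter recovery on one noiseless recording.

    Compares the estimated response parameters (from the mean ΔF/F trace
    over the valid response-region pixels) against the same parameters of
    the ground-truth ΔF/F trace.  Uses the generator's full-size default
    geometry (320×240).
    """
    cfg = config or SurrogateConfig(magnitude=magnitude, noise_level=0.0, seed=seed)
    seq, truth = generate_recording(cfg)
    sm = smooth(seq, sigma)
    mask = compute_mask(seq, 0.33)
    resp = compute_response(sm, mask, "polynomial", win)
    sel = (truth["region"] & resp.valid).ravel()
    T = seq.n_frames
    est_trace = resp.r.reshape(T, -1)[:, sel].mean(axis=1)
    true_trace = truth["true_dff"].reshape(T, -1)[:, sel].mean(axis=1)
    est = compute_params(est_trace, win)
    true = compute_params(true_trace, win)
    return {
        "estimated": est,
        "true": true,
        "peak_frame_error": est.peak_frame - true.peak_frame,
        "onset_error_frames": abs(est.latency - true.latency),
        "magnitude_relative_error": abs(est.magnitude - true.magnitude)
        / abs(true.magnitude),
    }
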