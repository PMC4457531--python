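"""Method-comparison framework: background-fit MSE, threshold classifier,
ROC curves and AUC.

Two MSE modes mirror the two ways the background fit is scored: on blank
recordings every frame is used (``no_stimulus``); on stimulated recordings
only the pre/post-baseline frames are used (``outside_response``), because
inside the response window the recorded signal is response plus background.

Stimulus discrimination uses the threshold classifier c(x) = 1 iff x > τ on
(optionally per-animal normalised) response magnitudes.  Sweeping τ over the
observed scores yields the ROC curve; the area under it (trapezoidal rule,
which equals the Mann–Whitney probability that a random positive outscores a
random negative, ties counted half) summarises how well a method's
magnitudes separate the two stimulus classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .background import (
    METHODS,
    AnalysisWindow,
    BackgroundModel,
    compute_response,
    fit_background,
)
from .io import ImageSequence
from .metrics import compute_params, magnitude, normalize_per_animal
from .preprocess import SmoothingConfig, compute_mask, smooth

__all__ = [
    "LabeledMeasurement",
    "LabeledRecording",
    "RocResult",
    "background_fit_mse",
    "classify",
    "roc_curve",
    "compare_methods",
]

MSE_MODES = ("no_stimulus", "outside_response")


@dataclass(frozen=True)
class LabeledMeasurement:
    """One normalised magnitude with its stimulus label."""

    recording_id: str
    animal_id: str
    label: str
    x: float


@dataclass
class LabeledRecording:
    """A recording plus the labels the evaluation needs."""

    seq: ImageSequence
    label: str
    animal_id: str = ""
    recording_id: str = ""
    blank: bool = False  # True: no stimulus was presented
    ground_truth: dict | None = None


@dataclass
class RocResult:
    """ROC curve from a descending threshold sweep, plus its area."""

    thresholds: np.ndarray  # descending; +inf first, -inf last
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def background_fit_mse(
    trace: np.ndarray,
    model: BackgroundModel,
    mode: str,
    win: AnalysisWindow,
) -> float | np.ndarray:
    """Mean squared residual (S - F̂)² over the mode's frame selection.

    ``no_stimulus`` selects every frame of a blank recording;
    ``outside_response`` selects only the pre/post-baseline frames.  Raw
    intensity units squared.
    """
    trace = np.asarray(trace, dtype=np.float64)
    T = trace.shape[0]
    if mode == "no_stimulus":
        idx = np.arange(T)
    elif mode == "outside_response":
        idx = win.baseline_frames(T)
    else:
        raise ValueError(f"unknown MSE mode {mode!r}; choose from {MSE_MODES}")
    if idx.size == 0:
        raise ValueError("empty frame selection for MSE")
    resid = trace[idx] - model.predict(idx)
    return np.mean(resid**2, axis=0)


def classify(x: float, tau: float) -> int:
    """Threshold classifier: 1 iff x > τ (strict)."""
    return int(x > tau)


def roc_curve(
    measurements: Sequence[LabeledMeasurement] | None = None,
    *,
    scores: np.ndarray | None = None,
    labels: Sequence | None = None,
    positive_label=None,
) -> RocResult:
    """ROC from sweeping the classifier threshold over all observed scores.

    Accepts either a list of :class:`LabeledMeasurement` or parallel
    ``scores``/``labels`` arrays.  Exactly two distinct labels are required;
    ``positive_label`` defaults to the lexically larger one.  The curve runs
    from (0, 0) at τ = +inf to (1, 1) at τ = -inf and is non-decreasing in
    both coordinates; the AUC is the trapezoidal area.
    """
    if measurements is not None:
        scores = np.array([m.x for m in measurements], dtype=np.float64)
        labels = [m.label for m in measurements]
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = classes[-1]
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate(([np.inf], uniq, [-np.inf]))
    tpr = np.array([np.mean(pos > t) for t in thresholds])
    fpr = np.array([np.mean(neg > t) for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def _pixel_magnitudes(resp) -> np.ndarray:
    """Per-pixel magnitudes of the valid pixels of a ResponseSequence."""
    a = magnitude(resp.r.reshape(resp.r.shape[0], -1), resp.window)
    return a[resp.valid.ravel()]


def compare_methods(
    recordings: Sequence[LabeledRecording],
    win: AnalysisWindow,
    *,
    methods: Sequence[str] = METHODS,
    sigma: float = 2.0,
    mask_threshold: float = 0.33,
    end_threshold: float = 0.0,
    normalize: bool = False,
    quartile_convention: str = "semi_iqr",
    aggregate: str = "recording",
    positive_label=None,
    stronger_by: str = "polynomial",
    keep_roc: bool = False,
) -> dict:
    """Run the full pipeline with every method and score them side by side.

    Per method and recording: smooth, mask, fit the background per pixel,
    extract ΔF/F, and take the recording's score as the mean per-pixel
    magnitude over valid pixels; latency and duration come from the
    valid-pixel-mean ROI trace.  Background-fit MSE is the per-pixel MSE
    averaged over valid pixels, in ``no_stimulus`` mode for blank recordings
    and ``outside_response`` mode for stimulated ones.

    Scores are optionally normalised per animal and aggregated per animal
    and stimulus (``aggregate="animal"``; default keeps one point per
    recording).  The ROC positive class defaults to the stimulus with the
    larger mean magnitude under ``stronger_by``; that class is also the
    "stronger response subset" used for the magnitude summaries.  The report
    is deterministic given identical input order.
    """
    recordings = list(recordings)
    if len(recordings) == 0:
        raise ValueError("no recordings")
    labels_all = sorted({r.label for r in recordings if not r.blank})
    cfg = SmoothingConfig(sigma=sigma)

    per_method: dict[str, dict] = {
        m: {
            "mse_no_stimulus": [],
            "mse_outside_response": [],
            "scores": [],
            "score_labels": [],
            "score_animals": [],
            "score_ids": [],
            "latency": [],
            "duration": [],
        }
        for m in methods
    }

    for rec in recordings:
        sm = smooth(rec.seq, cfg)
        mask = compute_mask(rec.seq, mask_threshold)
        for m in methods:
            resp = compute_response(sm, mask, m, win)
            d = per_method[m]
            # per-pixel fit MSE averaged over valid pixels
            flat = sm.frames.reshape(sm.n_frames, -1)
            v = resp.valid.ravel()
            model = fit_background(flat[:, v], win, m)
            mode = "no_stimulus" if rec.blank else "outside_response"
            mse = float(np.mean(background_fit_mse(flat[:, v], model, mode, win)))
            d[f"mse_{mode}"].append(mse)
            if not rec.blank:
                d["scores"].append(float(_pixel_magnitudes(resp).mean()))
                d["score_labels"].append(rec.label)
                d["score_animals"].append(rec.animal_id)
                d["score_ids"].append(rec.recording_id)
                params = compute_params(
                    resp.roi_trace(), win, end_threshold=end_threshold
                )
                if params.latency is not None:
                    d["latency"].append(params.latency)
                if params.duration is not None:
                    d["duration"].append(params.duration)

    # decide the positive ("stronger response") class once, from stronger_by
    if positive_label is None and len(labels_all) == 2:
        ref = per_method[stronger_by]
        s = np.asarray(ref["scores"])
        lab = np.asarray(ref["score_labels"])
        means = {c: float(s[lab == c].mean()) for c in labels_all}
        positive_label = max(labels_all, key=lambda c: means[c])

    report: dict = {"positive_label": positive_label, "methods": {}}
    for m in methods:
        d = per_method[m]
        entry: dict = {}
        for mode in MSE_MODES:
            vals = np.asarray(d[f"mse_{mode}"])
            entry[f"mse_{mode}"] = _summary(vals)
        scores = np.asarray(d["scores"], dtype=np.float64)
        labs = np.asarray(d["score_labels"])
        animals = np.asarray(d["score_animals"])
        if scores.size:
            if normalize:
                scores = _normalize_by_animal(scores, animals, quartile_convention)
            if aggregate == "animal":
                scores, labs = _aggregate_by_animal(scores, labs, animals)
            elif aggregate != "recording":
                raise ValueError(f"unknown aggregation {aggregate!r}")
            strong = scores[labs == positive_label]
            entry["magnitude"] = _summary(strong)
            if np.unique(labs).size == 2:
                roc = roc_curve(
                    scores=scores, labels=labs, positive_label=positive_label
                )
                entry["auc"] = roc.auc
                if keep_roc:
                    entry["roc"] = {
                        "thresholds": roc.thresholds.tolist(),
                        "fpr": roc.fpr.tolist(),
                        "tpr": roc.tpr.tolist(),
                    }
        entry["latency_std"] = _std(np.asarray(d["latency"]))
        entry["duration_std"] = _std(np.asarray(d["duration"]))
        report["methods"][m] = entry
    return report


def _summary(vals: np.ndarray) -> dict:
    if vals.size == 0:
        return {"mean": None, "std": None, "n": 0}
    return {
        "mean": float(vals.mean()),
        "std": _std(vals),
        "n": int(vals.size),
    }


def _std(vals: np.ndarray) -> float | None:
    if vals.size < 2:
        return None
    return float(vals.std(ddof=1))


def _normalize_by_animal(
    scores: np.ndarray, animals: np.ndarray, convention: str
) -> np.ndarray:
    out = scores.copy()
    for a in np.unique(animals):
        sel = animals == a
        out[sel] = normalize_per_animal(scores[sel], convention)
    return out


def _aggregate_by_animal(scores, labs, animals):
    """Mean score per (animal, stimulus) pair — avoids pseudo-replication."""
    keys = sorted({(a, l) for a, l in zip(animals, labs)})
    agg_scores, agg_labs = [], []
    for a, l in keys:
        sel = (animals == a) & (labs == l)
        agg_scores.append(float(scores[sel].mean()))
        agg_labs.append(l)
    return np.asarray(agg_scores), np.asarray(agg_labs)
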