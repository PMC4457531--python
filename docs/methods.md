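# Methods

This note documents the models implemented in dffpipe, the parameter choices
that matter, what the surrogate generator does and does not emulate, and the
numerical conventions — in enough detail to reproduce or audit any number
the package prints.

## Signal model and pipeline

A recording is a stack I(t) of w × h intensity frames (16-bit counts,
typically 40 frames at 4 Hz). The analysis assumes the recorded signal in a
pixel is a slowly decaying background (photobleaching) plus, possibly, a
stimulus-evoked transient confined to a known response window [a, b] of
frames, plus noise. All frame indices are 0-based internally; configuration
files accept the 1-based frame numbers used by acquisition software and
convert once at the boundary (`AnalysisWindow.from_one_based`).

### Spatial smoothing

S(t) = I(t) ∗ G_σ with a unit-sum Gaussian kernel, σ in pixels (default 2,
truncated at 3σ). Because the kernel sums to one, smoothing redistributes
intensity without creating or destroying it. **Boundary rule:** frames are
extended by half-sample symmetric reflection (`scipy.ndimage` mode
`"reflect"`). For a symmetric kernel this conserves the per-frame total
exactly (verified to machine precision, including corner impulses); we use
it instead of per-pixel kernel renormalisation because renormalisation
provably leaks mass at corners (1-D counterexample: 3 pixels, kernel
[¼, ½, ¼], impulse at the corner sums to 0.9167 after renormalisation).
σ = 0 is the identity. "σ" always means the standard deviation of the
kernel in pixels.

### Masking

Non-tissue pixels are removed by thresholding a reference image: keep iff
(S − S_min)/(S_max − S_min) ≥ T, default T = 0.33, strict `<` masked. The
reference is the **temporal mean of the raw sequence** — robust to
single-frame noise, and deterministic. A flat reference raises
`degenerate intensity range`; a mask that keeps nothing marks the recording
unusable (error, never silent).

### Background estimators

Fitted per pixel; baseline frames are `pre_start … a−1` plus `b+1 … end`.
`pre_start` (default: frame 6 of 40) exists because the earliest frames
decay faster than any smooth model fits; they are discarded from fitting
but still count in whole-recording error evaluation.

* **constant** — F̂ = mean of the `pre_average_width` (default 5) frames
  `onset−n … onset−1`. Strictly pre-onset: using the onset frame itself
  would leak stimulus into the baseline.
* **low-pass** — F̂(t) = trailing mean of the `lowpass_width` (default 5)
  most recent samples ending at t; for t < n−1 the available prefix is
  averaged (padding would fabricate data). The response frames deliberately
  enter this filter; that is exactly why the method underestimates
  responses.
* **linear** — F̂(t) = α + βt by ordinary least squares on the baseline.
* **polynomial** — cubic by least squares on the baseline. The time axis is
  mapped affinely to [−1, 1] before solving (Vandermonde + `lstsq`);
  coefficients are reported back in frame units. With ≤ 50 frames the raw
  axis would also be solvable, but the scaling keeps the oracle comparison
  in the tests tight at 1e-8.

Division conventions: all "means" divide by the number of summed terms.
Precondition checks: ≥ 2 (linear) / ≥ 4 (cubic) baseline samples, rank
checks, and pre-onset windows that reach before frame 0 raise.

### ΔF/F and response parameters

R(t) = (S(t) − F̂(t)) / F̂(t) per kept pixel. Pixels where F̂(t) ≤ 0 at any
frame are excluded and counted in a diagnostics log — never silently
zeroed. Masked/excluded pixels carry NaN.

* magnitude A = mean R over [a, b] (sampling-rate independent); `total` is
  the sum for those who want it.
* peak = max R in the window, earliest frame on ties.
* response start: first frame a* in [a, b] with R > 0 (strict); if
  R(a*−1) < 0 the start is the interpolated zero crossing
  (a*−1) − R(a*−1)/(R(a*) − R(a*−1)), which lies between a*−1 and a*;
  if R(a*−1) ≥ 0 the start is a*−1 exactly. Latency = start − onset.
  A trace with no positive frame in the window has *no response*: latency
  and duration are None, a result, not an error.
* duration: start to the first interpolated fall below the end threshold θ
  after the peak (θ default 0; θ ≥ peak raises as degenerate); if R stays
  above θ, the end is b.
* per-animal normalisation: (x − median)/s with s = (Q3 − Q1)/2 — the
  average distance of the two quartiles from the median, a robust scale.
  The alternative reading of "average of the two quartiles", the midhinge
  (Q1+Q3)/2, is available via `convention="midhinge"`; the spread reading
  is the default because the operation is meant as an outlier-insensitive
  scale normalisation. Quartiles interpolate linearly between order
  statistics.

### Evaluation

Background-fit MSE = mean (S − F̂)² over either all frames of a blank
recording (`no_stimulus`) or only baseline frames of a stimulated one
(`outside_response`), in raw intensity units squared. The classifier is
c(x) = 1 iff x > τ, strict. The ROC sweeps τ from +∞ down through every
distinct observed score to −∞; the AUC is the trapezoidal area, which
equals the Mann–Whitney pair statistic with ties counted half (asserted to
1e-9 in the tests, and cross-checked against scikit-learn). Score
aggregation defaults to one point per recording; per-animal mean
aggregation (avoids pseudo-replication) and per-animal normalisation are
options. The "stronger response" class for magnitude summaries defaults to
the class with the larger mean magnitude under the polynomial method; the
sweep experiments instead pass the ground-truth stimulated class
explicitly, since auto-selection on null data folds AUCs upward.

## Surrogate generator

Emulates the structure of a real recording:

frames(t) = B(x,y)·D(t) + 1_region(x,y)·M·range·g(t) + ε(x,y,t)

* **B** — pedestal 1000 counts, one broad central tissue blob (amplitude
  1500, σ = 0.35·min(w,h)) plus 25 seeded random blobs (amplitudes
  200–1200, σ 5–20% of min(w,h)). The central blob guarantees the masked
  tissue contains the response region. Default geometry 320×240 × 40
  frames at 4 Hz.
* **D** — double exponential α₁e^{λ₁t̃} + α₂e^{λ₂t̃} on normalised time
  t̃ ∈ [0, 1], normalised to D(0) = 1. Defaults α = (0.05, 0.95),
  λ = (−80, −0.45): a small fast component with ~0.12 s time constant that
  dies within the first second, and a slow component that removes ~36% of
  the signal over 10 s. These coefficients are this package's choice
  (selected in a design study for realistic curvature and a clear
  fast-initial-decay phase); they are not taken from any specific recording.
  Being a true double exponential, D is *not* in the cubic model class, so
  the polynomial estimator keeps a small nonzero residual — the generator
  stays independent of the estimators it tests.
* **g** — Gaussian in time, σ_r = 0.04 in normalised time (≈1.6 frames on
  40 frames, a plausible sub-second transient at 4 Hz; an interpretation
  in frames can be configured), peak value 1 at frame 20.
* **M·range** — response amplitude; range = spatial-mean(first frame) −
  spatial-mean(last frame) of the noiseless sequence. M = 0.02 gives a
  ~1% peak ΔF/F, the scale of a strong antennal-lobe response.
* **ε** — i.i.d. Gaussian, σ_n = L·range (default L = 0.05). Noise may push
  working values below zero; clipping happens only at 16-bit TIFF export.
* Response region: a centred disc of radius min(w,h)/5 (the spatial
  footprint is not otherwise constrained).

Identical seed + config reproduce a recording bit for bit; datasets draw
per-recording sub-seeds from one master generator.

What the generator does **not** emulate: photon shot noise (variance scales
with intensity in real data; here it is additive and homoscedastic), motion
artefacts, dye kinetics, spatially structured noise, and pixel-to-pixel
variation of the bleaching *shape* (D is shared; only the amplitude varies
via B). Tests passing on surrogates therefore demonstrate correctness of
the estimators under the stated model, not robustness to every real-data
pathology.

## Canonical experiments (`dffpipe.experiments`)

Batch experiments run at 64×48 px — a scaled-down version of the default
320×240 geometry chosen as the package's standard experiment size; the
ΔF/F scale, bleaching and noise model are unaffected by frame size, only
the per-recording score noise grows slightly. All experiments take a single
seed. Analysis window: onset 11, response 14–26, baseline from frame 6.

* **MSE ordering** — 40 blank recordings at L = 0.05 through the full
  pipeline; expected: constant > low-pass > linear ≥ polynomial.
* **Magnitude sweep** — M ∈ {0, 0.02, 0.1, 0.5} at L = 0.02, 20 recordings
  per class, known positive class; AUC should rise (to ≥ 0.95 for the
  regression methods) and sit near 0.5 at M = 0.
* **Noise sweep** — L ∈ {0.05, 0.25, 1, 5, 25}; the same recordings
  (identical sub-seeds) are regenerated at each L and evaluated on a fixed
  tissue mask computed from the ground-truth background image. Holding the
  pixel set fixed isolates the estimators from mask jitter: with
  per-recording masks, borderline pixels flip with the noise draw and the
  resulting ±0.2% fluctuations of the constant method's large fixed bias
  would swamp the tiny low-L noise increments being measured. The grid
  starts at L = 0.05 because below that the noise contribution is smaller
  than bias/noise cross terms even on a fixed mask.
* **Null** — two identical classes, 20 + 20 recordings; AUC near 0.5.
* **Parameter recovery** — one noiseless 320×240 recording at M = 0.02,
  polynomial method; estimated vs ground-truth peak frame, onset, and
  magnitude of the response-region mean trace.

## Numerical conventions and edge cases

* Least squares via SVD (`numpy.linalg.lstsq`) on the scaled axis; rank
  deficiency raises rather than returning a minimum-norm fit.
* Peak ties break to the earliest frame; response start/end use strict
  inequalities (R > 0 to start, R < θ to end).
* `std` summaries in comparison reports use ddof = 1; fewer than two values
  give None.
* ROC thresholds include ±∞ sentinels so the curve always starts at (0,0)
  and ends at (1,1); relabelling the classes maps AUC to 1 − AUC exactly.
* TIFF round trips are bit-exact for 16-bit integers; multi-sample (RGB)
  and float TIFFs are rejected, both byte orders and deflate accepted.

## Known limitations

* The latency estimate is the zero crossing of a near-zero trace and is the
  least stable parameter under noise (visible in the worked example).
* The cubic extrapolates into the discarded initial-decay frames; on raw
  (unsmoothed) high-noise data this extrapolation amplifies noise and the
  polynomial's whole-recording MSE then exceeds the linear method's — the
  known failure mode at extreme noise, reproduced in the noise sweep.
* Per-animal normalisation needs ≥ 3 recordings per animal with nonzero
  spread; the comparison framework falls back to raw magnitudes when
  normalisation is disabled.
* No motion correction and no shot-noise model; see the surrogate caveats
  above.
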