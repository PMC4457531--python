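# dffpipe

Per-pixel ΔF/F extraction for wide-field calcium imaging, with four
photobleaching background estimators and a reproducible, ROC-based framework
for comparing them.

Functional calcium imaging of the insect brain (antennal lobe, mushroom
body) produces 16-bit multi-page TIFF stacks — typically 40 frames at 4 Hz —
in which the stimulus-evoked signal is a ~1% (or far smaller) intensity
change riding on a bright, *decaying* background: photobleaching removes a
large fraction of the fluorescence within a single recording. Recovering the
response means estimating, in every pixel, the background trace F̂(t) that
would have been recorded without a response, then computing

    R(t) = (S(t) − F̂(t)) / F̂(t)

where S is the spatially smoothed signal. The package is aimed at
experimenters who want a fully automatic pipeline — no ROI drawing, no
per-recording hand tuning — and at method-minded users who want to quantify
which background model to trust on their data.

## Pipeline

1. **Smoothing** — each frame is convolved with a unit-sum Gaussian kernel
   G_σ (reflective borders, so per-frame total intensity is conserved
   exactly). `snr_vs_filter_width` maps the SNR-vs-σ trade-off.
2. **Masking** — pixels outside the tissue are removed by thresholding the
   normalised temporal-mean image: keep iff (S − S_min)/(S_max − S_min) ≥ T,
   typically T = 0.33.
3. **Background estimation**, per pixel, from frames outside the response
   window [a, b]:
   * *constant* — mean of the n frames immediately before stimulus onset;
   * *low-pass* — trailing moving average of the n most recent frames;
   * *linear* — α + βt, least squares on the pre/post-response baseline;
   * *polynomial* — α + βt + γt² + δt³, least squares on the baseline
     (a cubic approximates the multi-exponential bleaching decay well with
     the few samples available, where explicit multi-exponential fitting is
     ill-conditioned).
4. **Response parameters** — magnitude A = mean R(t) over [a, b]
   (sampling-rate independent), peak value/frame, sub-frame latency and
   duration via linear interpolation of threshold crossings, and robust
   per-animal normalisation (x − median) / ((Q3 − Q1)/2).
5. **Evaluation** — background-fit MSE (on blank recordings, or on baseline
   frames of stimulated ones); the threshold classifier c(x) = 1 iff x > τ
   swept over magnitudes gives ROC curves and AUC as the measure of how well
   each method separates two stimulus classes.

A **surrogate generator** builds recordings with known ground truth — static
anatomical image, double-exponential bleaching D(t) = α₁e^{λ₁t} + α₂e^{λ₂t},
a Gaussian-in-time response (σ = 0.04 in normalised time, centred at frame
20) of magnitude M × bleach-range injected in a spatial region, and Gaussian
noise with σ = L × bleach-range — so every comparison here is reproducible
without external data.

## Worked example

`python examples/01_extract_response.py` (synthetic recording, ~1% injected
response, low noise) prints:

```
recording: 320x240 px, 40 frames @ 4.0 Hz
mask keeps 48086 of 76800 pixels
response-region mean dF/F, polynomial background:
  magnitude  0.00239   (truth 0.00244)
  peak       0.00788 at frame 20 (truth frame 20)
  latency    3.66 frames after stimulus onset (truth 2.00)
```

The magnitude (mean ΔF/F over the response window) is recovered to ~2% and
the peak lands exactly on the injected frame; latency, which depends on a
zero crossing of a near-zero trace, is the noisiest parameter.

`python examples/02_method_comparison.py` (10 blank vs 10 stimulated
surrogate recordings) prints:

```
method           fit MSE   magnitude     AUC
constant        352042.9    -0.12779   1.000
lowpass           3522.9    -0.02292   0.780
linear             166.9    -0.00744   1.000
polynomial           8.4     0.00091   1.000
```

The fit-quality ordering (constant ≫ low-pass ≫ linear > polynomial) is the
package's core result: ignoring bleaching costs five orders of magnitude in
background error, and only the regression methods recover magnitudes close
to the injected scale. The low-pass method's AUC is lowest because its
background absorbs part of the response.

`examples/03_snr_filter_width.py` and `examples/04_surrogate_sweeps.py`
print the SNR-vs-filter-width curve and the magnitude/noise sweeps.

## Command line

```sh
dffpipe simulate -o sims --n 10 --magnitude 0.02        # surrogate TIFFs
dffpipe analyze sims -c run.yaml -o results             # per-recording CSV
dffpipe compare --surrogate-spec spec.yaml -o report.json
dffpipe snr-scan sims/surrogate_000.tif -o snr.csv
```

`analyze` processes every recording without manual intervention, logs
failures instead of dropping them, and exits non-zero on partial success.
All run parameters live in one flat YAML config (frame numbers 1-based, as
acquired).

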