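# Methods

This note documents the models, algorithms and design choices behind
`pulsebp`: what each stage computes, which parameters matter, what the
synthetic benchmark does and does not demonstrate.

## Signal model and simulator

The simulator emulates a bedside acquisition of three synchronized channels
at a common rate (default 125 Hz, a typical monitor rate): ECG, finger PPG,
and invasive arterial pressure (ABP, in mmHg).  Per beat `k`:

- **Pressures.** SBP and DBP follow independent random walks reflected
  inside configured ranges (defaults [100, 160] and [60, 100] mmHg,
  step SD 3 mmHg/beat — the upper end of physiological beat-to-beat
  variability, so that even a two-minute record covers a useful pressure
  range).  SBP is forced at least 5 mmHg above DBP.  Mean arterial pressure
  uses the conventional one-third rule, `MAP = DBP + (SBP − DBP)/3`.
- **Transit time.** `PTT[ms] = a − b·MAP` with defaults `a = 350 ms`,
  `b = 1.2 ms/mmHg` — a monotone-decreasing law in the physiological range
  (206–262 ms across the default pressures).  The PPG beat is placed so its
  sampled maximum lags the R peak by exactly `round(PTT·fs)` samples.
- **Beat morphology.** Each PPG cycle is the sum of three Gaussian bells —
  main (percussion) wave, tidal shoulder, dicrotic/repetition wave — at
  relative centers 0.16 / 0.26 / 0.60 of the cycle with relative widths
  0.045 / 0.10 / 0.06 and amplitudes 1 / 0.30 / 0.45.  The tidal component
  is deliberately a *shoulder* on the falling limb (broad, close to the
  main wave) and the dicrotic wave is the textbook prominent repetition
  wave: both choices mirror classical pulse-contour illustrations, and the
  prominent dicrotic wave is what makes per-beat localization of F
  statistically feasible at the simulated noise level (at half that
  amplitude the Cramér–Rao bound on peak localization already exceeds one
  sample of jitter).
- **Pressure→shape coupling.** Vascular stiffening with pressure raises the
  tidal (augmentation) wave, shrinks and advances the dicrotic reflection,
  and a larger pulse pressure broadens the main wave (coupling coefficients
  in `SimConfig`).  This is the mechanism by which waveform-based
  regressors can out-resolve the sample-quantized transit time, as they do
  on real finger-pulse data.
- **Ground truth** records, per beat, the R-peak sample, the exact law PTT,
  the placed dicrotic-center transit time, both pressures and the beat's
  Gaussian parameters.
- **Nuisances.** A sinusoidal baseline drift (default 0.3 units at
  0.05 Hz) and white noise (default SD 0.05 = 5% of the pulse amplitude)
  are added to ECG and PPG *after* clean synthesis.  ABP is left clean so
  the per-beat labels (fragment max/min) remain exact mmHg.

The ECG is a flat baseline plus a ~60 ms biphasic QRS template per beat:
only the R-peak location matters downstream, so template realism is
intentionally minimal.

What the simulator does **not** model: arrhythmia, motion artifact,
respiratory coupling, sensor saturation, circadian rhythm (the random walk
stands in for slow variation), or inter-subject differences.  Passing tests
on this benchmark therefore demonstrates correctness of the algorithms
under controlled conditions, not clinical accuracy.

## Preprocessing

- **Baseline removal**: discrete wavelet decomposition (default `db4`) to
  the level whose approximation band falls below 0.5 Hz at the given rate;
  the reconstructed approximation is subtracted.  A constant maps to zero;
  a 0.05 Hz drift is attenuated by more than 10×, while the beat band is
  preserved within a few percent.
- **R-peak detection**: band-pass (5–18 Hz) → derivative → square →
  150 ms moving integration, adaptive two-level signal/noise threshold,
  250 ms refractory interval, and refinement to the local ECG maximum.
  When two detections fall inside the refractory interval the
  larger-amplitude one wins, so a noise blip cannot mask a true beat.
- **Cycle division**: one candidate cycle per R-peak interval (R peak to
  next R peak); labels from the ABP fragment's max/min.
- **Quality rules**: duration within [0.4, 1.5] s, PPG amplitude at least
  5% of the record's median beat amplitude, correlation with the record's
  median-beat template at least 0.8.  Violations set named flags; nothing
  is repaired silently.

## Fiducial detection and transit times

Fiducials are integer sample indices on the (lightly smoothed) PPG cycle:

- **B** is the global maximum of the cycle.  A ~70 ms Hann-weighted moving
  average is applied before all fiducial detection; it suppresses sample
  noise without measurably moving the peak.
- **E and F** come from the single-scale continuous wavelet transform with
  the `gaus1` kernel (default scale 0.064·fs samples, chosen so the
  smoothing kernel is narrower than the dicrotic wave itself — much larger
  scales flatten the dicrotic bump into the falling limb).  Zero crossings
  of the transform mark extrema of the smoothed signal; crossings are
  classified by sign-change direction, so the descending gorge E is the
  first minimum-type crossing after B (any leading maximum-type crossing
  belongs to the smoothed main peak itself) and F is the crossing that
  follows.  A cycle with no repetition wave raises a typed error and is
  flagged, not crashed on.
- **F localization**: the crossing gives the neighbourhood; the final F is
  the vertex of a parabola fitted around the local maximum of the cycle
  smoothed with a Gaussian kernel matched to the dicrotic width.  This
  keeps per-beat jitter near the white-noise localization bound without
  biasing the clean-signal position.
- **Bell decomposition** (optional refinement, `refine=True`): bounded
  least squares fits three Gaussians *plus a constant offset* — after
  drift removal a pulse train sits below zero by its own mean, which pure
  bells cannot represent.  Initialization takes the three most prominent
  peaks when the segment shows them, otherwise the pulse fiducials
  (B, the B–E midpoint for the tidal shoulder, F); a quantile-based
  restart guards against local minima in heavily merged segments.  The
  fitted dicrotic center replaces F only when it lands within 10% of the
  cycle length of the raw detection.

`PTT-p = B/fs` and `PTT-d = F/fs`, both measured from the cycle's R peak
(segments start at the R peak).  On noise-free default records both are
recovered within ±2 samples for 100% of extracted beats; at 10% noise, for
≥95%.

## ABP-net

Default architecture (each cycle resampled to 128 samples and min-max
normalized; all convolutions valid-mode, float64):

```
Conv(1→8, K=7) → BN → ReLU → MaxPool(2,2)
Conv(8→16, K=7) → BN → ReLU  ⊕ center-cropped 1×1-conv skip   (residual)
→ MaxPool(2,2)
Conv(16→32, K=7) → BN → ReLU → MaxPool(2,2)
AVG → concat z-scored [PTT-p, PTT-d] → FC(34→32) → ReLU → FC(32→2)
```

Design notes:

- Batch normalization uses the biased variance and pools all positions of a
  feature map across the batch; inference applies running averages of the
  batch statistics (momentum 0.1).
- The residual skip is a 1×1 convolution center-cropped to the branch
  length, the valid-mode analogue of a projection shortcut.
- One network predicts both pressures jointly; targets are z-scored
  internally and predictions returned in mmHg, with all normalization
  statistics stored in the model.
- Training is plain mini-batch gradient descent (default batch 32, learning
  rate 0.05, 60 epochs, 15% validation split; `batch_size=None` gives full
  batch).  No momentum or adaptive steps, so the recorded trajectory is
  exactly reproducible from the seed.  Analytic gradients of every layer
  match central finite differences to better than 1e−4 relative error.
- Initialization is fan-in-scaled uniform from a seeded generator;
  identical (seed, data, config) reproduce identical parameters bit for
  bit.

The exact depth, map counts and kernel sizes are package choices — the
smallest architecture containing every named component (convolution, batch
norm, ReLU, both pooling kinds via the AVG bridge, a residual connection,
fully connected layers, the hybrid concatenation).

## Benchmark and evaluation

`run_benchmark` simulates one long session (default ~2,400 beats), splits
it chronologically (~2,000 train / 400 held-out), trains ABP-net, and fits
four baselines: linear regression and random forest (100 trees, seeded) on
either `[PTT-p, PTT-d]` or the 128-sample waveform.  Errors are reported
as MAE ± SD of the absolute errors plus the within-5-mmHg fraction (a
signed-error mode is available).  Typical held-out results at the default
conditions: ABP-net ~2–4 mmHg for SBP and ~1.5–2.5 mmHg for DBP, versus
~9–14 / ~5–7 mmHg for the transit-time-only regressors.

Problem sizes throughout the test suite (hundreds to ~2,400 beats, 60–120 s
fixture records) were chosen to exercise every code path at desk scale
while keeping the suite fast to run.

Clinical statistics: the 2×2 chi-square uses the uncorrected Pearson
statistic — the convention that reproduces the published readmission
comparison (χ² = 4.093 from `[[8, 52], [17, 43]]`); Yates correction is
available behind a flag.  The t test is the two-sided pooled-variance
variant.  "x ± y" accuracy entries are read as MAE ± SD of absolute error;
the statistic is configurable because the convention is not universal.

## Known limitations

- Fiducials are integer samples; at 125 Hz one sample is 8 ms of transit
  time, i.e. ~6.7 mmHg of MAP through the default law.  This quantization,
  not the detector, limits transit-time-only regression.
- The tidal wave's C/D points are reported when derivable but unused; the
  second-derivative acceleration-plethysmography indices are out of scope.
- The per-cycle min-max normalization of the network input discards
  absolute pulse amplitude; on real data amplitude carries information that
  this pipeline deliberately does not use.
- WFDB support covers single-segment, single-rate, format-16 records only;
  EDF/BDF and streaming ingestion are out of scope.
- The simulator's pressure→shape coupling is smooth and deterministic; real
  vascular ageing and drug effects are noisier and subject-specific, so
  real-data accuracy will be worse than the benchmark numbers.
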