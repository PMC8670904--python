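# pulsebp

Cuffless, per-beat blood-pressure estimation from synchronized ECG and
photoplethysmogram (PPG) signals, built around two ideas:

1. **Pulse transit time (PTT).** The delay between the ECG R peak and a
   downstream pulse-wave landmark shortens as arterial pressure rises.  Two
   transit times are measured per beat: `PTT-p` to the main wave peak **B**
   (the PPG maximum of the cycle) and `PTT-d` to the repetition (dicrotic)
   wave peak **F**, located from the zero crossings of the continuous
   wavelet transform with the first-derivative-of-Gaussian (`gaus1`) kernel
   and optionally refined by decomposing the pulse into three Gaussian
   "bell" waves (main, tidal, dicrotic).
2. **ABP-net, a hybrid-feature 1D CNN.** Transit times alone under-determine
   pressure; the pulse *shape* carries the rest.  ABP-net feeds the
   fixed-length PPG cycle through a small convolutional branch
   (valid-mode Conv1D → batch norm → ReLU → max pool, three blocks with one
   residual connection), averages the final feature maps (AVG), concatenates
   the z-scored `[PTT-p, PTT-d]`, and regresses `(SBP, DBP)` through a fully
   connected stack.  Every operator is implemented from its defining
   equation in float64 numpy, with hand-derived backpropagation:

   - convolution `v_j(x) = Σ_i Σ_p k_{i,j}(p)·u_i(xS+p) + b_j`
   - batch normalization `y_i = γ·(x_i − μ_B)/√(σ_B² + ε) + β` with the
     biased variance `σ_B² = (1/n)Σ(x_i − μ_B)²`
   - `ReLU(x) = max(0, x)`; max/mean pooling over sliding windows
   - loss `MSE = (1/n)Σ(y_i − ŷ_i)²`, minimized by plain (mini-)batch
     gradient descent.

Because no public recording set accompanies the method, the package ships a
first-class signal simulator: synchronized ECG/PPG/ABP with a programmable
monotone-decreasing pressure→PTT law (`PTT[ms] = a − b·MAP`), three-bell
beat morphology whose shape stiffens with pressure, baseline drift, noise,
and exact per-beat ground truth.  Every stage of the pipeline is validated
against that ground truth.

Intended users: researchers in physiological signal processing who want a
transparent, fully testable reference pipeline for PTT-based blood-pressure
estimation — not a clinical device.

## Worked example

`examples/03_train_and_compare.py` simulates a ~10-minute session, trains
ABP-net on the first ~500 beats and scores it against the classical
baselines on the held-out tail:

```
trained on 461 beats, tested on 120 held-out beats
method                   SBP (mmHg)             DBP (mmHg)
abp_net         3.53 ± 2.15   73.3%within5     2.10 ± 1.66   94.2%within5
linreg_ptt      9.19 ± 5.68   25.0%within5     5.42 ± 3.76   50.0%within5
linreg_ppg      2.51 ± 2.23   87.5%within5     2.15 ± 1.57   94.2%within5
rf_ptt          8.84 ± 5.55   24.2%within5     5.04 ± 3.73   53.3%within5
rf_ppg          4.07 ± 3.06   70.8%within5     3.29 ± 2.58   76.7%within5
```

Each entry is the mean absolute error ± SD of the absolute errors, with the
fraction of beats within 5 mmHg.  The pattern to read off: methods that see
the pulse waveform (ABP-net, the PPG-feature baselines) clearly beat the
transit-time-only regressors, whose accuracy is limited by the 8 ms sample
quantization of PTT; and diastolic pressure is predicted more accurately
than systolic.  The other examples cover simulation
(`01_simulate_record.py`), transit-time recovery against ground truth
(`02_transit_time_features.py` — 100% of beats within ±2 samples at 5%
noise), and the clinical group statistics (`04_clinical_statistics.py` —
the readmission table `[[8, 52], [17, 43]]` gives the uncorrected Pearson
χ² = 4.093, p = 0.043).

A command-line interface mirrors the library:

```bash
pulsebp simulate --out session/ --seed 7
pulsebp preprocess --in session/record.csv --out cycles.npz
pulsebp features --cycles cycles.npz --out features.csv
pulsebp train --features features.csv --cycles cycles.npz --out model.npz
pulsebp run --out demo/ --seed 7          # the whole pipeline, with manifest
pulsebp stats chi2 --table 8,52,17,43
```

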