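"""Train ABP-net on a synthetic session and compare it with the baselines.

A ~10-minute session is split chronologically; the hybrid network (PPG
waveform branch + transit-time features) and four classical baselines are
fitted on the first part and scored on the held-out tail.  Expect the
characteristic ordering: methods that see the waveform (the network,
PPG-feature regressors) well ahead of the transit-time-only baselines, and
diastolic pressure predicted more accurately than systolic.
"""

from pulsebp import run_benchmark

results, info = run_benchmark(seed=1, n_train_beats=500, n_test_beats=120)

print(f"trained on {info['n_train']} beats, tested on {info['n_test']} held-out beats")
print(f"{'method':<12} {'SBP (mmHg)':>22} {'DBP (mmHg)':>22}")
for method in ("abp_net", "linreg_ptt", "linreg_ppg", "rf_ptt", "rf_ppg"):
    r = results[method]
    print(f"{method:<12} {r['sbp'].mae:7.2f} ± {r['sbp'].sd_abs_error:<5.2f}"
          f"{100 * r['sbp'].within_5mmhg:6.1f}%within5"
          f"  {r['dbp'].mae:7.2f} ± {r['dbp'].sd_abs_error:<5.2f}"
          f"{100 * r['dbp'].within_5mmhg:6.1f}%within5")
print("values are MAE ± SD of the absolute error on the held-out beats")
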