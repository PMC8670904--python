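"""Generate a synthetic ECG/PPG/ABP session and look at its ground truth.

The generator couples blood pressure to the waveform twice over: the pulse
arrives earlier when pressure is high (the transit-time law), and the beat
shape stiffens (larger tidal wave, earlier and smaller dicrotic wave).
"""

import numpy as np

from pulsebp import SimConfig, simulate_record, write_record

config = SimConfig(duration=60.0, seed=42)
record, truth = simulate_record(config)

print(f"record: {record.duration:.0f} s at {record.sampling_rate:.0f} Hz, "
      f"{truth.n_beats} beats")
print(f"SBP range  {truth.true_sbp.min():6.1f} - {truth.true_sbp.max():6.1f} mmHg")
print(f"DBP range  {truth.true_dbp.min():6.1f} - {truth.true_dbp.max():6.1f} mmHg")
print(f"PTT-p range {1e3 * truth.true_ptt_p.min():5.1f} - "
      f"{1e3 * truth.true_ptt_p.max():5.1f} ms (shorter when pressure is higher)")

r = np.corrcoef(truth.true_map, truth.true_ptt_p)[0, 1]
print(f"corr(MAP, PTT-p) = {r:+.3f}  -> the programmed monotone-decreasing law")

write_record(record, "record_demo.csv", format="csv")
print("wrote record_demo.csv (ECG/PPG/ABP, one row per sample)")
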