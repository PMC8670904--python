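"""Shared fixtures: simulated records reused across the suite.

Session-scoped fixtures hold immutable raw material (records, ground truth,
detected R peaks); tests that mutate cycles segment their own copies.
"""

import numpy as np
import pytest

from pulsebp.preprocess import detect_r_peaks, remove_baseline, segment_cycles
from pulsebp.synth import SimConfig, simulate_record

CLEAN_SEED = 3
NOISY_SEED = 5


@pytest.fixture(scope="session")
def clean_sim():
    """~120-beat record with no noise and no drift (exact ground truth)."""
    cfg = SimConfig(duration=100.0, noise_sd=0.0, drift_amplitude=0.0, seed=CLEAN_SEED)
    record, truth = simulate_record(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def clean_prepped(clean_sim):
    """Baseline-removed channels and detected R peaks for the clean record."""
    cfg, record, truth = clean_sim
    fs = cfg.sampling_rate
    ecg = remove_baseline(record["ecg"], fs)
    ppg = remove_baseline(record["ppg"], fs)
    r_peaks = detect_r_peaks(ecg, fs)
    return cfg, record, truth, ppg, r_peaks


@pytest.fixture()
def clean_cycles(clean_prepped):
    """Freshly segmented cycles of the clean record (safe to mutate)."""
    cfg, record, truth, ppg, r_peaks = clean_prepped
    return segment_cycles(record, r_peaks, ppg=ppg)


@pytest.fixture(scope="session")
def noisy_sim():
    """60 s record with 10% noise and baseline drift."""
    cfg = SimConfig(duration=60.0, noise_sd=0.10, drift_amplitude=0.3, seed=NOISY_SEED)
    record, truth = simulate_record(cfg)
    return cfg, record, truth


def match_beats(truth, r_peaks, tol=3):
    """Map each detected R peak to the nearest true beat index (or -1)."""
    out = []
    for rp in np.asarray(r_peaks, dtype=int):
        j = int(np.argmin(np.abs(truth.r_peak_index - rp)))
        out.append(j if abs(int(truth.r_peak_index[j]) - rp) <= tol else -1)
    return np.asarray(out)
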