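"""Preprocessing: baseline removal, cardiac-cycle division, BP labeling, QC.

The cycle anchor is the ECG R peak; each candidate cycle spans from one R
peak to the next, and carries the PPG and ABP fragments of that interval.
True per-cycle SBP/DBP labels are the maximum/minimum of the ABP fragment.
Cycles with implausible duration, collapsed amplitude or an atypical shape
are flagged and excluded before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .signal_io import Record

__all__ = [
    "CardiacCycle",
    "QualityRules",
    "remove_baseline",
    "detect_r_peaks",
    "segment_cycles",
    "label_bp",
    "reject_noisy_cycles",
    "preprocess_record",
]


@dataclass
class CardiacCycle:
    """One beat: R-peak anchor plus aligned PPG/ABP fragments and labels."""

    r_peak_index: int
    ppg_segment: np.ndarray
    abp_segment: np.ndarray
    sbp: float
    dbp: float
    sampling_rate: float
    quality_flags: set[str] = field(default_factory=set)

    @property
    def cycle_duration(self) -> float:
        """Beat length in seconds (segment length over sampling rate)."""
        return len(self.ppg_segment) / self.sampling_rate

    @property
    def accepted(self) -> bool:
        return not self.quality_flags


@dataclass(frozen=True)
class QualityRules:
    """Cycle-rejection rules; a cycle is rejected iff it violates >= 1 rule."""

    min_duration: float = 0.4            # s
    max_duration: float = 1.5            # s
    min_relative_amplitude: float = 0.05 # fraction of the record's median beat amplitude
    min_template_correlation: float = 0.8


def remove_baseline(x, sampling_rate: float, wavelet: str = "db4",
                    cutoff_hz: float = 0.5) -> np.ndarray:
    """Subtract the low-frequency baseline via discrete wavelet decomposition.

    The signal is decomposed to the level whose approximation band lies
    below ``cutoff_hz``; the reconstructed approximation (the baseline) is
    subtracted, so a constant or slow drift is removed while beat-scale
    content is preserved.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    # approximation band after L levels is [0, fs / 2^(L+1)]
    level = max(int(np.ceil(np.log2(sampling_rate / cutoff_hz))) - 1, 1)
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(x.size, w.dec_len)
    if max_level < level:
        raise ValueError(
            f"signal of {x.size} samples too short for a level-{level} "
            f"{wavelet} decomposition (max level {max_level})"
        )
    coeffs = pywt.wavedec(x, w, level=level)
    baseline_coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    baseline = pywt.waverec(baseline_coeffs, w)[: x.size]
    return x - baseline


def detect_r_peaks(ecg, sampling_rate: float, refractory: float = 0.25) -> np.ndarray:
    """Locate ECG R peaks (derivative-square-integrate with adaptive threshold).

    The detector band-passes the ECG around the QRS band, squares the
    derivative, integrates over a 150 ms window, picks integration peaks
    with an adaptively updated signal/noise threshold and a refractory
    period, then refines each detection to the local ECG maximum.
    Returns strictly increasing sample indices; a flat or empty signal
    yields an empty array.
    """
    ecg = np.asarray(ecg, dtype=float)
    fs = float(sampling_rate)
    if ecg.size < int(0.5 * fs) or np.ptp(ecg) == 0:
        return np.array([], dtype=int)

    nyq = fs / 2.0
    hi = min(18.0, 0.9 * nyq)
    sos = sps.butter(2, [5.0 / nyq, hi / nyq], btype="band", output="sos")
    band = sps.sosfiltfilt(sos, ecg)
    energy = np.gradient(band) ** 2
    win = max(int(0.15 * fs), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    min_dist = max(int(refractory * fs), 1)
    cand, _ = sps.find_peaks(integ, distance=min_dist)
    if cand.size == 0:
        return np.array([], dtype=int)

    # adaptive two-level threshold (running signal / noise estimates)
    spk = float(np.max(integ[cand[: max(1, cand.size // 10)]]))
    npk = float(np.median(integ))
    peaks = []
    for c in cand:
        thr = npk + 0.25 * (spk - npk)
        if integ[c] >= thr:
            peaks.append(c)
            spk = 0.125 * integ[c] + 0.875 * spk
        else:
            npk = 0.125 * integ[c] + 0.875 * npk

    # refine to the raw-ECG maximum near each integration peak
    half = max(int(0.10 * fs), 1)
    refined = []
    for c in peaks:
        lo, hi_ = max(c - half, 0), min(c + half + 1, ecg.size)
        refined.append(lo + int(np.argmax(ecg[lo:hi_])))
    refined = np.unique(refined)
    if refined.size > 1:
        # merge detections closer than the refractory interval, keeping the
        # larger-amplitude one (a noise blip must not mask a true R peak)
        keep = [int(refined[0])]
        for r in refined[1:]:
            if r - keep[-1] >= min_dist:
                keep.append(int(r))
            elif ecg[r] > ecg[keep[-1]]:
                keep[-1] = int(r)
        refined = np.asarray(keep)
    return refined.astype(int)


def label_bp(abp_segment) -> tuple[float, float]:
    """SBP/DBP labels of one beat: the ABP fragment's maximum and minimum."""
    abp_segment = np.asarray(abp_segment, dtype=float)
    if abp_segment.size == 0:
        raise ValueError("cannot label an empty ABP segment")
    return float(np.max(abp_segment)), float(np.min(abp_segment))


def segment_cycles(record: Record, r_peaks, ppg=None) -> list[CardiacCycle]:
    """Divide a record into candidate cardiac cycles, one per R-peak interval.

    Each cycle's PPG/ABP segments span from its R peak to the next R peak;
    the last R peak opens no cycle.  ``ppg`` may supply a preprocessed
    (baseline-removed) PPG channel to segment instead of the raw one.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 2:
        raise ValueError("need at least 2 R peaks to form a cycle")
    ppg = record["ppg"] if ppg is None else np.asarray(ppg, dtype=float)
    abp = record["abp"]
    cycles = []
    for a, b in zip(r_peaks[:-1], r_peaks[1:]):
        abp_seg = abp[a:b]
        sbp, dbp = label_bp(abp_seg)
        cycles.append(
            CardiacCycle(
                r_peak_index=int(a),
                ppg_segment=ppg[a:b].copy(),
                abp_segment=abp_seg.copy(),
                sbp=sbp,
                dbp=dbp,
                sampling_rate=record.sampling_rate,
            )
        )
    return cycles


def _resample_linear(x: np.ndarray, n: int) -> np.ndarray:
    if x.size == n:
        return x.astype(float)
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, x)


def reject_noisy_cycles(
    cycles: list[CardiacCycle], rules: QualityRules | None = None
) -> tuple[list[CardiacCycle], dict]:
    """Flag abnormal cycles; return the accepted ones and a summary.

    Rules (each sets a named flag on violation): duration outside
    ``[min_duration, max_duration]`` ("short_cycle"/"long_cycle"),
    PPG peak-to-peak amplitude below ``min_relative_amplitude`` times the
    record's median beat amplitude ("low_amplitude"), and correlation with
    the record's median-beat template below ``min_template_correlation``
    ("template_mismatch").  Rejected cycles keep their flags; nothing is
    repaired.
    """
    rules = rules or QualityRules()
    if not cycles:
        return [], {"n_total": 0, "n_accepted": 0, "accepted_fraction": float("nan")}

    amplitudes = np.array([np.ptp(c.ppg_segment) for c in cycles])
    median_amp = float(np.median(amplitudes))
    n_tpl = 100
    resampled = np.vstack([_resample_linear(c.ppg_segment, n_tpl) for c in cycles])
    template = np.median(resampled, axis=0)
    tpl_sd = float(np.std(template))

    for c, amp, shape in zip(cycles, amplitudes, resampled):
        if c.cycle_duration < rules.min_duration:
            c.quality_flags.add("short_cycle")
        if c.cycle_duration > rules.max_duration:
            c.quality_flags.add("long_cycle")
        if amp < rules.min_relative_amplitude * median_amp:
            c.quality_flags.add("low_amplitude")
        elif tpl_sd > 0 and np.std(shape) > 0:
            r = float(np.corrcoef(shape, template)[0, 1])
            if r < rules.min_template_correlation:
                c.quality_flags.add("template_mismatch")

    accepted = [c for c in cycles if c.accepted]
    summary = {
        "n_total": len(cycles),
        "n_accepted": len(accepted),
        "accepted_fraction": len(accepted) / len(cycles),
    }
    return accepted, summary


def preprocess_record(
    record: Record, rules: QualityRules | None = None
) -> tuple[list[CardiacCycle], dict]:
    """Full preprocessing: baseline removal, R peaks, segmentation, QC.

    ECG and PPG are baseline-corrected; ABP is left untouched so labels stay
    in true mmHg.  Returns the accepted cycles and the rejection summary.
    """
    fs = record.sampling_rate
    ecg = remove_baseline(record["ecg"], fs)
    ppg = remove_baseline(record["ppg"], fs)
    r_peaks = detect_r_peaks(ecg, fs)
    if r_peaks.size < 2:
        return [], {"n_total": 0, "n_accepted": 0, "accepted_fraction": float("nan")}
    cycles = segment_cycles(record, r_peaks, ppg=ppg)
    return reject_noisy_cycles(cycles, rules)
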