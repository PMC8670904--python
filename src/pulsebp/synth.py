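"""Synthetic generator for synchronized ECG/PPG/ABP records with ground truth.

The generator produces the study conditions every downstream stage is tested
against: a beat sequence whose systolic/diastolic pressures follow bounded
random walks, a pulse-transit-time law ``PTT = a - b * MAP`` (ms, with
``MAP = DBP + (SBP - DBP)/3``), and a PPG pulse modeled as the sum of three
Gaussian "bell" waves (main, tidal, dicrotic/repetition).  Beat morphology is
coupled to the pressure state: arterial stiffening at high mean pressure
raises the tidal (augmentation) wave, shrinks and advances the reflected
dicrotic wave, and a larger pulse pressure broadens the main wave.  This
coupling is what lets waveform-based regressors see blood pressure beyond the
sample-quantized transit time, as they do on real finger-pulse data.

Every beat's true R-peak index, transit times, pressures and Gaussian
parameters are returned alongside the record, so detection and regression
errors can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import Record

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimConfigError",
    "make_beat_waveform",
    "simulate_record",
    "mean_arterial_pressure",
    "ptt_law",
]


class SimConfigError(ValueError):
    """Raised for physically impossible simulation configurations."""


#: default three-Gaussian beat morphology: per wave
#: (relative amplitude, relative center as cycle fraction, relative width as
#: cycle fraction) for the main, tidal and dicrotic components.
DEFAULT_BEAT_GAUSSIANS = (
    (1.00, 0.16, 0.045),
    (0.30, 0.26, 0.100),
    (0.45, 0.60, 0.060),
)

#: biphasic QRS template (R peak at index 3, amplitude 1), ~60 ms at 125 Hz
_QRS_TEMPLATE = np.array([-0.08, -0.18, 0.25, 1.00, 0.20, -0.30, -0.08])
_QRS_R_OFFSET = 3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated acquisition session.

    The pressure-to-shape coupling coefficients (``*_coupling``) scale how
    strongly beat morphology tracks mean arterial pressure (MAP, centered at
    ``map_center`` mmHg) and pulse pressure (PP, centered at ``pp_center``).
    Setting them to zero gives a fixed morphology.
    """

    sampling_rate: float = 125.0          # Hz
    duration: float = 60.0                # s
    heart_rate_mean: float = 75.0         # bpm
    heart_rate_sd: float = 3.0            # bpm, beat-to-beat
    sbp_range: tuple[float, float] = (100.0, 160.0)   # mmHg
    dbp_range: tuple[float, float] = (60.0, 100.0)    # mmHg
    bp_step_sd: float = 3.0               # mmHg per beat, random-walk step
    ptt_law_coeffs: tuple[float, float] = (350.0, 1.2)  # (a ms, b ms/mmHg)
    beat_gaussians: tuple[tuple[float, float, float], ...] = DEFAULT_BEAT_GAUSSIANS
    drift_amplitude: float = 0.3          # signal units, ECG/PPG baseline wander
    drift_frequency: float = 0.05         # Hz
    noise_sd: float = 0.05                # signal units, additive white noise
    seed: int = 0
    # morphology <-> pressure coupling
    map_center: float = 95.0
    map_scale: float = 25.0
    pp_center: float = 50.0
    pp_scale: float = 20.0
    tidal_amp_coupling: float = 0.35      # tidal amplitude rises with MAP
    dicrotic_amp_coupling: float = 0.25   # dicrotic amplitude falls with MAP
    dicrotic_shift_coupling: float = 0.035 # dicrotic center advances with MAP (cycle fraction)
    main_width_coupling: float = 0.30     # main width grows with PP

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise SimConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.duration <= 0:
            raise SimConfigError(f"duration must be > 0, got {self.duration}")
        if self.heart_rate_mean <= 0:
            raise SimConfigError(f"heart_rate_mean must be > 0, got {self.heart_rate_mean}")
        if self.heart_rate_sd < 0:
            raise SimConfigError("heart_rate_sd must be >= 0")
        if self.duration * self.heart_rate_mean / 60.0 < 2:
            raise SimConfigError("duration must cover at least 2 beats at heart_rate_mean")
        a, b = self.ptt_law_coeffs
        if b <= 0:
            raise SimConfigError("PTT law slope b must be > 0 (PTT decreases with MAP)")
        if len(self.beat_gaussians) != 3:
            raise SimConfigError("beat_gaussians must list exactly three components")
        centers = [g[1] for g in self.beat_gaussians]
        if not (centers[0] < centers[1] < centers[2]):
            raise SimConfigError("beat Gaussian centers must be strictly increasing")
        for amp, _, width in self.beat_gaussians:
            if width <= 0:
                raise SimConfigError("beat Gaussian widths must be > 0")
        for lo, hi in (self.sbp_range, self.dbp_range):
            if not lo < hi:
                raise SimConfigError("pressure ranges must satisfy low < high")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise SimConfigError("noise_sd and drift_amplitude must be >= 0")


@dataclass
class GroundTruth:
    """Per-beat ground truth of a simulated record (arrays of equal length)."""

    r_peak_index: np.ndarray      # sample index of each R peak
    true_ptt_p: np.ndarray        # s, R peak -> main-wave peak (exact law value)
    true_ptt_d: np.ndarray        # s, R peak -> dicrotic-wave peak
    true_sbp: np.ndarray          # mmHg
    true_dbp: np.ndarray          # mmHg
    gaussian_params: np.ndarray   # (n_beats, 3, 3): (amplitude, center_frac, width_frac)

    @property
    def n_beats(self) -> int:
        return self.r_peak_index.size

    @property
    def true_map(self) -> np.ndarray:
        return mean_arterial_pressure(self.true_sbp, self.true_dbp)


def mean_arterial_pressure(sbp, dbp):
    """MAP = DBP + (SBP - DBP) / 3, the conventional one-third rule."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    return dbp + (sbp - dbp) / 3.0


def ptt_law(map_mmhg, coeffs=(350.0, 1.2)):
    """Pulse transit time in seconds for a given MAP, ``PTT[ms] = a - b*MAP``."""
    a, b = coeffs
    return (a - b * np.asarray(map_mmhg, dtype=float)) / 1000.0


def make_beat_waveform(params, n_samples: int) -> np.ndarray:
    """Evaluate a three-Gaussian pulse on a uniform cycle grid.

    Parameters
    ----------
    params
        Three ``(amplitude, center, width)`` triplets with center and width
        expressed as fractions of the cycle.
    n_samples
        Grid length; the cycle spans samples ``0 .. n_samples - 1``.
    """
    if n_samples < 8:
        raise SimConfigError(f"n_samples must be >= 8, got {n_samples}")
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 3:
        raise SimConfigError("params must be triplets of (amplitude, center, width)")
    if np.any(params[:, 2] <= 0):
        raise SimConfigError("Gaussian widths must be > 0")
    x = np.arange(n_samples, dtype=float) / (n_samples - 1)  # cycle fraction
    wave = np.zeros(n_samples)
    for amp, center, width in params:
        wave += amp * np.exp(-0.5 * ((x - center) / width) ** 2)
    return wave


def _bounded_walk(rng, n, lo, hi, start, step_sd):
    """Random walk reflected at [lo, hi]."""
    out = np.empty(n)
    x = start
    for i in range(n):
        x += rng.normal(0.0, step_sd)
        if x < lo:
            x = lo + (lo - x)
        if x > hi:
            x = hi - (x - hi)
        x = min(max(x, lo), hi)
        out[i] = x
    return out


def _beat_params(config: SimConfig, sbp: float, dbp: float) -> np.ndarray:
    """Morphology of one beat, coupled to its pressure state."""
    base = np.asarray(config.beat_gaussians, dtype=float).copy()
    map_ = float(mean_arterial_pressure(sbp, dbp))
    xm = (map_ - config.map_center) / config.map_scale
    xp = ((sbp - dbp) - config.pp_center) / config.pp_scale
    params = base.copy()
    params[1, 0] = max(base[1, 0] * (1.0 + config.tidal_amp_coupling * xm), 0.05)
    params[2, 0] = max(base[2, 0] * (1.0 - config.dicrotic_amp_coupling * xm), 0.05)
    params[2, 1] = np.clip(
        base[2, 1] - config.dicrotic_shift_coupling * xm, base[1, 1] + 0.10, 0.90
    )
    params[0, 2] = base[0, 2] * float(np.clip(1.0 + config.main_width_coupling * xp, 0.6, 1.6))
    return params


def simulate_record(config: SimConfig) -> tuple[Record, GroundTruth]:
    """Generate one synchronized ECG/PPG/ABP record plus its ground truth.

    Construction per beat ``k`` (R peak at sample ``r_k``, next at
    ``r_{k+1}``):

    * true pressures from reflected random walks inside the configured
      ranges (SBP forced at least 5 mmHg above DBP);
    * ``PTT_k`` from the monotone law at that beat's MAP; the PPG beat
      waveform is placed so that its sampled maximum falls exactly
      ``round(PTT_k * fs)`` samples after ``r_k``;
    * the ABP fragment over ``[r_k, r_{k+1})`` is the beat waveform rescaled
      to span exactly ``[DBP_k, SBP_k]``;
    * sinusoidal baseline drift and white noise are added to ECG and PPG
      only, after clean synthesis, so ABP-derived labels stay exact.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_total = int(round(config.duration * fs))

    # --- beat schedule ------------------------------------------------------
    r_peaks, rr_samples = [], []
    t = int(round(0.1 * fs))  # small lead-in before the first beat
    while True:
        hr = float(np.clip(rng.normal(config.heart_rate_mean, config.heart_rate_sd), 30.0, 180.0))
        rr = max(int(round(fs * 60.0 / hr)), 8)
        if t + rr >= n_total:
            break
        r_peaks.append(t)
        rr_samples.append(rr)
        t += rr
    if len(r_peaks) < 2:
        raise SimConfigError("duration too short: fewer than 2 complete beats generated")
    r_peaks = np.asarray(r_peaks, dtype=int)
    rr_samples = np.asarray(rr_samples, dtype=int)
    n_beats = r_peaks.size

    # --- per-beat pressures -------------------------------------------------
    sbp = _bounded_walk(rng, n_beats, *config.sbp_range,
                        start=np.mean(config.sbp_range), step_sd=config.bp_step_sd)
    dbp = _bounded_walk(rng, n_beats, *config.dbp_range,
                        start=np.mean(config.dbp_range), step_sd=config.bp_step_sd)
    sbp = np.maximum(sbp, dbp + 5.0)

    map_ = mean_arterial_pressure(sbp, dbp)
    ptt = ptt_law(map_, config.ptt_law_coeffs)
    if np.any(ptt <= 0):
        raise SimConfigError("PTT law produced non-positive transit times in range")

    ecg = np.zeros(n_total)
    ppg = np.zeros(n_total)
    abp = np.zeros(n_total)

    gauss = np.empty((n_beats, 3, 3))
    ptt_d = np.empty(n_beats)

    for k in range(n_beats):
        r, rr = int(r_peaks[k]), int(rr_samples[k])
        params = _beat_params(config, sbp[k], dbp[k])
        gauss[k] = params
        wave = make_beat_waveform(params, rr)

        # ECG: QRS template with R spike exactly at r
        lo = r - _QRS_R_OFFSET
        hi = lo + _QRS_TEMPLATE.size
        s0, s1 = max(lo, 0), min(hi, n_total)
        ecg[s0:s1] += _QRS_TEMPLATE[s0 - lo : s1 - lo]

        # PPG: shift so the waveform's sampled maximum lags R by round(ptt*fs)
        peak_off = int(np.argmax(wave))
        start = r + int(round(ptt[k] * fs)) - peak_off
        s0, s1 = max(start, 0), min(start + rr, n_total)
        ppg[s0:s1] += wave[s0 - start : s1 - start]

        # ABP: beat waveform rescaled to span [dbp, sbp] over [r, r+rr)
        lo_v, hi_v = wave.min(), wave.max()
        norm = (wave - lo_v) / (hi_v - lo_v)
        abp[r : min(r + rr, n_total)] = (
            dbp[k] + (sbp[k] - dbp[k]) * norm[: min(rr, n_total - r)]
        )

        # dicrotic transit: measured to the placed dicrotic center, so that
        # ground truth describes the waveform as sampled (within rounding it
        # equals ptt_p plus the main-to-dicrotic center spacing)
        ptt_d[k] = (start + params[2, 1] * (rr - 1) - r) / fs

    # fill ABP outside the beat span with the neighbouring diastolic level
    abp[: r_peaks[0]] = dbp[0]
    tail = r_peaks[-1] + rr_samples[-1]
    if tail < n_total:
        abp[tail:] = dbp[-1]

    # --- drift and noise (ECG/PPG only) -------------------------------------
    tt = np.arange(n_total) / fs
    drift = config.drift_amplitude * np.sin(2.0 * np.pi * config.drift_frequency * tt)
    ecg = ecg + drift + rng.normal(0.0, config.noise_sd, n_total)
    ppg = ppg + drift + rng.normal(0.0, config.noise_sd, n_total)

    record = Record({"ecg": ecg, "ppg": ppg, "abp": abp}, sampling_rate=fs)
    truth = GroundTruth(
        r_peak_index=r_peaks,
        true_ptt_p=ptt,
        true_ptt_d=ptt_d,
        true_sbp=sbp,
        true_dbp=dbp,
        gaussian_params=gauss,
    )
    return record, truth


def fixed_bp_config(sbp: float = 120.0, dbp: float = 80.0, **kwargs) -> SimConfig:
    """Convenience: a config whose every beat has the same SBP/DBP.

    Implemented by collapsing both pressure ranges to a point (the walk then
    stays at the reflecting boundaries).
    """
    eps = 1e-9
    return replace(
        SimConfig(**kwargs),
        sbp_range=(sbp - eps, sbp + eps),
        dbp_range=(dbp - eps, dbp + eps),
    )


def truth_to_frame(truth: GroundTruth):
    """Ground truth as a pandas DataFrame (one row per beat) for sidecar files."""
    import pandas as pd

    return pd.DataFrame(
        {
            "r_peak_index": truth.r_peak_index,
            "true_ptt_p": truth.true_ptt_p,
            "true_ptt_d": truth.true_ptt_d,
            "true_sbp": truth.true_sbp,
            "true_dbp": truth.true_dbp,
        }
    )
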