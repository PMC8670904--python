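"""Fiducial detection, the gaus1 transform, bell decomposition, transit times."""

import numpy as np
import pytest

from pulsebp.features import (
    NoDicroticWaveError,
    _zero_crossings,
    bell_decompose,
    compute_ptt,
    detect_e_f,
    detect_main_peak,
    extract_features,
    refine_f,
    wavelet_transform_gaus1,
)
from pulsebp.preprocess import CardiacCycle, segment_cycles
from pulsebp.synth import make_beat_waveform
from tests.conftest import match_beats


def _gaussian(n, center, sigma, amp=1.0):
    x = np.arange(n, dtype=float)
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


class TestDetectMainPeak:
    def test_global_maximum(self):
        assert detect_main_peak([0, 1, 3, 2, 1]) == 2

    def test_plateau_ties_break_earliest(self):
        assert detect_main_peak([0, 3, 3, 0]) == 1

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            detect_main_peak([])

    def test_clean_beat_peak_near_programmed_center(self, clean_prepped):
        cfg, record, truth, ppg, r_peaks = clean_prepped
        fs = cfg.sampling_rate
        cycles = segment_cycles(record, r_peaks, ppg=ppg)
        beats = match_beats(truth, [c.r_peak_index for c in cycles])
        for cyc, j in zip(cycles[1:-1], beats[1:-1]):
            b = detect_main_peak(cyc.ppg_segment)
            assert abs(b - truth.true_ptt_p[j] * fs) <= 1.5

    def test_amplitude_scaling_leaves_fiducials_unchanged(self):
        wave = make_beat_waveform([(1.0, 0.16, 0.045), (0.3, 0.26, 0.1),
                                   (0.45, 0.6, 0.06)], 100)
        b1 = detect_main_peak(wave)
        b2 = detect_main_peak(7.3 * wave)
        assert b1 == b2
        e1, f1 = detect_e_f(wave, b1, 6.0)
        e2, f2 = detect_e_f(7.3 * wave, b2, 6.0)
        assert (e1, f1) == (e2, f2)


class TestGaus1Transform:
    def test_constant_segment_transforms_to_zero(self):
        # away from the borders (where the kernel hangs off the segment)
        out = wavelet_transform_gaus1(np.full(200, 2.5), 8.0)
        np.testing.assert_allclose(out[45:-45], 0.0, atol=1e-8)

    def test_linearity_under_negation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=256)
        np.testing.assert_allclose(
            wavelet_transform_gaus1(-x, 6.0), -wavelet_transform_gaus1(x, 6.0),
            rtol=1e-10, atol=1e-12,
        )

    def test_output_length_equals_input_length(self):
        x = np.zeros(150)
        assert wavelet_transform_gaus1(x, 5.0).size == 150

    def test_zero_crossing_at_gaussian_center(self):
        bump = _gaussian(256, 128, 12)
        t = wavelet_transform_gaus1(bump, 8.0)
        crossings = [i for i, _ in _zero_crossings(t)]
        assert min(abs(c - 128) for c in crossings) <= 1

    def test_crossings_match_brute_force_convolution_oracle(self):
        # independent oracle: directly convolve with the sampled
        # derivative-of-Gaussian kernel and scan for sign changes
        bump = _gaussian(256, 100, 10) + _gaussian(256, 170, 12, 0.5)
        scale = 8.0
        u = np.arange(-5 * scale, 5 * scale + 1) / scale
        kernel = -2 * u * np.exp(-(u**2))  # d/du exp(-u^2), up to sign/norm
        conv = np.convolve(bump, kernel[::-1], mode="same")
        sign_changes = np.flatnonzero(np.sign(conv[:-1]) * np.sign(conv[1:]) < 0)
        t = wavelet_transform_gaus1(bump, scale)
        ours = np.array([i for i, _ in _zero_crossings(t)])
        interior = [c for c in sign_changes if 45 <= c <= bump.size - 45]
        assert interior
        for c in interior:
            assert np.min(np.abs(ours - c)) <= 2

    def test_scale_too_large_rejected(self):
        with pytest.raises(ValueError):
            wavelet_transform_gaus1(np.zeros(50), 10.0)


class TestDetectEF:
    def test_three_bell_beat_locates_dicrotic_peak(self):
        wave = make_beat_waveform([(1.0, 0.16, 0.045), (0.3, 0.26, 0.1),
                                   (0.45, 0.6, 0.06)], 100)
        b = detect_main_peak(wave)
        e, f = detect_e_f(wave, b, 6.4)
        assert b < e < f
        assert abs(f - 0.6 * 99) <= 2

    def test_monotone_decay_has_no_dicrotic_wave(self):
        wave = _gaussian(100, 20, 8)
        b = detect_main_peak(wave)
        with pytest.raises(NoDicroticWaveError):
            detect_e_f(wave, b, 6.4)

    def test_crossing_assigned_to_smaller_magnitude_sample(self):
        t = np.array([0.5, 0.1, -0.4, -0.1, 0.3])
        crossings = _zero_crossings(t)
        assert crossings[0][0] == 1  # |0.1| < |-0.4|
        assert crossings[1][0] == 3  # |-0.1| < |0.3|

    def test_invalid_main_peak_index_rejected(self):
        with pytest.raises(ValueError):
            detect_e_f(np.zeros(100), 200, 6.0)


class TestBellDecompose:
    exact_params = [
        ((1.0, 18.0, 5.0), (0.35, 30.0, 9.0), (0.45, 60.0, 6.5)),
        ((0.8, 15.0, 4.0), (0.30, 28.0, 8.0), (0.50, 55.0, 7.0)),
    ]

    @pytest.mark.parametrize("params", exact_params)
    def test_exact_three_gaussian_sum_is_a_fixed_point(self, params):
        n = 100
        x = np.arange(n, dtype=float)
        seg = sum(a * np.exp(-0.5 * ((x - c) / w) ** 2) for a, c, w in params)
        d = bell_decompose(seg)
        np.testing.assert_allclose(d.centers, [c for _, c, _ in params], atol=0.5)
        assert d.residual_rms < 1e-6 * seg.max()

    def test_permuted_initial_centers_recover_same_solution(self):
        params = self.exact_params[0]
        n = 100
        x = np.arange(n, dtype=float)
        seg = sum(a * np.exp(-0.5 * ((x - c) / w) ** 2) for a, c, w in params)
        init = [0.4, 58.0, 6.0, 1.0, 17.0, 5.0, 0.4, 31.0, 8.0]  # permuted order
        d = bell_decompose(seg, init=np.array(init))
        np.testing.assert_allclose(d.centers, [18.0, 30.0, 60.0], atol=0.5)

    def test_white_noise_degenerate_input_contract(self):
        rng = np.random.default_rng(0)
        d = bell_decompose(rng.normal(size=80))
        assert d.residual_rms >= 0.0
        assert isinstance(d.converged, bool)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            bell_decompose(np.zeros(10))


class TestRefineF:
    def _decomp(self, third_center):
        from pulsebp.features import BellWaveDecomposition

        return BellWaveDecomposition(
            amplitudes=np.array([1.0, 0.3, 0.4]),
            centers=np.array([20.0, 40.0, third_center]),
            widths=np.array([5.0, 8.0, 6.0]),
            residual_rms=0.0,
            converged=True,
        )

    def test_center_within_tolerance_replaces_raw(self):
        assert refine_f(self._decomp(71.0), f_raw=73, cycle_length=125) == 71

    def test_center_outside_tolerance_keeps_raw(self):
        assert refine_f(self._decomp(30.0), f_raw=73, cycle_length=125) == 73

    def test_unconverged_fit_keeps_raw(self):
        d = self._decomp(71.0)
        d.converged = False
        assert refine_f(d, f_raw=73, cycle_length=125) == 73

    def test_refinement_does_not_degrade_clean_extraction(self, clean_prepped):
        cfg, record, truth, ppg, r_peaks = clean_prepped
        fs = cfg.sampling_rate
        cycles = segment_cycles(record, r_peaks, ppg=ppg)
        raw = extract_features(cycles, refine=False)
        ref = extract_features(cycles, refine=True)
        merged = raw.merge(ref, on="beat", suffixes=("_raw", "_ref"))
        beats = match_beats(truth, merged["r_peak_index_raw"])
        true_d = truth.true_ptt_d[beats]
        err_raw = np.abs(merged["ptt_d_raw"].to_numpy() - true_d) * fs
        err_ref = np.abs(merged["ptt_d_ref"].to_numpy() - true_d) * fs
        assert err_ref.mean() <= err_raw.mean() + 0.05


class TestComputePTT:
    def _cycle(self, n=125, fs=125.0):
        return CardiacCycle(
            r_peak_index=0, ppg_segment=np.zeros(n), abp_segment=np.zeros(n),
            sbp=120.0, dbp=80.0, sampling_rate=fs,
        )

    def test_offsets_to_seconds(self):
        ptt = compute_ptt(self._cycle(), b=25, f=60)
        assert ptt.ptt_p == pytest.approx(0.200)
        assert ptt.ptt_d - ptt.ptt_p == pytest.approx(0.280)

    def test_f_not_after_b_rejected(self):
        with pytest.raises(ValueError):
            compute_ptt(self._cycle(), b=60, f=25)

    def test_index_outside_segment_rejected(self):
        with pytest.raises(ValueError):
            compute_ptt(self._cycle(), b=25, f=300)


class TestExtractFeatures:
    def test_ordering_invariant_on_accepted_cycles(self, clean_cycles):
        feats = extract_features(clean_cycles)
        assert np.all(feats["ptt_p"] < feats["ptt_d"])
        durations = np.array([clean_cycles[int(i)].cycle_duration for i in feats["beat"]])
        assert np.all(feats["ptt_d"] < durations)

    def test_shift_equivariance_of_transit_times(self, clean_cycles):
        k = 4  # delay the PPG by k samples: both PTTs grow by k/fs
        cyc = clean_cycles[10]
        fs = cyc.sampling_rate
        base = extract_features([cyc])
        shifted = CardiacCycle(
            r_peak_index=cyc.r_peak_index,
            ppg_segment=np.concatenate([np.full(k, cyc.ppg_segment[0]), cyc.ppg_segment]),
            abp_segment=np.concatenate([np.full(k, cyc.abp_segment[0]), cyc.abp_segment]),
            sbp=cyc.sbp, dbp=cyc.dbp, sampling_rate=fs,
        )
        after = extract_features([shifted])
        assert after["ptt_p"][0] - base["ptt_p"][0] == pytest.approx(k / fs, abs=1e-9)
        assert after["ptt_d"][0] - base["ptt_d"][0] == pytest.approx(k / fs, abs=0.6 / fs)

    def test_ptt_map_rank_correlation_strongly_negative(self, clean_prepped):
        from scipy.stats import spearmanr

        _, record, truth, ppg, r_peaks = clean_prepped
        cycles = segment_cycles(record, r_peaks, ppg=ppg)
        feats = extract_features(cycles)
        beats = match_beats(truth, feats["r_peak_index"])
        rho = spearmanr(feats["ptt_p"], truth.true_map[beats]).statistic
        assert rho <= -0.9
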