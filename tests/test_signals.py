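"""Signal conditioning, amplitude metrics, spectra and screening rules."""

import numpy as np
import pytest
from scipy import signal as sps

from tremorlab.signals import (
    EMGRecording, PowerSpectrum, TremorRecording, bandpass_tremor,
    classify_origin, disjoint_spectrum, kinetic_rms, postural_rms,
    process_emg, screen_outliers, segment_movements,
    analyze_postural, analyze_kinetic, FILTER_ORDER, TREMOR_BAND,
)
from tremorlab.synth import (
    TremorGenSpec, generate_kinetic_trajectory, generate_tremor,
    generate_tremor_pair,
)

FS = 200.0


def sinusoid(freq, fs=FS, duration=60.0, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def dual_pass_gain(freq, fs=FS):
    """Squared magnitude response of the band-pass design at one
    frequency — the independent frequency-domain oracle for the
    forward-backward filter."""
    b, a = sps.butter(FILTER_ORDER, TREMOR_BAND, btype="bandpass", fs=fs)
    _, h = sps.freqz(b, a, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)


class TestBandpass:
    def test_dc_offset_removed(self):
        out = bandpass_tremor(np.full(12000, 3.7), fs=FS)
        assert np.max(np.abs(out[400:-400])) < 1e-6

    @pytest.mark.parametrize("freq, fs", [(10.0, 200.0), (80.0, 1000.0)])
    def test_amplitude_matches_frequency_response(self, freq, fs):
        # amplitude measured by projection onto the tone, away from edge
        # transients; oracle is the squared magnitude response of the
        # 4th-order design (applied twice)
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        out = bandpass_tremor(x, fs=fs)
        n = int(5 * fs)
        core, tc = out[n:-n], t[n:-n]
        measured = 2 * np.abs(np.exp(-2j * np.pi * freq * tc) @ core) / len(core)
        assert measured == pytest.approx(dual_pass_gain(freq, fs), rel=0.01)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            bandpass_tremor(np.zeros(2000), fs=80.0)

    def test_zero_phase(self):
        """Cross-correlation of a passband sinusoid with its filtered
        version peaks at lag zero."""
        x = sinusoid(6.0)
        out = bandpass_tremor(x, fs=FS)
        core = slice(400, -400)
        lags = sps.correlation_lags(len(x[core]), len(out[core]))
        xc = sps.correlate(x[core], out[core])
        assert lags[np.argmax(xc)] == 0


class TestPosturalRms:
    def test_zero_signal(self):
        assert postural_rms(np.zeros(2000), FS) == 0.0

    def test_sinusoid_closed_form(self):
        x = bandpass_tremor(sinusoid(8.0, amplitude=0.3), fs=FS)
        assert postural_rms(x, FS) == pytest.approx(0.3 / np.sqrt(2),
                                                    rel=0.01)

    def test_variance_additivity_of_tremor_plus_noise(self):
        # oscillation and broadband noise powers add (within the filter's
        # slight noise attenuation) — Monte-Carlo over seeds
        a, sd = 0.2, 0.05
        expected = np.sqrt(a ** 2 / 2 + sd ** 2)
        vals = []
        for seed in range(10):
            rec = generate_tremor(TremorGenSpec(amplitude=a, frequency=6.0,
                                                noise_sd=sd, seed=seed))
            vals.append(postural_rms(bandpass_tremor(rec), FS))
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_scaling_equivariance(self):
        rec = generate_tremor(TremorGenSpec(seed=1))
        filt = bandpass_tremor(rec)
        assert postural_rms(3.5 * filt, FS) == pytest.approx(
            3.5 * postural_rms(filt, FS))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            postural_rms(np.zeros(100), FS)  # shorter than 2x edge trim


class TestSegmentation:
    def test_ideal_triangle_windows_span_middle_40_degrees(self):
        traj = generate_kinetic_trajectory(
            TremorGenSpec(amplitude=0.0, noise_sd=0.0, seed=0), n_cycles=1)
        windows, degraded = segment_movements(traj.samples, FS)
        assert not degraded
        assert len(windows) == 2  # one extension + one flexion
        for _, a, b in windows:
            # 40 deg at 5 deg/s = 8 s per window
            assert (b - a) / FS == pytest.approx(8.0, abs=0.3)
            seg = traj.samples[a:b + 1]
            assert seg.min() == pytest.approx(-20.0, abs=1.0)
            assert seg.max() == pytest.approx(20.0, abs=1.0)

    def test_two_cycles_give_four_windows(self):
        traj = generate_kinetic_trajectory(
            TremorGenSpec(amplitude=0.5, frequency=5.0, noise_sd=0.05,
                          seed=2), n_cycles=2)
        windows, degraded = segment_movements(traj.samples, FS)
        assert len(windows) == 4
        assert not degraded
        assert {p for p, _, _ in windows} == {"extension", "flexion"}

    def test_flat_trajectory_flags_degraded(self):
        windows, degraded = segment_movements(np.zeros(8000), FS)
        assert windows == [] and degraded


class TestKineticRms:
    def test_ramp_alone_is_removed_by_highpass(self):
        traj = generate_kinetic_trajectory(
            TremorGenSpec(amplitude=0.0, noise_sd=0.0, seed=0))
        windows, _ = segment_movements(traj.samples, FS)
        filt = bandpass_tremor(traj)
        assert kinetic_rms(filt, windows) < 0.05  # deg, vs 50 deg ramp

    def test_ramp_plus_sinusoid_closed_form(self):
        traj = generate_kinetic_trajectory(
            TremorGenSpec(amplitude=0.5, frequency=5.0, noise_sd=0.0,
                          seed=1))
        windows, _ = segment_movements(traj.samples, FS)
        filt = bandpass_tremor(traj)
        assert kinetic_rms(filt, windows) == pytest.approx(
            0.5 / np.sqrt(2), rel=0.05)

    def test_stationary_tremor_consistent_across_windows(self):
        traj = generate_kinetic_trajectory(
            TremorGenSpec(amplitude=0.5, frequency=5.0, noise_sd=0.0,
                          seed=3))
        windows, _ = segment_movements(traj.samples, FS)
        filt = bandpass_tremor(traj)
        per_window = [kinetic_rms(filt, [w]) for w in windows]
        assert np.ptp(per_window) / np.mean(per_window) < 0.05

    def test_no_windows_rejected(self):
        with pytest.raises(ValueError):
            kinetic_rms(np.zeros(1000), [])


class TestEmg:
    FS_EMG = 5000.0

    def test_zero_input_zero_envelope(self):
        out = process_emg(np.zeros(50_000), mvc_max=1.0, fs=self.FS_EMG)
        assert np.allclose(out, 0.0)

    def test_rectified_sinusoid_mean(self):
        # mean of a full-wave-rectified sinusoid of amplitude A is 2A/pi
        t = np.arange(50_000) / self.FS_EMG
        x = 0.4 * np.sin(2 * np.pi * 100 * t)
        env = process_emg(x, mvc_max=1.0, fs=self.FS_EMG)
        core = env[5000:-5000]
        assert np.mean(core) == pytest.approx(2 * 0.4 / np.pi, rel=0.01)

    def test_mvc_trial_self_normalises(self):
        t = np.arange(50_000) / self.FS_EMG
        x = np.sin(2 * np.pi * 120 * t)
        raw_env = process_emg(x, mvc_max=1.0, fs=self.FS_EMG)
        env = process_emg(x, mvc_max=float(raw_env.max()), fs=self.FS_EMG)
        assert env.max() == pytest.approx(1.0)

    def test_invalid_mvc_rejected(self):
        with pytest.raises(ValueError, match="mvc"):
            process_emg(np.zeros(10_000), mvc_max=0.0, fs=self.FS_EMG)

    def test_emg_recording_rate_floor(self):
        with pytest.raises(ValueError):
            EMGRecording(samples=np.zeros(100), fs=500.0)


class TestDisjointSpectrum:
    def test_standard_postural_recording_geometry(self):
        sp = disjoint_spectrum(np.random.default_rng(0).normal(size=12000),
                               fs=FS)
        assert sp.n_segments == 12
        assert sp.resolution == pytest.approx(0.2)
        assert np.allclose(np.diff(sp.frequencies), 0.2)
        assert sp.frequencies[0] == 0.0

    def test_sinusoid_peak_in_correct_bin(self):
        sp = disjoint_spectrum(sinusoid(6.0), fs=FS)
        assert sp.frequencies[np.argmax(sp.power)] == pytest.approx(6.0)

    def test_parseval_on_white_noise(self):
        x = np.random.default_rng(1).normal(size=12000)
        sp = disjoint_spectrum(x, fs=FS)
        assert np.sum(sp.power) * sp.resolution == pytest.approx(
            np.var(x), rel=0.10)

    def test_power_scales_quadratically(self):
        x = sinusoid(6.0) + np.random.default_rng(2).normal(size=12000)
        p1 = disjoint_spectrum(x, fs=FS).power
        p2 = disjoint_spectrum(2.0 * x, fs=FS).power
        assert np.allclose(p2, 4.0 * p1)

    def test_single_segment_equals_plain_periodogram(self):
        x = np.random.default_rng(3).normal(size=1000)
        sp = disjoint_spectrum(x, fs=FS, segment_length=5.0)
        f_ref, p_ref = sps.periodogram(x, fs=FS, window="boxcar",
                                       detrend=False)
        # compare the first (only full) segment's average to scipy on
        # the same samples
        sp1 = disjoint_spectrum(x[:1000], fs=FS, segment_length=1000 / FS)
        assert sp1.n_segments == 1
        assert np.allclose(sp1.frequencies, f_ref)
        assert np.allclose(sp1.power, p_ref)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            disjoint_spectrum(np.zeros(100), fs=FS, segment_length=5.0)


class TestOriginClassification:
    @pytest.mark.parametrize("shift, expected", [
        (0.0, "central-consistent"),
        (2.0, "shifted-noncentral"),
    ])
    def test_synthetic_peak_shift(self, shift, expected):
        u, w = generate_tremor_pair(TremorGenSpec(
            amplitude=0.1, frequency=8.0, freq_shift_weighted=shift,
            noise_sd=0.02, seed=7))
        assert classify_origin(disjoint_spectrum(u.samples, FS),
                               disjoint_spectrum(w.samples, FS)) == expected

    def test_flat_spectra_have_no_peak(self):
        f = np.arange(0, 100.2, 0.2)
        flat = PowerSpectrum(f, np.ones_like(f), 0.2, 12, 5.0)
        assert classify_origin(flat, flat) == "no-peak"

    def test_grid_mismatch_rejected(self):
        f1 = np.arange(0, 100.2, 0.2)
        f2 = np.arange(0, 50.2, 0.2)
        s1 = PowerSpectrum(f1, np.ones_like(f1), 0.2, 12, 5.0)
        s2 = PowerSpectrum(f2, np.ones_like(f2), 0.2, 12, 5.0)
        with pytest.raises(ValueError, match="grid"):
            classify_origin(s1, s2)


class TestOutlierScreening:
    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 21), [10.0]])
        flags = screen_outliers({"control": vals})
        assert list(np.flatnonzero(flags["control"])) == [21]

    def test_identical_values_unflagged(self):
        flags = screen_outliers({"g": [2.0] * 10})
        assert not flags["g"].any()

    def test_two_planted_control_outliers_reproduce_exclusion_count(self):
        """A cohort built with 2 extreme control amplitudes yields
        exactly 2 control exclusions under the >3 SD rule."""
        rng = np.random.default_rng(8)
        control = np.concatenate([rng.normal(0.04, 0.01, 20), [0.5, 0.5]])
        et = rng.normal(0.15, 0.05, 20)
        flags = screen_outliers({"control": control, "ET": et})
        assert flags["control"].sum() == 2
        assert flags["ET"].sum() == 0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            screen_outliers({"g": [1.0, 2.0]})


class TestPipelines:
    def test_postural_pipeline_recovers_amplitude_and_peak(self):
        """End-to-end amplitude/frequency recovery over seeds."""
        a, f0 = 0.15, 6.0
        rms_vals, peaks = [], []
        for seed in range(20):
            rec = generate_tremor(TremorGenSpec(amplitude=a, frequency=f0,
                                                noise_sd=0.01, seed=seed))
            m = analyze_postural(rec)
            rms_vals.append(m.postural_rms)
            peaks.append(m.peak_freq_unweighted)
        assert np.mean(rms_vals) == pytest.approx(
            np.sqrt(a ** 2 / 2 + 0.01 ** 2), rel=0.05)
        assert all(abs(p - f0) <= 0.2 for p in peaks)

    def test_kinetic_pipeline(self):
        traj = generate_kinetic_trajectory(
            TremorGenSpec(amplitude=0.4, frequency=5.0, noise_sd=0.02,
                          seed=9))
        m = analyze_kinetic(traj)
        assert m.kinetic_rms == pytest.approx(
            np.sqrt(0.4 ** 2 / 2 + 0.02 ** 2), rel=0.1)
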