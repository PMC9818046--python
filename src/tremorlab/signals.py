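"""Tremor and EMG signal conditioning, amplitude metrics and spectra.

The processing chain mirrors standard practice for upper-limb tremor
recordings: zero-phase Butterworth band-pass filtering of calibrated
acceleration (m s^-2) and joint-angle (degrees) signals, RMS amplitude
metrics for postural and kinetic tremor, an EMG envelope normalised to
maximal voluntary contraction, and power spectra by the method of
disjoint segments (averaged periodograms of non-overlapping windows).

Two screening classifiers reproduce common participant-exclusion rules:
a loading-induced downward shift of the dominant spectral peak (tremor
not of central origin, e.g. enhanced physiological tremor), and a
greater-than-k-SD amplitude outlier flag within group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import signal as sps

TREMOR_BAND = (0.5, 40.0)       # Hz, analysis band for tremor signals
EMG_BAND = (20.0, 450.0)        # Hz, surface-EMG band-pass
EMG_ENVELOPE_LOWPASS = 40.0     # Hz, envelope smoothing after rectification
FILTER_ORDER = 4                # applied forward-backward (zero phase)
EDGE_TRIM_S = 1.0               # seconds discarded at each end before RMS
PEAK_SEARCH_BAND = (3.0, 12.0)  # Hz, band searched for the tremor peak
PEAK_PROMINENCE_FACTOR = 3.0    # peak must exceed this x median band power


@dataclass
class TremorRecording:
    """A calibrated tremor time series with acquisition metadata."""

    samples: np.ndarray
    fs: float
    condition: Literal["postural", "kinetic"] = "postural"
    load: Literal["unweighted", "weighted"] = "unweighted"
    units: str = "m/s^2"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class EMGRecording:
    """Raw surface EMG (volts) with sampling rate and MVC reference."""

    samples: np.ndarray
    fs: float
    muscle: Literal["FCR", "ECR"] = "ECR"
    mvc_max: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs < 1000:
            raise ValueError("EMG sampling rate must be >= 1000 Hz")


@dataclass
class PowerSpectrum:
    """One-sided power spectral density on an evenly spaced grid."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float
    n_segments: int
    segment_length: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)

    def band_peak(self, band: tuple[float, float] = PEAK_SEARCH_BAND,
                  prominence_factor: float = PEAK_PROMINENCE_FACTOR,
                  ) -> float | None:
        """Frequency of the dominant peak in ``band``, or None if no bin
        exceeds ``prominence_factor`` times the median band power."""
        mask = (self.frequencies >= band[0]) & (self.frequencies <= band[1])
        if not mask.any():
            return None
        p = self.power[mask]
        f = self.frequencies[mask]
        med = float(np.median(p))
        i = int(np.argmax(p))
        if med <= 0 or p[i] <= prominence_factor * med:
            return None
        return float(f[i])


@dataclass
class TremorMetrics:
    """Per-participant tremor summary used for screening and comparison."""

    postural_rms: float | None = None
    kinetic_rms: float | None = None
    peak_freq_unweighted: float | None = None
    peak_freq_weighted: float | None = None
    origin_class: str | None = None
    outlier_flag: bool = False


def _bandpass_sos(low: float, high: float, fs: float, order: int = FILTER_ORDER):
    return sps.butter(order, [low, high], btype="bandpass", fs=fs,
                      output="sos")


def bandpass_tremor(recording: TremorRecording | np.ndarray,
                    fs: float | None = None) -> np.ndarray:
    """Zero-phase 0.5-40 Hz band-pass of a tremor signal.

    A 4th-order Butterworth design applied forward and backward
    (`sosfiltfilt`), giving zero phase lag and an 8th-order effective
    magnitude response.  Removes DC and slow drift along with
    out-of-band noise.
    """
    if isinstance(recording, TremorRecording):
        x, fs = recording.samples, recording.fs
    else:
        x = np.asarray(recording, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if fs <= 2 * TREMOR_BAND[1]:
        raise ValueError(
            f"fs={fs} Hz too low for a {TREMOR_BAND[1]} Hz passband edge")
    if len(x) < 5 * fs:
        raise ValueError("recording shorter than 5 s; filtering unstable")
    sos = _bandpass_sos(*TREMOR_BAND, fs)
    return sps.sosfiltfilt(sos, x - np.mean(x))


def postural_rms(filtered: np.ndarray, fs: float,
                 edge_trim: float = EDGE_TRIM_S) -> float:
    """Root-mean-square amplitude of a filtered postural tremor signal.

    ``edge_trim`` seconds are discarded at each end to exclude the edge
    transients of the forward-backward filter.
    """
    x = np.asarray(filtered, dtype=float)
    n_trim = int(round(edge_trim * fs))
    if len(x) <= 2 * n_trim:
        raise ValueError("signal too short after edge trimming")
    core = x[n_trim:len(x) - n_trim] if n_trim else x
    if core.size == 0:
        raise ValueError("empty signal")
    return float(np.sqrt(np.mean(core ** 2)))


def segment_movements(angle: np.ndarray, fs: float,
                      excursion: float = 50.0,
                      analysis_span: float = 40.0,
                      lowpass_hz: float = 1.0,
                      tolerance: float = 5.0,
                      ) -> tuple[list[tuple[str, int, int]], bool]:
    """Identify extension/flexion phases of slow wrist ramp movements.

    The raw angle is low-passed (``lowpass_hz``, zero phase) to strip the
    superimposed tremor, then split into monotone half-cycles.  For each
    half-cycle spanning at least ``excursion - tolerance`` degrees, the
    middle ``analysis_span`` window (excluding the first and last
    ``(excursion - analysis_span)/2`` degrees) is returned as
    ``(phase, start_index, end_index)`` with phase "extension" (rising)
    or "flexion" (falling).

    Returns ``(windows, degraded)`` where ``degraded`` flags best-effort
    segmentation of trajectories that fall short of the full excursion.
    """
    x = np.asarray(angle, dtype=float)
    sos = sps.butter(2, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    smooth = sps.sosfiltfilt(sos, x)

    total_span = float(np.ptp(smooth))
    if total_span < tolerance:
        return [], True  # flat trajectory: nothing to segment

    # monotone runs of the smoothed trajectory
    d = np.diff(smooth)
    rising = d > 0
    change = np.flatnonzero(np.diff(rising.astype(int)) != 0) + 1
    bounds = np.concatenate(([0], change, [len(smooth) - 1]))

    margin = (excursion - analysis_span) / 2.0
    windows: list[tuple[str, int, int]] = []
    degraded = False
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < int(0.5 * fs):  # ignore sub-half-second jitter runs
            continue
        lo, hi = smooth[a], smooth[b]
        span = abs(hi - lo)
        if span < analysis_span:
            continue
        if span < excursion - tolerance:
            degraded = True
        phase = "extension" if hi > lo else "flexion"
        seg = smooth[a:b + 1]
        low_thr = min(lo, hi) + margin
        high_thr = max(lo, hi) - margin
        inside = np.flatnonzero((seg >= low_thr) & (seg <= high_thr))
        if inside.size < 2:
            continue
        windows.append((phase, a + int(inside[0]), a + int(inside[-1])))
    if not windows:
        degraded = True
    return windows, degraded


def kinetic_rms(filtered_angle: np.ndarray,
                windows: Sequence[tuple[str, int, int]]) -> float:
    """Average RMS of the band-passed angle over the movement windows.

    RMS is computed per phase window on the 0.5-40 Hz filtered angle
    (which removes the slow voluntary ramp) and averaged across windows.
    """
    if not windows:
        raise ValueError("no movement windows supplied")
    x = np.asarray(filtered_angle, dtype=float)
    vals = [float(np.sqrt(np.mean(x[a:b + 1] ** 2))) for _, a, b in windows]
    return float(np.mean(vals))


def process_emg(recording: EMGRecording | np.ndarray,
                mvc_max: float | None = None,
                fs: float | None = None) -> np.ndarray:
    """MVC-normalised EMG envelope.

    Chain: mean removal -> 20-450 Hz band-pass (4th order, zero phase)
    -> full-wave rectification -> 40 Hz low-pass (4th order, zero phase)
    -> division by ``mvc_max``.  Output is a dimensionless fraction of
    maximal voluntary activity.
    """
    if isinstance(recording, EMGRecording):
        x, fs = recording.samples, recording.fs
        if mvc_max is None:
            mvc_max = recording.mvc_max
    else:
        x = np.asarray(recording, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if mvc_max is None or mvc_max <= 0:
        raise ValueError("mvc_max must be positive")
    sos_bp = _bandpass_sos(*EMG_BAND, fs)
    sos_lp = sps.butter(FILTER_ORDER, EMG_ENVELOPE_LOWPASS, btype="lowpass",
                        fs=fs, output="sos")
    rectified = np.abs(sps.sosfiltfilt(sos_bp, x - np.mean(x)))
    return sps.sosfiltfilt(sos_lp, rectified) / mvc_max


def disjoint_spectrum(series: np.ndarray, fs: float,
                      segment_length: float = 5.0) -> PowerSpectrum:
    """Power spectral density by the method of disjoint segments.

    The series is cut into non-overlapping windows of ``segment_length``
    seconds (a trailing partial window is discarded); the one-sided
    periodogram of each window (rectangular taper, no detrending) is
    averaged.  Frequency resolution is ``1 / segment_length`` — 0.2 Hz
    for the standard 5 s windows, giving 12 segments from a 60 s
    recording at 200 Hz.
    """
    x = np.asarray(series, dtype=float)
    nperseg = int(round(segment_length * fs))
    if len(x) < nperseg:
        raise ValueError(
            f"series ({len(x)} samples) shorter than one "
            f"{segment_length} s segment ({nperseg} samples)")
    n_segments = len(x) // nperseg
    f, p = sps.welch(x[:n_segments * nperseg], fs=fs, window="boxcar",
                     nperseg=nperseg, noverlap=0, detrend=False,
                     scaling="density", average="mean")
    return PowerSpectrum(frequencies=f, power=p,
                         resolution=fs / nperseg,
                         n_segments=n_segments,
                         segment_length=nperseg / fs)


def classify_origin(spectrum_unweighted: PowerSpectrum,
                    spectrum_weighted: PowerSpectrum,
                    band: tuple[float, float] = PEAK_SEARCH_BAND,
                    shift_tolerance: float | None = None,
                    ) -> str:
    """Classify tremor origin from unweighted vs weighted spectra.

    A dominant peak that moves to a lower frequency under inertial
    loading (by more than ``shift_tolerance``, default one frequency
    bin) indicates mechanical-reflex rather than centrally generated
    tremor.  Returns ``"shifted-noncentral"``, ``"central-consistent"``
    or ``"no-peak"``.
    """
    fu, fw = spectrum_unweighted.frequencies, spectrum_weighted.frequencies
    if len(fu) != len(fw) or not np.allclose(fu, fw):
        raise ValueError("spectra must share an identical frequency grid")
    if shift_tolerance is None:
        shift_tolerance = spectrum_unweighted.resolution
    peak_u = spectrum_unweighted.band_peak(band)
    peak_w = spectrum_weighted.band_peak(band)
    if peak_u is None or peak_w is None:
        return "no-peak"
    if peak_u - peak_w > shift_tolerance:
        return "shifted-noncentral"
    return "central-consistent"


def screen_outliers(values_by_group: Mapping[str, Sequence[float]],
                    k: float = 3.0) -> dict[str, np.ndarray]:
    """Flag values more than ``k`` SD from their own group mean.

    Mean and SD are computed over the full group including the candidate
    point (no leave-one-out).  Groups with zero variance produce no
    flags.  Requires at least 3 values per group.
    """
    flags: dict[str, np.ndarray] = {}
    for group, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        if len(v) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 values")
        sd = float(np.std(v, ddof=1))
        if sd == 0:
            flags[group] = np.zeros(len(v), dtype=bool)
        else:
            flags[group] = np.abs(v - np.mean(v)) > k * sd
    return flags


def analyze_postural(recording: TremorRecording,
                     weighted: TremorRecording | None = None,
                     ) -> TremorMetrics:
    """End-to-end postural pipeline: filter, RMS, spectra, origin class."""
    filt = bandpass_tremor(recording)
    metrics = TremorMetrics(
        postural_rms=postural_rms(filt, recording.fs))
    spec_u = disjoint_spectrum(recording.samples, recording.fs)
    peak_u = spec_u.band_peak()
    metrics.peak_freq_unweighted = peak_u
    if weighted is not None:
        spec_w = disjoint_spectrum(weighted.samples, weighted.fs)
        metrics.peak_freq_weighted = spec_w.band_peak()
        metrics.origin_class = classify_origin(spec_u, spec_w)
    return metrics


def analyze_kinetic(recording: TremorRecording) -> TremorMetrics:
    """End-to-end kinetic pipeline: segment ramps, filter, windowed RMS."""
    windows, _ = segment_movements(recording.samples, recording.fs)
    filt = bandpass_tremor(recording)
    return TremorMetrics(kinetic_rms=kinetic_rms(filt, windows))
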