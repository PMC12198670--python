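"""Pre-processing chain for EEG/EMG trials.

Stages, in pipeline order: 50-Hz notch (2nd-order Butterworth band-stop,
49-51 Hz), 1-100 Hz band-pass, edge trimming (default 5 s per side), ECG
template subtraction from EMG, common-average re-referencing of the EEG block,
downsampling to 250 Hz, and segmentation of the 20-s trial into the 4-s
peak-search and 16-s analysis segments.

All filters are zero-phase (forward-backward) by default: the delay estimator
downstream measures lags of a few samples, and filter group delay would bias
it directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EEG, EMG, Recording, Trial
from .wavelets import WaveletBank, center_frequencies, cwt

__all__ = [
    "PreprocessConfig",
    "apply_filters",
    "trim_edges",
    "remove_ecg",
    "common_average_reference",
    "resample_250",
    "segment_trial",
    "preprocess_trial",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    notch_hz: float = 50.0
    notch_order: int = 2
    notch_bw_hz: float = 2.0
    hp_hz: float = 1.0
    lp_hz: float = 100.0
    bp_order: int = 4
    fs_target: float = 250.0
    trim_s: float = 5.0
    zero_phase: bool = True
    # ECG removal sub-steps.  QRS localisation uses wavelet intensity between
    # ecg_min_cf_hz and ecg_max_cf_hz: in the 4-7 Hz range the QRS impulse
    # dominates, surface EMG carries little power, and alpha-band rhythms
    # (>= 8 Hz) do not leak in.  Because these high-Q wavelets ring between
    # beats, the peak threshold is multiplicative (x median), not MAD-based.
    ecg_min_cf_hz: float = 4.0
    ecg_max_cf_hz: float = 7.0
    ecg_refractory_s: float = 0.3
    ecg_window_s: float = 0.15
    ecg_threshold_factor: float = 2.0
    ecg_min_beats: int = 5
    ecg_max_interval_cv: float = 0.25

    def __post_init__(self) -> None:
        if not (self.hp_hz < self.lp_hz < self.fs_target / 2):
            raise ValueError("requires hp_hz < lp_hz < fs_target/2")


def _sos_chain(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    if fs <= 2 * cfg.lp_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for low-pass at {cfg.lp_hz} Hz"
        )
    half_bw = cfg.notch_bw_hz / 2.0
    notch = signal.butter(
        cfg.notch_order,
        [cfg.notch_hz - half_bw, cfg.notch_hz + half_bw],
        btype="bandstop",
        fs=fs,
        output="sos",
    )
    hp = signal.butter(cfg.bp_order, cfg.hp_hz, btype="highpass", fs=fs, output="sos")
    lp = signal.butter(cfg.bp_order, cfg.lp_hz, btype="lowpass", fs=fs, output="sos")
    return np.vstack([notch, hp, lp])


def apply_filters(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Notch then band-pass every channel; zero-phase when configured."""
    sos = _sos_chain(cfg, rec.fs)
    out = rec.copy()
    if cfg.zero_phase:
        out.samples = signal.sosfiltfilt(sos, out.samples, axis=1)
    else:
        out.samples = signal.sosfilt(sos, out.samples, axis=1)
    return out


def trim_edges(rec: Recording, trim_s: float) -> Recording:
    """Drop ``trim_s`` seconds from both ends (transient removal)."""
    if trim_s < 0:
        raise ValueError("trim_s must be >= 0")
    n_trim = int(round(trim_s * rec.fs))
    if rec.n_samples <= 2 * n_trim:
        raise ValueError(
            f"recording of {rec.duration_s:g} s too short to trim {trim_s:g} s per side"
        )
    out = rec.copy()
    out.samples = out.samples[:, n_trim : rec.n_samples - n_trim].copy()
    return out


def _low_cf_intensity(
    x: np.ndarray, fs: float, max_cf: float, min_cf: float = 0.0
) -> np.ndarray:
    """Wavelet intensity (summed squared modulus) at low center frequencies,
    used to localise QRS events."""
    cfs = center_frequencies()
    cfs = cfs[(cfs >= min_cf) & (cfs <= max_cf)]
    bank = WaveletBank(cfs=cfs)
    coeff = cwt(x, bank, fs, pad_policy="pow2").coefficients
    return np.sum(np.abs(coeff) ** 2, axis=0)


def remove_ecg(
    emg_channel: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract ECG contamination from one EMG channel.

    (i) wavelet intensity at low center frequencies (4-7 Hz) localises QRS
    events; (ii) beats are intensity peaks above a multiple of the median
    intensity with a >= 300 ms refractory period, accepted only if they form
    a regular rhythm; (iii) an ensemble-average beat template is built;
    (iv) the smoothed template, least-squares scaled per beat, is subtracted.
    Returns (cleaned channel, beat times in seconds); with no accepted beats
    the input is returned unchanged.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(emg_channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("remove_ecg expects a single channel")
    # QRS localisation runs on an anti-aliased ~100-Hz copy (the intensity
    # trace lives below ~10 Hz); beat times are then refined at native rate.
    dec = max(int(fs // 100), 1)
    if dec > 1:
        lp = signal.butter(4, 0.4 * fs / dec, btype="lowpass", fs=fs, output="sos")
        x_smooth = signal.sosfiltfilt(lp, x)
        x_low = x_smooth[::dec]
    else:
        x_smooth = x
        x_low = x
    fs_low = fs / dec
    intensity = _low_cf_intensity(x_low, fs_low, cfg.ecg_max_cf_hz, cfg.ecg_min_cf_hz)
    med = np.median(intensity)
    height = cfg.ecg_threshold_factor * max(med, 1e-12)
    coarse, _ = signal.find_peaks(
        intensity, height=height, distance=max(int(cfg.ecg_refractory_s * fs_low), 1)
    )
    refine = int(round(0.025 * fs))
    peaks = []
    for c in coarse:
        i = c * dec
        lo, hi = max(i - refine, 0), min(i + refine + 1, len(x))
        peaks.append(lo + int(np.argmax(np.abs(x_smooth[lo:hi]))))
    peaks = np.asarray(peaks, dtype=int)
    half = int(round(cfg.ecg_window_s * fs))
    peaks = peaks[(peaks >= half) & (peaks < len(x) - half)]
    # plausibility gate: enough beats and a regular rhythm, otherwise the
    # "template" would be an average of unrelated EMG stretches
    intervals = np.diff(peaks) / fs
    regular = (
        len(peaks) >= cfg.ecg_min_beats
        and intervals.std() / max(intervals.mean(), 1e-9) <= cfg.ecg_max_interval_cv
    )
    if not regular:
        log.info(
            "remove_ecg: %d peak(s), rhythm not ECG-like; channel left unchanged",
            len(peaks),
        )
        return x.copy(), np.array([])

    segments = np.stack([x[p - half : p + half] for p in peaks])
    template = segments.mean(axis=0)
    win = min(2 * int(0.005 * fs) + 1, len(template) - 1)
    if win >= 5:
        template = signal.savgol_filter(template, win, 3)
    denom = float(np.dot(template, template))
    cleaned = x.copy()
    for p in peaks:
        seg = cleaned[p - half : p + half]
        a = float(np.dot(seg, template)) / denom
        cleaned[p - half : p + half] = seg - a * template
    return cleaned, peaks / fs


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the per-sample mean across EEG channels from each EEG channel."""
    eeg_idx = [i for i, r in enumerate(rec.roles) if r == EEG]
    if len(eeg_idx) < 2:
        raise ValueError("common average reference requires >= 2 EEG channels")
    out = rec.copy()
    block = out.samples[eeg_idx]
    out.samples[eeg_idx] = block - block.mean(axis=0, keepdims=True)
    return out


def resample_250(rec: Recording, fs_target: float = 250.0) -> Recording:
    """Decimate to ``fs_target`` by integer-stride slicing.

    Valid only after the 100-Hz low-pass (which precludes aliasing).  The
    sampling rate must be an integer multiple of the target.
    """
    ratio = rec.fs / fs_target
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fs {rec.fs} Hz is not an integer multiple of {fs_target} Hz; "
            "resample externally (e.g. polyphase) before this stage"
        )
    step = int(round(ratio))
    out = rec.copy()
    if step > 1:
        out.samples = out.samples[:, ::step].copy()
    out.fs = fs_target
    return out


def segment_trial(
    rec: Recording, peak_s: float = 4.0, analysis_s: float = 16.0
) -> tuple[Recording, Recording]:
    """Split a trimmed 20-s trial into the 4-s peak-search and 16-s analysis
    segments (no overlap; their concatenation reconstructs the input)."""
    n_peak = int(round(peak_s * rec.fs))
    n_total = n_peak + int(round(analysis_s * rec.fs))
    if rec.n_samples != n_total:
        raise ValueError(
            f"expected {n_total} samples ({peak_s + analysis_s:g} s at {rec.fs:g} Hz), "
            f"got {rec.n_samples}"
        )
    peak = rec.copy()
    peak.samples = rec.samples[:, :n_peak].copy()
    peak.meta = {**rec.meta, "segment": "peak_4s"}
    analysis = rec.copy()
    analysis.samples = rec.samples[:, n_peak:].copy()
    analysis.meta = {**rec.meta, "segment": "analysis_16s"}
    return peak, analysis


def preprocess_trial(
    trial: Trial, cfg: PreprocessConfig | None = None
) -> Recording:
    """Full chain on one trial; returns a merged 250-Hz Recording.

    Order: notch -> band-pass -> trim -> ECG removal (EMG only) -> common
    average reference (EEG only) -> downsample to 250 Hz.
    """
    cfg = cfg or PreprocessConfig()
    eeg = trim_edges(apply_filters(trial.eeg, cfg), cfg.trim_s)
    eeg = common_average_reference(eeg)
    eeg = resample_250(eeg, cfg.fs_target)

    emg = trim_edges(apply_filters(trial.emg, cfg), cfg.trim_s)
    beats = {}
    for i, lb in enumerate(emg.labels):
        emg.samples[i], beats[lb] = remove_ecg(emg.samples[i], emg.fs, cfg)
    emg = resample_250(emg, cfg.fs_target)

    merged = Recording(
        np.vstack([eeg.samples, emg.samples]),
        cfg.fs_target,
        eeg.labels + emg.labels,
        eeg.roles + emg.roles,
        {**trial.meta, "ecg_beats_detected": {k: len(v) for k, v in beats.items()}},
    )
    return merged
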