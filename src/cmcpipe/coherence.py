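"""Windowed wavelet coherence between an EEG and an EMG channel.

The coherence estimator follows the windowed-average construction: the signal
pair is cut into non-overlapping windows (default 8 windows of 496 samples at
250 Hz, i.e. 1.984 s each, giving the 0.504-Hz spectral resolution of a
15.872-s record).  Within each window the cross-spectrum Wx * conj(Wy) and the
auto-spectra |Wx|^2, |Wy|^2 are averaged over time, the coherency is their
normalised ratio, and the window coherence is its modulus.  The reported value
per center frequency is the mean of the per-window coherences.

Note the within-window time average is essential: a per-sample ratio of the
printed coherency expression has modulus identically 1.  Averaging the spectra
first (then taking the modulus, then averaging across windows) is the estimator
consistent with coherence values below 1 and is what this module implements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelets import WaveletBank, cwt

__all__ = [
    "WindowingConfig",
    "BandDefinition",
    "DEFAULT_BANDS",
    "wavelet_coherence",
    "coherence_from_windows",
    "window_coefficients",
    "band_peak_frequency",
    "band_mean",
    "participant_peak_cf",
]


@dataclass(frozen=True)
class WindowingConfig:
    """Windowing of the analysis segment.

    Defaults give 8 x 496 samples = 3968 samples = 15.872 s at 250 Hz and a
    spectral resolution of 1 / 1.984 s = 0.504 Hz.
    """

    n_windows: int = 8
    window_samples: int = 496
    overlap: float = 0.0
    pad_policy: str = "pow2_double"

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.window_samples < 2:
            raise ValueError("window_samples must be >= 2")
        if self.overlap != 0.0:
            raise ValueError("only non-overlapping windows are supported")

    @property
    def n_samples(self) -> int:
        return self.n_windows * self.window_samples

    def window_s(self, fs: float) -> float:
        return self.window_samples / fs

    def resolution_hz(self, fs: float) -> float:
        """Spectral resolution 1 / window length."""
        return 1.0 / self.window_s(fs)

    def for_segment(self, n_samples: int) -> "WindowingConfig":
        """Same window length, as many full windows as fit in ``n_samples``."""
        n_win = n_samples // self.window_samples
        if n_win < 1:
            raise ValueError(
                f"segment of {n_samples} samples shorter than one window "
                f"({self.window_samples} samples)"
            )
        return WindowingConfig(n_win, self.window_samples, self.overlap, self.pad_policy)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")

    def mask(self, cfs: np.ndarray) -> np.ndarray:
        return (cfs >= self.lo) & (cfs <= self.hi)


#: Frequency bands used throughout: alpha 8-12, beta 13-30, low/high gamma.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "low_gamma": BandDefinition("low_gamma", 30.0, 45.0),
    "high_gamma": BandDefinition("high_gamma", 45.0, 63.0),
}


@dataclass
class CoherenceSpectrum:
    """Per-center-frequency coherence for one channel pair."""

    coherence: np.ndarray
    cfs: np.ndarray
    n_windows: int
    pair: tuple[str, str] = ("x", "y")
    segment: str = "analysis_16s"

    def __post_init__(self) -> None:
        self.coherence = np.asarray(self.coherence, dtype=float)
        self.cfs = np.asarray(self.cfs, dtype=float)
        if self.coherence.shape != self.cfs.shape:
            raise ValueError("coherence and cfs must align")

    def to_frame(self):
        """Tidy one-row-per-cf table (pair, segment, cf, coherence)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "eeg": self.pair[0],
                "emg": self.pair[1],
                "segment": self.segment,
                "cf_hz": self.cfs,
                "coherence": self.coherence,
            }
        )


def window_coefficients(
    x: np.ndarray, bank: WaveletBank, wincfg: WindowingConfig, fs: float,
    dtype=np.float64,
) -> np.ndarray:
    """Wavelet coefficients per window: shape (n_windows, n_cfs, window_samples).

    Accepts leading batch axes on ``x`` (…, n_samples)."""
    x = np.asarray(x, dtype=float)
    n = wincfg.n_samples
    if x.shape[-1] != n:
        raise ValueError(
            f"signal length {x.shape[-1]} != n_windows*window_samples = {n}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN or infinite samples")
    windows = x.reshape(x.shape[:-1] + (wincfg.n_windows, wincfg.window_samples))
    return cwt(windows, bank, fs, wincfg.pad_policy, dtype=dtype).coefficients


def coherence_from_windows(wx: np.ndarray, wy: np.ndarray) -> np.ndarray:
    """Coherence per cf from per-window coefficients (..., n_win, n_cfs, n_samp).

    Time-averages the cross- and auto-spectra within each window, forms the
    coherency modulus per window, and averages moduli across windows.
    """
    # real/imaginary einsums avoid large complex temporaries in the hot path
    xr, xi = wx.real, wx.imag
    yr, yi = wy.real, wy.imag
    n = wx.shape[-1]
    re = (np.einsum("...s,...s->...", xr, yr) + np.einsum("...s,...s->...", xi, yi)) / n
    im = (np.einsum("...s,...s->...", xi, yr) - np.einsum("...s,...s->...", xr, yi)) / n
    sxx = (np.einsum("...s,...s->...", xr, xr) + np.einsum("...s,...s->...", xi, xi)) / n
    syy = (np.einsum("...s,...s->...", yr, yr) + np.einsum("...s,...s->...", yi, yi)) / n
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_window = np.sqrt(re**2 + im**2) / denom
    per_window = np.where(denom > 0, per_window, 0.0)
    return np.clip(per_window.mean(axis=-2), 0.0, 1.0)


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    bank: WaveletBank,
    wincfg: WindowingConfig,
    fs: float = 250.0,
    pair: tuple[str, str] = ("x", "y"),
    segment: str = "analysis_16s",
) -> CoherenceSpectrum:
    """Windowed wavelet coherence between signals ``x`` and ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    wx = window_coefficients(x, bank, wincfg, fs)
    wy = window_coefficients(y, bank, wincfg, fs)
    coh = coherence_from_windows(wx, wy)
    return CoherenceSpectrum(coh, bank.cfs, wincfg.n_windows, pair, segment)


def band_peak_frequency(cohspec: CoherenceSpectrum, band: BandDefinition) -> float:
    """Center frequency with maximal coherence inside ``band``.

    Ties break to the lowest cf (argmax returns the first maximum on an
    ascending cf grid).
    """
    mask = band.mask(cohspec.cfs)
    if not mask.any():
        raise ValueError(f"no bank center frequency inside band {band.name}")
    cfs = cohspec.cfs[mask]
    coh = cohspec.coherence[mask]
    return float(cfs[int(np.argmax(coh))])


def band_mean(cohspec: CoherenceSpectrum, band: BandDefinition) -> float:
    """Mean coherence over the bank cfs inside ``band``."""
    mask = band.mask(cohspec.cfs)
    if not mask.any():
        raise ValueError(f"no bank center frequency inside band {band.name}")
    return float(cohspec.coherence[mask].mean())


def participant_peak_cf(
    peak_cfs: np.ndarray, bank: WaveletBank, method: str = "mean_of_argmax"
) -> float:
    """Participant-level peak frequency: per-trial peaks averaged, snapped to
    the nearest bank cf."""
    peak_cfs = np.atleast_1d(np.asarray(peak_cfs, dtype=float))
    if peak_cfs.size == 0:
        raise ValueError("no per-trial peak frequencies given")
    if method != "mean_of_argmax":
        raise ValueError(f"unknown method {method!r}")
    mean_cf = peak_cfs.mean()
    return float(bank.cfs[int(np.argmin(np.abs(bank.cfs - mean_cf)))])
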