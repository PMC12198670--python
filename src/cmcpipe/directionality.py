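"""Lag-scanned coherence: afferent/efferent CMC and transmission delays.

The EEG and EMG analysis segments are shifted against each other in
integer-sample steps (4 ms at 250 Hz) up to +/-128 ms, and the windowed
wavelet coherence at the band's peak center frequency is recomputed at every
lag on a fixed overlapping span of 3968 samples (15.872 s) so that values are
comparable across lags.  Positive lag means the EEG precedes the EMG
(efferent side: cortex -> muscle); negative lag means the EMG precedes the
EEG (afferent side).  After a 16-ms moving average, each side's maximum gives
that direction's CMC value and the coherence-maximising shift gives the
transmission-delay estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coherence import WindowingConfig, coherence_from_windows, window_coefficients
from .wavelets import WaveletBank

__all__ = [
    "LagProfile",
    "DirectionalCMC",
    "lagged_coherence",
    "smooth_lag_profile",
    "estimate_directional_cmc",
]


@dataclass
class LagProfile:
    """Coherence at one center frequency as a function of signal lag."""

    lags_ms: np.ndarray
    coherence: np.ndarray
    peak_cf: float
    fs: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.coherence = np.asarray(self.coherence, dtype=float)
        if self.lags_ms.shape != self.coherence.shape:
            raise ValueError("lags and coherence must align")


@dataclass
class DirectionalCMC:
    """Per-direction coherence maxima and delays for one pair and band."""

    peak_cf: float
    afferent_cmc: float
    efferent_cmc: float
    afferent_delay_ms: float
    efferent_delay_ms: float


def lagged_coherence(
    eeg: np.ndarray,
    emg: np.ndarray,
    peak_cf: float,
    bank: WaveletBank,
    wincfg: WindowingConfig,
    fs: float = 250.0,
    max_lag_ms: float = 128.0,
) -> LagProfile:
    """Coherence at ``peak_cf`` for every integer-sample lag within max_lag_ms.

    Sign convention: at lag +L the EEG sample stream is paired with EMG
    samples L later (EEG precedes EMG, efferent side).  All lags are evaluated
    on the same number of samples (n_windows * window_samples), the span that
    remains at the maximal shift.
    """
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if eeg.shape != emg.shape or eeg.ndim != 1:
        raise ValueError("eeg and emg must be equal-length 1-D segments")
    max_lag = int(round(max_lag_ms / 1000.0 * fs))
    n_keep = wincfg.n_samples
    if eeg.size < n_keep + max_lag:
        raise ValueError(
            f"segment of {eeg.size} samples too short for max lag {max_lag} samples "
            f"on a {n_keep}-sample span"
        )
    single = bank.single(peak_cf)
    starts = np.arange(max_lag + 1)
    # Wavelet coefficients of the retained span for every possible start
    # offset of each signal; shape (n_starts, n_windows, n_samples).
    wx = window_coefficients(
        np.stack([eeg[s : s + n_keep] for s in starts]), single, wincfg, fs
    )
    wy = window_coefficients(
        np.stack([emg[s : s + n_keep] for s in starts]), single, wincfg, fs
    )
    lags = np.arange(-max_lag, max_lag + 1)
    sx = np.maximum(0, -lags)
    sy = np.maximum(0, lags)
    coh = coherence_from_windows(wx[sx], wy[sy])[:, 0]  # (n_lags,)
    return LagProfile(
        lags_ms=lags * 1000.0 / fs, coherence=coh, peak_cf=peak_cf, fs=fs
    )


def smooth_lag_profile(profile: LagProfile, span_ms: float = 16.0) -> LagProfile:
    """Centered moving average over ``span_ms`` (5 points at 4-ms spacing;
    the nearest odd point count).  Edges use the available shrinking window."""
    step_ms = 1000.0 / profile.fs
    n_pts = int(round(span_ms / step_ms))
    if n_pts % 2 == 0:
        n_pts += 1
    n_pts = max(n_pts, 1)
    kernel = np.ones(n_pts)
    num = np.convolve(profile.coherence, kernel, mode="same")
    den = np.convolve(np.ones_like(profile.coherence), kernel, mode="same")
    return LagProfile(
        lags_ms=profile.lags_ms.copy(),
        coherence=num / den,
        peak_cf=profile.peak_cf,
        fs=profile.fs,
        smoothed=True,
    )


def _side_argmax(lags: np.ndarray, coh: np.ndarray) -> tuple[float, float]:
    """(delay_ms, cmc) of one side; ties break to the smallest |lag|."""
    order = np.argsort(np.abs(lags), kind="stable")
    coh_sorted = coh[order]
    best = int(np.argmax(coh_sorted))  # first maximum -> smallest |lag|
    return float(abs(lags[order][best])), float(coh_sorted[best])


def estimate_directional_cmc(profile: LagProfile) -> DirectionalCMC:
    """Per-direction delay and CMC from a (smoothed) lag profile.

    Efferent side: lags > 0; afferent side: lags < 0; lag 0 belongs to
    neither.
    """
    lags = profile.lags_ms
    coh = profile.coherence
    eff = lags > 0
    aff = lags < 0
    if not eff.any() or not aff.any():
        raise ValueError("lag profile must contain both positive and negative lags")
    eff_delay, eff_cmc = _side_argmax(lags[eff], coh[eff])
    aff_delay, aff_cmc = _side_argmax(lags[aff], coh[aff])
    return DirectionalCMC(
        peak_cf=profile.peak_cf,
        afferent_cmc=aff_cmc,
        efferent_cmc=eff_cmc,
        afferent_delay_ms=aff_delay,
        efferent_delay_ms=eff_delay,
    )
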