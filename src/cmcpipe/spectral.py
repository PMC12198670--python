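"""Power spectral density of EEG channels and band-power summaries.

PSDs are averaged periodograms of non-overlapping, zero-padded 2-s boxcar
windows, normalised as a density (µV²/Hz) so that the integral over frequency
approximates the signal variance.  Zero-padding refines the frequency grid
only; where the zeros are placed (symmetrically or at the end) does not affect
the magnitude spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .coherence import BandDefinition

__all__ = ["PowerSpectrum", "psd_boxcar", "band_power", "average_psd"]


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray  # µV²/Hz
    channel: str = ""
    n_windows: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must align")


def _pad_length(n: int, pad_policy: str) -> int:
    if pad_policy == "pow2_double":
        return int(2 ** np.ceil(np.log2(2 * n)))
    if pad_policy == "none":
        return n
    raise ValueError(f"unknown pad_policy {pad_policy!r}")


def psd_boxcar(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    pad_policy: str = "pow2_double",
    channel: str = "",
) -> PowerSpectrum:
    """Averaged periodogram over non-overlapping zero-padded boxcar windows."""
    x = np.asarray(x, dtype=float)
    n_win = int(round(window_s * fs))
    if x.size < n_win:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {window_s:g}-s window"
        )
    nfft = _pad_length(n_win, pad_policy)
    freqs, power = signal.welch(
        x[: (x.size // n_win) * n_win],
        fs=fs,
        window="boxcar",
        nperseg=n_win,
        noverlap=0,
        nfft=nfft,
        detrend=False,
        scaling="density",
    )
    return PowerSpectrum(freqs, power, channel=channel, n_windows=x.size // n_win)


def band_power(spectrum: PowerSpectrum, band: BandDefinition) -> float:
    """Trapezoidal integral of the density over [band.lo, band.hi], in µV²."""
    f = spectrum.freqs
    if band.lo < f[0] or band.hi > f[-1]:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}] outside spectrum range "
            f"[{f[0]:g}, {f[-1]:g}]"
        )
    mask = (f >= band.lo) & (f <= band.hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band.name} covers fewer than two frequency bins")
    return float(np.trapezoid(spectrum.power[mask], f[mask]))


def average_psd(spectra: list[PowerSpectrum]) -> pd.DataFrame:
    """Mean power and standard error of the mean across spectra on a shared
    frequency grid (the display convention for group-level PSD curves)."""
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != f0.shape or not np.allclose(s.freqs, f0):
            raise ValueError("spectra must share a frequency grid")
    stack = np.stack([s.power for s in spectra])
    mean = stack.mean(axis=0)
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        if stack.shape[0] > 1
        else np.zeros_like(mean)
    )
    return pd.DataFrame({"freq_hz": f0, "mean_power": mean, "sem": sem})
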