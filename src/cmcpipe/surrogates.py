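"""AAFT surrogates and the coherence significance threshold.

Amplitude-adjusted Fourier-transform surrogates destroy all cross-signal
dependence (and any nonlinear structure) while preserving the exact value
distribution of the original signal and, approximately, its power spectrum.
Surrogating both channels of a pair independently therefore realises the null
hypothesis "EEG and EMG were collected with no mutual coupling", and the
distribution of band-mean coherence across surrogate pairs yields a per-trial
significance threshold.

The threshold statistic is the median of the surrogate band-mean coherences
by default (a coherence value exceeds it by chance about half the time); a
percentile statistic is available for stricter thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coherence import (
    BandDefinition,
    WindowingConfig,
    coherence_from_windows,
    window_coefficients,
)
from .wavelets import WaveletBank

__all__ = ["SurrogateConfig", "aaft", "coherence_threshold", "significance_mask"]


@dataclass(frozen=True)
class SurrogateConfig:
    n_surrogates: int = 100
    statistic: str = "median"
    percentile: float = 95.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 2:
            raise ValueError("n_surrogates must be >= 2")
        if self.statistic not in ("median", "percentile"):
            raise ValueError("statistic must be 'median' or 'percentile'")
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must lie in (0, 100)")

    def threshold_of(self, values: np.ndarray) -> float:
        if self.statistic == "median":
            return float(np.median(values))
        return float(np.percentile(values, self.percentile))


def _ranks(a: np.ndarray) -> np.ndarray:
    """Ordinal ranks along the last axis."""
    return np.argsort(np.argsort(a, axis=-1, kind="stable"), axis=-1, kind="stable")


def aaft(x: np.ndarray, seed, n_surrogates: int = 1) -> np.ndarray:
    """Amplitude-adjusted Fourier-transform surrogate(s) of ``x``.

    Steps: Gaussian noise is rank-reordered to follow x's ranks; that
    Gaussianised series is phase-randomised (Hermitian-symmetric, so the
    result stays real); finally x's sorted values are remapped onto the ranks
    of the phase-randomised series.  The surrogate's sorted values equal x's
    sorted values exactly.

    ``seed`` may be an int or a numpy Generator.  Returns a 1-D array when
    n_surrogates == 1, else (n_surrogates, n).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("aaft requires a 1-D signal of length >= 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("aaft requires finite input")
    if np.ptp(x) == 0:
        raise ValueError("aaft undefined for a constant signal (ranks degenerate)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.size
    m = n_surrogates
    sorted_x = np.sort(x)
    rank_x = _ranks(x)

    gauss = np.sort(rng.standard_normal((m, n)), axis=-1)[:, rank_x]
    spec = np.fft.rfft(gauss, axis=-1)
    phases = np.exp(2j * np.pi * rng.random(spec.shape))
    phases[:, 0] = 1.0
    if n % 2 == 0:
        phases[:, -1] = 1.0
    randomized = np.fft.irfft(spec * phases, n=n, axis=-1)
    surr = sorted_x[_ranks(randomized)]
    return surr[0] if n_surrogates == 1 else surr


def surrogate_band_coherences(
    x: np.ndarray,
    y: np.ndarray,
    bank: WaveletBank,
    wincfg: WindowingConfig,
    band: BandDefinition,
    cfg: SurrogateConfig,
    fs: float = 250.0,
) -> np.ndarray:
    """Band-mean coherence of each of n_surrogates independently surrogated
    pairs (vectorised across surrogates)."""
    rng = np.random.default_rng(cfg.seed)
    sub = bank.subset(band.lo, band.hi)
    sx = aaft(np.asarray(x, float), rng, cfg.n_surrogates)
    sy = aaft(np.asarray(y, float), rng, cfg.n_surrogates)
    wx = window_coefficients(sx, sub, wincfg, fs)  # (m, n_win, n_cfs, n_samp)
    wy = window_coefficients(sy, sub, wincfg, fs)
    coh = coherence_from_windows(wx, wy)  # (m, n_cfs)
    return coh.mean(axis=-1)


def coherence_threshold(
    x: np.ndarray,
    y: np.ndarray,
    bank: WaveletBank,
    wincfg: WindowingConfig,
    band: BandDefinition,
    cfg: SurrogateConfig,
    fs: float = 250.0,
) -> float:
    """Significance threshold for the band-mean coherence of the pair (x, y).

    Deterministic given cfg.seed."""
    values = surrogate_band_coherences(x, y, bank, wincfg, band, cfg, fs)
    return cfg.threshold_of(values)


def significance_mask(band_means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag which (trial, band, ...) records exceed their threshold.

    ``band_means`` must contain columns 'band_mean' and 'threshold'; any other
    columns (trial, band, pair, ...) are carried through.  Returns the mask
    table (with a boolean 'retained') and a per-band retention summary.
    """
    for col in ("band_mean", "threshold"):
        if col not in band_means.columns:
            raise ValueError(f"band_means table lacks column {col!r}")
    mask = band_means.copy()
    mask["retained"] = mask["band_mean"] > mask["threshold"]
    if "band" in mask.columns:
        summary = (
            mask.groupby("band", sort=False)["retained"]
            .agg(retained_fraction="mean", n="size")
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            {"band": ["all"], "retained_fraction": [mask["retained"].mean()],
             "n": [len(mask)]}
        )
    return mask, summary
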