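"""Complex Cauchy wavelet family and the frequency-domain continuous wavelet transform.

The family is defined directly in Fourier space.  Each wavelet is a unimodal
gain function

    F_psi(f; cf) = (f / cf)**mode * exp((1 - f / cf) * mode),    mode = cf * scale,

which attains its maximum value 1 exactly at the center frequency ``cf`` and
vanishes at f = 0.  The bank's center frequencies follow the non-linear rule

    cf_j = (1 / scale) * (j + q)**r

so that relative bandwidth stays roughly constant across the bank.  With the
default parameters (scale 12, q 1.45, r 1.959, j = 1..30) the bank spans
~0.48 Hz to ~71.6 Hz in 30 steps.

The transform is evaluated per analysis window: the window is zero-padded
symmetrically, Fourier transformed, multiplied by the one-sided gain (negative
frequencies zeroed, which makes the coefficients analytic and phase-bearing),
and transformed back.  Coefficients are returned cropped to the original
window span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveletBank",
    "TimeFrequencyMap",
    "center_frequencies",
    "wavelet_filter",
    "cwt",
]


def center_frequencies(
    scale: float = 12.0,
    q: float = 1.45,
    r: float = 1.959,
    j_range: tuple[int, int] = (1, 30),
) -> np.ndarray:
    """Center frequencies cf_j = (1/scale) * (j + q)**r in Hz.

    ``j_range`` is inclusive on both ends.  The result is strictly increasing.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if r <= 0:
        raise ValueError("r must be positive")
    j_lo, j_hi = j_range
    if j_hi < j_lo:
        raise ValueError(f"empty j_range {j_range}")
    j = np.arange(j_lo, j_hi + 1, dtype=float)
    return (1.0 / scale) * (j + q) ** r


@dataclass(frozen=True)
class WaveletBank:
    """A family of frequency-domain Cauchy wavelets.

    ``cfs`` is derived from (scale, q, r, j_range) unless given explicitly,
    which the lag-scan stage uses to evaluate a single center frequency.
    """

    scale: float = 12.0
    q: float = 1.45
    r: float = 1.959
    j_range: tuple[int, int] = (1, 30)
    cfs: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cfs is None:
            cfs = center_frequencies(self.scale, self.q, self.r, self.j_range)
        else:
            cfs = np.atleast_1d(np.asarray(self.cfs, dtype=float))
            if cfs.ndim != 1 or cfs.size == 0:
                raise ValueError("cfs must be a non-empty 1-D sequence")
            if np.any(cfs <= 0):
                raise ValueError("center frequencies must be positive")
            if cfs.size > 1 and np.any(np.diff(cfs) <= 0):
                raise ValueError("center frequencies must be strictly increasing")
        object.__setattr__(self, "cfs", cfs)

    @property
    def modes(self) -> np.ndarray:
        """Per-cf exponent mode = cf * scale."""
        return self.cfs * self.scale

    @property
    def n_cfs(self) -> int:
        return int(self.cfs.size)

    def single(self, cf: float) -> "WaveletBank":
        """A one-wavelet bank at ``cf`` with this bank's scale."""
        return WaveletBank(scale=self.scale, q=self.q, r=self.r, cfs=np.array([cf]))

    def subset(self, lo: float, hi: float) -> "WaveletBank":
        """Bank restricted to cfs within [lo, hi] (inclusive)."""
        keep = (self.cfs >= lo) & (self.cfs <= hi)
        if not keep.any():
            raise ValueError(f"no center frequency inside [{lo}, {hi}] Hz")
        return WaveletBank(scale=self.scale, q=self.q, r=self.r, cfs=self.cfs[keep])

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "q": self.q,
            "r": self.r,
            "j_range": list(self.j_range),
            "cfs_hz": [float(c) for c in self.cfs],
        }


@dataclass
class TimeFrequencyMap:
    """Complex wavelet coefficients, shape (..., n_cfs, n_samples)."""

    coefficients: np.ndarray
    cfs: np.ndarray
    fs: float


def wavelet_filter(f_axis: np.ndarray, cf: float, scale: float = 12.0) -> np.ndarray:
    """Frequency-domain gain of the Cauchy wavelet centered at ``cf``.

    Evaluated in log-space to avoid overflow: the exponent
    mode * (log(f/cf) + 1 - f/cf) is <= 0 for all f > 0, so the gain lies in
    [0, 1] with its maximum 1 at f = cf.  Gain at f <= 0 is 0.
    """
    if cf <= 0:
        raise ValueError("cf must be positive")
    f = np.asarray(f_axis, dtype=float)
    mode = cf * scale
    gain = np.zeros_like(f)
    pos = f > 0
    ratio = f[pos] / cf
    gain[pos] = np.exp(mode * (np.log(ratio) + 1.0 - ratio))
    return gain


def _pad_length(n: int, pad_policy: str) -> int:
    if pad_policy == "pow2_double":
        return int(2 ** np.ceil(np.log2(2 * n)))
    if pad_policy == "pow2":
        return int(2 ** np.ceil(np.log2(n)))
    if pad_policy == "none":
        return n
    raise ValueError(f"unknown pad_policy {pad_policy!r}")


def bank_gains(bank: WaveletBank, n_pad: int, fs: float) -> np.ndarray:
    """Gain matrix (n_cfs, n_pad) on the full FFT grid, one-sided."""
    f = np.fft.fftfreq(n_pad, d=1.0 / fs)
    gains = np.zeros((bank.n_cfs, n_pad))
    pos = f > 0
    ratio = f[pos][None, :] / bank.cfs[:, None]
    gains[:, pos] = np.exp(bank.modes[:, None] * (np.log(ratio) + 1.0 - ratio))
    return gains


def cwt(
    window_samples: np.ndarray,
    bank: WaveletBank,
    fs: float,
    pad_policy: str = "pow2_double",
    dtype=np.float64,
) -> TimeFrequencyMap:
    """Continuous wavelet transform of one or many windows.

    ``window_samples`` may have any leading batch shape; the transform acts on
    the last axis.  Each window is zero-padded symmetrically to the padded
    length, filtered with the one-sided bank gains (yielding analytic complex
    coefficients), and cropped back to the input span.  Linear in the input.
    ``dtype`` may be float32 for throughput-critical batch use.
    """
    from scipy import fft as sp_fft

    x = np.asarray(window_samples, dtype=dtype)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("window must contain at least 2 samples")
    n_pad = _pad_length(n, pad_policy)
    left = (n_pad - n) // 2
    xp = np.zeros(x.shape[:-1] + (n_pad,), dtype=dtype)
    xp[..., left : left + n] = x
    # the gains are one-sided (f <= 0 zeroed), so the forward transform only
    # needs the non-negative half of the spectrum
    half = sp_fft.rfft(xp, axis=-1)
    ctype = np.complex64 if dtype == np.float32 else np.complex128
    spectrum = np.zeros(x.shape[:-1] + (len(bank.cfs), n_pad), dtype=ctype)
    gains = bank_gains(bank, n_pad, fs)[..., : half.shape[-1]].astype(dtype)
    spectrum[..., : half.shape[-1]] = half[..., None, :] * gains
    coeff = sp_fft.ifft(spectrum, axis=-1, overwrite_x=True)
    coeff = coeff[..., left : left + n]
    return TimeFrequencyMap(coefficients=coeff, cfs=bank.cfs.copy(), fs=fs)
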