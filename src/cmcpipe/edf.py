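"""Minimal EDF writer for single-rate multichannel recordings.

Writes plain EDF (16-bit, little-endian, 1-second data records) with physical
units of microvolts.  Only what the pipeline needs is implemented: one
sampling rate per file and integer-second durations.  Reading is done through
``mne.io.read_raw_edf`` (see :mod:`cmcpipe.io`), which also serves as an
independent check of this writer.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .recording import Recording

__all__ = ["write_edf"]


def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path) -> None:
    """Write ``rec`` to ``path`` in EDF format.

    The recording must contain an integer number of seconds; each channel is
    scaled independently to the full 16-bit digital range, so quantization
    error is at most (physical range) / 2**16 per channel.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples / fs
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValueError("EDF writer requires an integer number of seconds")
    n_records = int(round(n_records))
    n_sig = rec.n_channels

    dig_min, dig_max = -32768, 32767
    phys_min = np.floor(rec.samples.min(axis=1) - 1.0)
    phys_max = np.ceil(rec.samples.max(axis=1) + 1.0)

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)  # local patient identification
    header += _ascii("Startdate X X X X", 80)
    now = _dt.datetime(2000, 1, 1)
    header += _ascii(now.strftime("%d.%m.%y"), 8)
    header += _ascii(now.strftime("%H.%M.%S"), 8)
    header += _ascii(str(256 * (1 + n_sig)), 8)
    header += _ascii("", 44)
    header += _ascii(str(n_records), 8)
    header += _ascii("1", 8)  # record duration, seconds
    header += _ascii(str(n_sig), 4)

    fields = [
        [_ascii(lb, 16) for lb in rec.labels],
        [_ascii("", 80)] * n_sig,
        [_ascii("uV", 8)] * n_sig,
        [_ascii(f"{phys_min[i]:g}", 8) for i in range(n_sig)],
        [_ascii(f"{phys_max[i]:g}", 8) for i in range(n_sig)],
        [_ascii(str(dig_min), 8)] * n_sig,
        [_ascii(str(dig_max), 8)] * n_sig,
        [_ascii("", 80)] * n_sig,
        [_ascii(str(fs), 8)] * n_sig,
        [_ascii("", 32)] * n_sig,
    ]
    for group in fields:
        for item in group:
            header += item

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - dig_min * scale
    digital = np.round((rec.samples - offset[:, None]) / scale[:, None])
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())
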