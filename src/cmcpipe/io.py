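"""Reading and writing recordings: EDF (via mne) and delimited text.

The delimited format is a tab-separated table of channels in columns, preceded
by ``#``-prefixed header lines carrying the sampling rate, channel roles and
trial metadata, so a file round-trips to an identical Recording.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .edf import write_edf
from .recording import EEG, EMG, Recording

__all__ = ["read_recording", "write_recording", "write_edf", "infer_roles"]

#: Channel labels recognised as EEG (10-20 motor strip) / EMG (SENIAM names).
KNOWN_EEG = {"C3", "C4", "Cz", "FC1", "FC2", "FC5", "FC6", "CP1", "CP2", "Fz", "Pz"}
KNOWN_EMG = {"ExO", "ES", "TA", "GM"}


def infer_roles(labels: list[str]) -> list[str]:
    """Infer per-channel roles from electrode names."""
    roles = []
    for lb in labels:
        base = lb.split("-")[0].strip()
        if base in KNOWN_EEG or base.upper().startswith("EEG"):
            roles.append(EEG)
        elif base in KNOWN_EMG or base.upper().startswith("EMG"):
            roles.append(EMG)
        else:
            raise IOError(f"cannot infer role of channel {base!r}")
    return roles


def write_recording(rec: Recording, path, format: str = "delimited") -> None:
    """Write a recording as EDF or delimited text (format by name or suffix)."""
    path = Path(path)
    if format == "edf" or (format == "auto" and path.suffix.lower() == ".edf"):
        write_edf(rec, path)
        return
    with open(path, "w") as fh:
        fh.write(f"# fs_hz: {rec.fs:g}\n")
        fh.write(f"# roles: {json.dumps(dict(zip(rec.labels, rec.roles)))}\n")
        if rec.meta:
            fh.write(f"# meta: {json.dumps(rec.meta)}\n")
        fh.write("\t".join(rec.labels) + "\n")
        np.savetxt(fh, rec.samples.T, fmt="%.6f", delimiter="\t")


def _read_delimited(path: Path) -> Recording:
    fs = None
    roles_map: dict = {}
    meta: dict = {}
    labels: list[str] | None = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                key = key.strip()
                if key == "fs_hz":
                    fs = float(value)
                elif key == "roles":
                    roles_map = json.loads(value)
                elif key == "meta":
                    meta = json.loads(value)
                continue
            if labels is None:
                labels = line.split("\t")
                continue
            parts = line.split("\t")
            if len(parts) != len(labels):
                raise IOError(
                    f"{path}: row {lineno} has {len(parts)} fields, expected {len(labels)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise IOError(f"{path}: row {lineno}: {exc}") from None
    if labels is None or not rows:
        raise IOError(f"{path}: no data rows found")
    if fs is None:
        raise IOError(f"{path}: missing '# fs_hz:' header")
    samples = np.asarray(rows, dtype=float).T
    roles = [roles_map[lb] for lb in labels] if roles_map else infer_roles(labels)
    return Recording(samples, fs, labels, roles, meta)


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if not labels:
        raise IOError(f"{path}: no channels found")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data, fs, labels, infer_roles(labels), {"source": str(path)})


def read_recording(path, format: str = "auto") -> Recording:
    """Read a Recording from an EDF or delimited-text file."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise IOError(f"empty file: {path}")
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {format!r}")
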