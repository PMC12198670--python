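"""In-memory containers for multichannel biosignal blocks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording", "Trial", "EEG", "EMG"]

EEG = "EEG"
EMG = "EMG"


@dataclass
class Recording:
    """A block of synchronously sampled channels.

    samples : (n_channels, n_samples) float array, microvolts
    fs      : sampling rate in Hz, shared by all channels
    labels  : unique channel names
    roles   : per-channel modality, "EEG" or "EMG"
    meta    : free-form identifiers (participant, group, task, trial, ...)
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    roles: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if len(self.roles) != len(self.labels):
            raise ValueError("roles must align with labels")
        bad = [r for r in self.roles if r not in (EEG, EMG)]
        if bad:
            raise ValueError(f"unknown channel roles {bad}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None
        return self.samples[idx]

    def select(self, labels: list[str]) -> "Recording":
        idx = [self.labels.index(lb) for lb in labels]
        return Recording(
            self.samples[idx].copy(),
            self.fs,
            [self.labels[i] for i in idx],
            [self.roles[i] for i in idx],
            dict(self.meta),
        )

    def by_role(self, role: str) -> "Recording":
        labels = [lb for lb, r in zip(self.labels, self.roles) if r == role]
        if not labels:
            raise ValueError(f"no channels with role {role}")
        return self.select(labels)

    def copy(self) -> "Recording":
        return Recording(
            self.samples.copy(), self.fs, list(self.labels), list(self.roles), dict(self.meta)
        )


@dataclass
class Trial:
    """One standing trial: an EEG block and an EMG block, plus generator truth.

    EEG and EMG are kept as separate Recordings because they are sampled at
    different native rates (500 Hz and 2000 Hz); the preprocessing chain merges
    them once both are at 250 Hz.
    """

    eeg: Recording
    emg: Recording
    truth: dict = field(default_factory=dict)

    @property
    def meta(self) -> dict:
        return self.eeg.meta
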