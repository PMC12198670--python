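"""Synthetic coupled EEG/EMG trial and cohort generation with known ground truth.

Every trial contains a band-limited Gaussian "cortical drive" that appears in
the EEG channels (with channel-specific gains, so that common-average
re-referencing leaves a non-zero residual in every channel) and is transmitted
to the EMG channels with a directional delay.  The EMG model carries the
coupling two ways at once: the delayed drive amplitude-modulates a broadband
carrier (the physiological picture of a common central drive gating motor-unit
activity) and a scaled copy of the delayed band-limited drive is added
directly, which guarantees genuine narrow-band linear EEG-EMG coherence that
the wavelet-coherence estimator can detect.  Optional 50-Hz line interference
and a QRS-like ECG pulse train (with +/-10 % beat-to-beat amplitude jitter)
contaminate the EMG channels.

Cohorts mirror the study layout: two groups, three standing tasks (EO, EC,
DT), seven 30-s trials per task by default, with per-(group, task, band,
direction) coupling-gain multipliers to inject known effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .recording import EEG, EMG, Recording, Trial

__all__ = [
    "CouplingSpec",
    "CohortDesign",
    "make_coupled_trial",
    "make_cohort",
    "BAND_COMPONENTS",
    "EEG_LABELS",
    "EMG_TRUNK_LABELS",
    "EMG_LEG_LABELS",
]

#: EEG electrode names (10-20 motor-cortex subset used for CMC).
EEG_LABELS = ["C3", "Cz", "FC1"]
#: Per-channel drive gains; chosen so no gain equals their mean and the
#: common-average-referenced residual drive is non-zero in every channel.
EEG_DRIVE_GAINS = np.array([1.0, 0.6, 0.5])

#: SENIAM-style EMG electrode names for trunk and leg muscles.
EMG_TRUNK_LABELS = ["ExO", "ES"]
EMG_LEG_LABELS = ["TA", "GM"]

#: Default coupling component per frequency band: (center Hz, bandwidth Hz).
BAND_COMPONENTS = {"alpha": (10.0, 4.0), "beta": (21.0, 8.0)}

DIRECTIONS = ("efferent", "afferent", "none")


@dataclass(frozen=True)
class CouplingSpec:
    """Parameters of one synthetic coupled trial.

    delay_ms is the corticomuscular transmission delay; with
    direction="efferent" the cortex leads the muscle by delay_ms (the EMG copy
    of the drive is delayed), with "afferent" the muscle leads, and with
    "none" the EEG and EMG drives are independent.  snr_db is the power ratio
    of the drive to the additive channel noise; -inf yields pure-noise
    channels.  coupling_strength scales both the additive drive copy and the
    carrier modulation depth and is the knob cohort effects multiply.
    """

    duration_s: float = 30.0
    fs_eeg: float = 500.0
    fs_emg: float = 2000.0
    coupling_center_hz: float = 10.0
    coupling_bandwidth_hz: float = 4.0
    delay_ms: float = 24.0
    direction: str = "efferent"
    snr_db: float = 10.0
    line_hz: float = 50.0
    ecg_bpm: float = 60.0
    ecg_amplitude: float = 3.0
    coupling_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not self.fs_emg >= self.fs_eeg:
            raise ValueError("fs_emg must be >= fs_eeg")
        nyq_need = 2.0 * (self.coupling_center_hz + self.coupling_bandwidth_hz)
        if self.fs_eeg < nyq_need:
            raise ValueError(
                f"fs_eeg={self.fs_eeg} below twice the coupling band edge ({nyq_need} Hz)"
            )
        if self.delay_ms < 0:
            raise ValueError("delay_ms must be >= 0")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.line_hz < 0:
            raise ValueError("line_hz must be >= 0")
        if self.ecg_bpm < 0:
            raise ValueError("ecg_bpm must be >= 0")
        if self.ecg_amplitude < 0:
            raise ValueError("ecg_amplitude must be >= 0")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    """Two-group cohort layout with per-cell coupling-gain effects.

    band_effects maps (group, task, band, direction) -> gain multiplier on
    coupling_strength for that band's component; unspecified cells default to
    gain 1.  Every trial contains one component per entry of ``bands``.
    """

    n_per_group: int = 10
    groups: tuple[str, str] = ("amputee", "control")
    tasks: tuple[str, ...] = ("EO", "EC", "DT")
    trials_per_task: int = 7
    bands: tuple[str, ...] = ("alpha", "beta")
    band_effects: dict = field(default_factory=dict)
    base_spec: CouplingSpec = field(default_factory=CouplingSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if len(self.groups) != 2:
            raise ValueError("exactly two groups are required")
        if self.trials_per_task < 1:
            raise ValueError("trials_per_task must be >= 1")
        for band in self.bands:
            if band not in BAND_COMPONENTS:
                raise ValueError(f"unknown band {band!r}")
        for key, gain in self.band_effects.items():
            group, task, band, direction = key
            if group not in self.groups:
                raise ValueError(f"band_effects: unknown group {group!r}")
            if task not in self.tasks:
                raise ValueError(f"band_effects: unknown task {task!r}")
            if band not in self.bands:
                raise ValueError(f"band_effects: unknown band {band!r}")
            if direction not in DIRECTIONS:
                raise ValueError(f"band_effects: unknown direction {direction!r}")
            if gain <= 0:
                raise ValueError("band_effects gains must be > 0")


def _bandpass_noise(rng, n, fs, center, bw):
    """Unit-variance Gaussian noise band-limited to center +/- bw/2."""
    lo = max(center - bw / 2.0, 0.1)
    hi = min(center + bw / 2.0, 0.49 * fs)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _carrier_noise(rng, n, fs):
    """Broadband EMG carrier: white noise high-passed at 7 Hz, unit variance.

    Surface EMG carries little power below ~10 Hz; keeping the carrier out of
    the 2-6 Hz range also leaves the wavelet-intensity trace there to the ECG,
    as in real trunk recordings.
    """
    sos = signal.butter(4, 7.0, btype="highpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _qrs_template(fs: float) -> np.ndarray:
    """Synthetic QRS-like pulse: Q and S dips around a dominant R peak."""
    t = np.arange(-0.12, 0.12, 1.0 / fs)
    g = lambda mu, sig: np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return -0.15 * g(-0.040, 0.010) + 1.0 * g(0.0, 0.012) - 0.30 * g(0.040, 0.010)


def _ecg_train(rng, n, fs, bpm, amplitude):
    """Periodic QRS train with +/-10 % beat amplitude jitter; returns the
    trace and the R-peak sample times (s)."""
    ecg = np.zeros(n)
    beats = []
    template = _qrs_template(fs)
    half = len(template) // 2
    period = 60.0 / bpm
    t_beat = 0.35
    while t_beat < n / fs:
        i = int(round(t_beat * fs))
        amp = amplitude * (1.0 + rng.uniform(-0.1, 0.1))
        lo, hi = i - half, i - half + len(template)
        tlo, thi = max(0, -lo), len(template) - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        ecg[lo:hi] += amp * template[tlo:thi]
        beats.append(i / fs)
        t_beat += period
    return ecg, np.array(beats)


def _component_drives(rng, spec, components, n_hi, margin):
    """Per-component (eeg_drive, emg_drive) pairs at the EMG rate.

    Positive delay with direction 'efferent' delays the EMG copy; 'afferent'
    delays the EEG copy; 'none' draws independent drives for the two sides.
    """
    out = []
    for comp in components:
        d = int(round(comp["delay_ms"] / 1000.0 * spec.fs_emg))
        full = _bandpass_noise(
            rng, n_hi + 2 * margin, spec.fs_emg, comp["center_hz"], comp["bandwidth_hz"]
        )
        if comp["direction"] == "efferent":
            eeg_d = full[margin : margin + n_hi]
            emg_d = full[margin - d : margin - d + n_hi]
        elif comp["direction"] == "afferent":
            eeg_d = full[margin - d : margin - d + n_hi]
            emg_d = full[margin : margin + n_hi]
        else:
            eeg_d = full[margin : margin + n_hi]
            emg_d = _bandpass_noise(
                rng, n_hi, spec.fs_emg, comp["center_hz"], comp["bandwidth_hz"]
            )
        out.append((eeg_d, emg_d, comp))
    return out


def _generate_trial(
    spec: CouplingSpec,
    components: list[dict],
    eeg_labels=None,
    emg_labels=None,
    include_internals: bool = True,
    meta: dict | None = None,
) -> Trial:
    """Shared generator behind make_coupled_trial and make_cohort."""
    eeg_labels = list(eeg_labels or EEG_LABELS)
    emg_labels = list(emg_labels or EMG_TRUNK_LABELS)
    rng = np.random.default_rng(spec.seed)
    n_hi = int(round(spec.duration_s * spec.fs_emg))
    n_lo = int(round(spec.duration_s * spec.fs_eeg))
    step = int(round(spec.fs_emg / spec.fs_eeg))
    margin = int(round(0.2 * spec.fs_emg))

    pure_noise = np.isneginf(spec.snr_db)
    drives = _component_drives(rng, spec, components, n_hi, margin)

    eeg_sum_hi = np.zeros(n_hi)
    emg_sum_hi = np.zeros(n_hi)
    for eeg_d, emg_d, comp in drives:
        eeg_sum_hi = eeg_sum_hi + comp["strength"] * eeg_d
        emg_sum_hi = emg_sum_hi + comp["strength"] * emg_d

    drive_scale = 10.0  # microvolt scale of the cortical drive in EEG
    noise_sd = drive_scale * 10 ** (-spec.snr_db / 20.0) if not pure_noise else drive_scale

    # --- EEG block at fs_eeg ---
    eeg = np.empty((len(eeg_labels), n_lo))
    gains = np.resize(EEG_DRIVE_GAINS, len(eeg_labels))
    eeg_drive_lo = eeg_sum_hi[::step][:n_lo]
    for c in range(len(eeg_labels)):
        ch = rng.standard_normal(n_lo) * noise_sd
        if not pure_noise:
            ch = ch + gains[c] * drive_scale * eeg_drive_lo
        eeg[c] = ch

    # --- EMG block at fs_emg ---
    carrier_sd = 50.0  # microvolts
    add_gain = 0.30  # additive drive copy, per unit coupling_strength
    mod_depth = 0.25  # carrier amplitude-modulation depth per unit strength
    emg = np.empty((len(emg_labels), n_hi))
    beat_times = np.array([])
    env = np.zeros(n_hi)
    if not pure_noise and drives:
        env = emg_sum_hi / max(np.abs(emg_sum_hi).max(), 1e-12)
    for c in range(len(emg_labels)):
        carrier = _carrier_noise(rng, n_hi, spec.fs_emg)
        mod = np.clip(1.0 + mod_depth * env, 0.0, None)
        ch = carrier_sd * carrier * mod
        if not pure_noise:
            ch = ch + carrier_sd * add_gain * emg_sum_hi
        if pure_noise:
            ch = ch + rng.standard_normal(n_hi) * carrier_sd
        else:
            ch = ch + rng.standard_normal(n_hi) * carrier_sd * 10 ** (-spec.snr_db / 20.0)
        if spec.line_hz > 0:
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(n_hi) / spec.fs_emg
            ch = ch + 0.5 * carrier_sd * np.sin(2 * np.pi * spec.line_hz * t + phase)
        if spec.ecg_bpm > 0 and spec.ecg_amplitude > 0:
            ecg, beat_times = _ecg_train(
                rng, n_hi, spec.fs_emg, spec.ecg_bpm, spec.ecg_amplitude * carrier_sd
            )
            ch = ch + ecg
        emg[c] = ch

    meta = dict(meta or {})
    truth: dict = {
        "spec": spec,
        "components": [dict(c) for c in components],
        "ecg_beat_times_s": beat_times,
    }
    if include_internals:
        truth["eeg_drive"] = eeg_sum_hi
        truth["emg_drive"] = emg_sum_hi
    eeg_rec = Recording(eeg, spec.fs_eeg, eeg_labels, [EEG] * len(eeg_labels), dict(meta))
    emg_rec = Recording(emg, spec.fs_emg, emg_labels, [EMG] * len(emg_labels), dict(meta))
    return Trial(eeg=eeg_rec, emg=emg_rec, truth=truth)


def make_coupled_trial(spec: CouplingSpec, include_internals: bool = True) -> Trial:
    """Generate one trial with a single coupling component per ``spec``.

    Deterministic given ``spec.seed``.
    """
    component = {
        "band": None,
        "center_hz": spec.coupling_center_hz,
        "bandwidth_hz": spec.coupling_bandwidth_hz,
        "delay_ms": spec.delay_ms,
        "direction": spec.direction,
        "strength": spec.coupling_strength,
    }
    return _generate_trial(spec, [component], include_internals=include_internals)


def make_cohort(
    design: CohortDesign,
    emg_labels=None,
    include_internals: bool = False,
) -> tuple[list[Trial], pd.DataFrame]:
    """Generate a full two-group cohort plus its tidy design table.

    Each participant draws an independent random stream from the master seed;
    each trial contains one coupling component per band in ``design.bands``
    with coupling strength base * band_effects gain for that participant's
    (group, task, band, direction) cell.
    """
    trials: list[Trial] = []
    rows = []
    ss = np.random.SeedSequence(design.seed)
    n_participants = 2 * design.n_per_group
    participant_seeds = ss.spawn(n_participants)
    idx = 0
    for gi, group in enumerate(design.groups):
        for p in range(design.n_per_group):
            participant = f"{group[:1].upper()}{p + 1:02d}"
            p_ss = participant_seeds[idx]
            idx += 1
            trial_seeds = p_ss.generate_state(
                len(design.tasks) * design.trials_per_task
            ) % (2**31)
            k = 0
            for task in design.tasks:
                for trial_no in range(1, design.trials_per_task + 1):
                    components = []
                    for band in design.bands:
                        center, bw = BAND_COMPONENTS[band]
                        gain = design.band_effects.get(
                            (group, task, band, design.base_spec.direction), 1.0
                        )
                        components.append(
                            {
                                "band": band,
                                "center_hz": center,
                                "bandwidth_hz": bw,
                                "delay_ms": design.base_spec.delay_ms,
                                "direction": design.base_spec.direction,
                                "strength": design.base_spec.coupling_strength * gain,
                            }
                        )
                    spec = replace(design.base_spec, seed=int(trial_seeds[k]))
                    meta = {
                        "participant": participant,
                        "group": group,
                        "task": task,
                        "trial": trial_no,
                    }
                    trials.append(
                        _generate_trial(
                            spec,
                            components,
                            emg_labels=emg_labels,
                            include_internals=include_internals,
                            meta=meta,
                        )
                    )
                    rows.append(meta)
                    k += 1
    table = pd.DataFrame(rows)
    return trials, table
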