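# cmcpipe

Directional corticomuscular coherence (CMC) analysis of EEG/EMG recordings
during quiet upright standing — for motor-control and posture researchers
who want the full chain from raw multichannel trials to group-level
statistics in one tested, scriptable package.

CMC quantifies the frequency-resolved synchrony between cortical activity
(EEG over the motor cortex) and muscle activity (surface EMG of trunk and
leg muscles). `cmcpipe` implements:

- **Cauchy-wavelet coherence.** Wavelets defined in Fourier space,
  `F_ψ(f; cf) = (f/cf)^mode · e^{(1 − f/cf)·mode}` with `mode = cf·scale`,
  on the non-linear frequency grid `cf_j = (1/scale)·(j+q)^r`
  (scale 12, q 1.45, r 1.959, j = 1…30 → 30 center frequencies,
  ≈ 0.48–71.6 Hz). Coherence is the modulus of the windowed coherency
  `|⟨W_x W̄_y⟩| / (⟨|W_x|²⟩ ⟨|W_y|²⟩)^{1/2}`, averaged over eight 1.984-s
  windows (0.504-Hz resolution).
- **AAFT surrogate thresholds.** Amplitude-adjusted Fourier-transform
  surrogates of both channels destroy cross-signal coupling while exactly
  preserving each signal's value distribution; the median (or any
  percentile) of 100 surrogate band-mean coherences is the per-trial
  significance threshold.
- **Transmission-delay and direction estimation.** Coherence at the
  per-participant band peak frequency is re-computed for signal lags up to
  ±128 ms in 4-ms steps on a fixed 15.872-s span; the coherence-maximising
  lag gives the delay, its sign the direction (positive = cortex leads
  muscle = efferent).
- **EEG power spectra** from zero-padded 2-s boxcar windows.
- **PERMANOVA on six-dimensional CMC profiles** (3 EEG × 2 EMG electrodes)
  with altGower distances, sequential sums of squares over band, task,
  group and their interactions, repeated-measures permutation (participants
  as exchangeable units for between-participant terms), task-wise group
  contrasts, and NMDS embeddings.
- **A synthetic cohort generator** producing coupled EEG/EMG trials with
  known coupling band, direction, delay, SNR, 50-Hz line noise and ECG
  contamination, plus two-group cohorts with injectable group × task × band
  effects — so every stage is testable without any recordings.

## Worked example

Generate one synthetic trial with a known 24-ms efferent delay and recover
it:

```python
import cmcpipe as cp
from cmcpipe.coherence import DEFAULT_BANDS, band_peak_frequency
from cmcpipe.directionality import (
    estimate_directional_cmc, lagged_coherence, smooth_lag_profile,
)
from cmcpipe.preprocess import preprocess_trial, segment_trial

spec = cp.CouplingSpec(coupling_center_hz=21.0, coupling_bandwidth_hz=10.0,
                       delay_ms=24.0, direction="efferent", snr_db=10.0,
                       coupling_strength=2.0, seed=9)
trial = cp.make_coupled_trial(spec)
merged = preprocess_trial(trial)              # notch, band-pass, trim, ECG
peak_seg, analysis = segment_trial(merged)    # 4 s + 16 s at 250 Hz

bank, win = cp.WaveletBank(), cp.WindowingConfig()
win4 = win.for_segment(peak_seg.n_samples)
spec4 = cp.wavelet_coherence(peak_seg.channel("C3")[:win4.n_samples],
                             peak_seg.channel("ExO")[:win4.n_samples],
                             bank, win4)
cf = band_peak_frequency(spec4, DEFAULT_BANDS["beta"])
prof = lagged_coherence(analysis.channel("C3"), analysis.channel("ExO"),
                        cf, bank, win)
est = estimate_directional_cmc(smooth_lag_profile(prof))
print(f"peak cf {cf:.2f} Hz | efferent delay {est.efferent_delay_ms:.0f} ms "
      f"(CMC {est.efferent_cmc:.2f}) | afferent CMC {est.afferent_cmc:.2f}")
```

Output:

```
peak cf 25.17 Hz | efferent delay 24 ms (CMC 0.93) | afferent CMC 0.92
```

The beta-band peak falls inside the injected 16–26 Hz drive band, the
efferent delay is recovered exactly, and the efferent-side coherence
exceeds the afferent side, classifying the direction correctly.

Full studies run from one YAML config, either via the API
(`cmcpipe.run_study(load_config("study.yaml"))`) or the CLI:

```bash
cmcpipe simulate --config study.yaml --out cohort/   # write EDF/TSV trials
cmcpipe run-all  --config study.yaml                 # full pipeline + stats
```

`run-all` writes tidy CSVs (peak frequencies, significance mask with
retention fractions, directional CMC per trial/pair/band, PSD summaries,
PERMANOVA and pairwise-contrast tables, NMDS coordinates) plus a manifest
with the config hash and library versions; re-running a config reproduces
every file bit-for-bit.

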