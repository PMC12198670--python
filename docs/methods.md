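# Methods

`cmcpipe` analyses directional corticomuscular coherence (CMC) between EEG
and surface EMG recorded during quiet upright standing, and ships a synthetic
coupled-signal generator so that every stage can be validated against known
ground truth. This note documents the models, the estimators, the numerical
choices, and what the synthetic benchmarks do and do not establish.

## Signal model and pre-processing

Trials are 30-s standing recordings: EEG at 500 Hz (motor-strip electrodes,
10–20 names), bipolar EMG at 2000 Hz (SENIAM-style names for trunk and leg
muscles). The chain, in order: 50-Hz notch (2nd-order Butterworth band-stop,
49–51 Hz), 1-Hz high-pass and 100-Hz low-pass (4th-order Butterworth), 5-s
edge trimming, ECG template subtraction from EMG, common-average
re-referencing (CAR) of the EEG block only, decimation to 250 Hz, and
segmentation into a 4-s peak-search segment and a 16-s analysis segment.

All filters are applied forward–backward (zero phase). This is a deliberate
choice: the delay estimator downstream resolves lags of one sample (4 ms),
and any filter group delay — which differs between the EEG and EMG chains
because the native rates differ — would bias it directly. The notch
bandwidth (2 Hz) is a choice as well; it is narrow enough to leave the low
gamma band intact. Bipolar EMG keeps its own reference and is never included
in the CAR.

ECG removal follows a wavelet-intensity scheme: (i) the summed squared
modulus of Cauchy-wavelet coefficients at low center frequencies (4–7 Hz)
localises QRS complexes — in this range the QRS impulse dominates, surface
EMG carries little power, and alpha-band physiological rhythms (≥ 8 Hz) do
not leak in; (ii) candidate beats are intensity peaks above twice the median
intensity with a ≥ 300-ms refractory period. A multiplicative threshold is
used rather than a median-absolute-deviation rule because the high-Q Cauchy
wavelets ring between beats, which inflates the MAD of an ECG-contaminated
trace. (iii) Candidates are accepted only if they form a plausible rhythm
(≥ 5 beats, inter-beat-interval coefficient of variation ≤ 0.25); this gate
is what makes the stage a strict no-op on ECG-free channels. (iv) An
ensemble-average template (±150 ms, Savitzky–Golay smoothed) is scaled per
beat by least squares and subtracted. Detection runs on an anti-aliased
100-Hz copy and beat times are refined at native rate.

## Wavelet bank and transform

The complex Cauchy family is defined in Fourier space:

    F_psi(f; cf) = (f/cf)^mode * exp((1 - f/cf) * mode),   mode = cf * scale
    cf_j = (1/scale) * (j + q)^r

with scale 12, q 1.45, r 1.959 and j = 1…30, giving 30 center frequencies
from ≈ 0.48 Hz to ≈ 71.6 Hz with approximately constant relative bandwidth
(the gain's spectral standard deviation is cf/√mode). The index range is
configurable; j = 1…29 tops out near 67 Hz. Gains are evaluated in log space
(the exponent mode·(ln(f/cf)+1−f/cf) is ≤ 0 for all f > 0), which avoids
overflow at high cf where mode exceeds 800.

The transform is evaluated per analysis window: symmetric zero-padding to
the next power of two ≥ twice the window length, FFT, multiplication with
the one-sided gain (negative frequencies zeroed, so coefficients are
analytic and carry phase), inverse FFT, and cropping back to the window
span. Batched inputs are transformed in one call; throughput-critical
pipeline paths may run in single precision (the resulting coherence values
agree with double precision to ~1e-6, far below any decision threshold in
the pipeline).

## Coherence estimator

The analysis segment is cut into 8 non-overlapping windows of 496 samples
(1.984 s at 250 Hz). 8 × 496 = 3968 samples = 15.872 s, and 1/1.984 s =
0.504 Hz is the spectral resolution. Within each window the cross-spectrum
Wx·conj(Wy) and both auto-spectra are averaged over the unpadded span, the
coherency is the normalised ratio, the window's coherence is its modulus,
and the reported value per center frequency is the mean of the per-window
coherences. A per-sample coherency ratio would have modulus identically 1;
time-averaging the spectra before normalising is the only reading under
which coherence < 1 is possible.

A consequence of averaging *moduli* across windows: the estimator's noise
bias is governed by the amount of within-window time averaging (longer
windows → lower bias), while increasing the number of windows reduces the
variance, not the bias. On independent noise the null level is ≈ 0.4 per cf
for the default windowing. All significance decisions are therefore made
against surrogate-derived thresholds, never against zero.

Frequency bands: alpha 8–12 Hz (3 bank cfs), beta 13–30 Hz (7 cfs), low
gamma 30–45 Hz, high gamma 45–63 Hz. Per-band peak frequencies are found on
the 4-s segment (argmax within the band; ties break to the lowest cf), one
peak per participant and band: per-trial argmaxes are pooled over that
participant's trials and electrode pairs, averaged, and snapped to the
nearest bank cf. Pooling over pairs (rather than keeping one peak per pair)
matches the design of one representative frequency per band per participant
and makes the lag scan reuse wavelet coefficients across pairs.

## Surrogate significance threshold

Amplitude-adjusted Fourier-transform (AAFT) surrogates: Gaussian noise is
rank-reordered to the signal's ranks, phase-randomised with a
Hermitian-symmetric phase draw, and the signal's sorted values are remapped
onto the result's ranks. The surrogate's value multiset equals the
original's exactly; its power spectrum is preserved approximately. Both
channels of a pair are surrogated independently, destroying all
cross-signal dependence. The threshold for a (trial, band, pair) record is
the median (configurable percentile) of the band-mean coherences of 100
surrogate pairs. "Median surrogate" is implemented as the median of the
surrogate coherence *values*, not a pointwise median signal — a median
signal would break value conservation and has no coherence interpretation.

Calibration on independent-noise pairs: the true band mean exceeds the
median-statistic threshold in ≈ 50 % of pairs and the 95th-percentile
threshold in ≈ 5–6 %. The slight excess over 5 % is a known property of
per-pair surrogate thresholds (the threshold is estimated from an ensemble
conditioned on the pair's own amplitude spectra, with 100 surrogates).

## Directional CMC and transmission delay

The EEG and EMG analysis segments are shifted against each other in
integer-sample steps (4 ms) to ±128 ms (±32 samples). Every lag is
evaluated on the same span length — the 3968 samples that remain at the
maximal shift — so values are comparable across lags. Positive lag pairs
EEG samples with later EMG samples (cortex leads muscle: efferent side);
negative lags form the afferent side; lag 0 belongs to neither. The lag
profile at the participant's band peak cf is smoothed with a 16-ms centred
moving average (5 points; the nearest odd count), and each side's maximum
gives that direction's CMC and delay. All-equal profiles tie-break to the
smallest |lag| per side.

The temporal resolution of this scan is intrinsically limited by the
wavelet's bandwidth: at cf = 21 Hz the analytic envelope decorrelates over
≈ 100 ms, so the profile is a shallow dome around the true delay. The
single-sample recovery documented by the acceptance suite therefore uses a
strong-coupling benchmark condition (beta-band drive 16–26 Hz, coupling
strength 2, SNR 10 dB) where the estimator noise is small relative to the
dome's curvature; at weaker coupling the delay error grows while direction
classification degrades much more slowly.

## Group statistics

CMC values of the six electrode pairs (3 EEG × 2 EMG of one muscle set) are
averaged over the retained trials of each participant × task × band ×
direction cell and stacked into six-dimensional profiles. Dissimilarity is
altGower: the mean absolute difference across the six dimensions, without
range normalisation (coherences are already in [0, 1] and strictly
positive, so double-zero handling is moot).

PERMANOVA uses the distance-based sum-of-squares partitioning (Gower-centred
−D²/2, sequential/type-I sums of squares via accumulated hat matrices) with
the term order band, task, group, band:task, band:group, task:group,
band:task:group. p-values are permutation-based with
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), 5000 permutations by default.

Repeated measures are honoured through the permutation scheme: observations
of one participant stay together. For terms whose factors are constant
within participants (group), entire participant blocks are exchanged — the
exchangeable units are participants. For terms involving within-participant
factors (task, band, interactions), observations are permuted within each
participant. Permuting within participants cannot alter a between-
participant factor at all, so block exchange is the only scheme under which
the group test has power; this is the standard exchangeability argument for
repeated-measures PERMANOVA and calibrates the group-effect type-I error to
0.05 on null cohorts with participant random effects. Block exchange
requires equal-sized participant strata; participants with missing cells
(no retained trial for some pair) are dropped with a log message rather
than silently unbalancing the test.

Task-wise group contrasts subset the distance matrix per task and re-test
group; no multiplicity adjustment is applied. NMDS embeddings (Kruskal
stress-1, isotonic regression, multi-start SMACOF via scikit-learn) are
computed for visualisation; nonmetric stress only constrains distance
ranks, so configurations are recovered up to rotation, reflection, scale
and a small monotone warp that shrinks as the number of points grows.

## Synthetic data: what it emulates, and what it does not

Each trial contains per-band cortical drives: unit-variance Gaussian noise
band-passed to the coupling band (alpha component at 10 ± 2 Hz, beta at
21 ± 4 Hz for cohorts). The EEG channels receive the drive with
channel-specific gains (1.0, 0.6, 0.5) — chosen so that no gain equals the
gain mean, hence CAR leaves a non-zero drive residual in every channel —
plus white noise at the requested SNR. The EMG model carries the coupling
twice: the delayed drive amplitude-modulates a broadband carrier
(modulation depth 0.25 per unit coupling strength), and a scaled copy of
the delayed band-limited drive is added directly (gain 0.3 per unit
strength relative to the 50-µV carrier). The additive path is what
guarantees narrow-band linear EEG–EMG coherence at a controlled level; pure
envelope modulation alone is largely invisible to a linear coherence
estimator. The carrier is high-passed at 7 Hz: surface EMG carries little
power below ~10 Hz, and this keeps the 4–7 Hz wavelet-intensity band free
for ECG detection. EMG channels of one trial share the cortical drive but
draw independent carriers (a common central drive to distinct muscles).
Nuisance components: a 50-Hz line sinusoid and a QRS-like pulse train
(tri-Gaussian template, ±10 % beat-amplitude jitter, default 60 bpm,
R amplitude 3 × carrier SD).

Cohorts mirror the study layout — two groups × 10 participants × 3 standing
tasks (eyes open, eyes closed, dual task) × 7 trials by default — with
per-(group, task, band, direction) gain multipliers on coupling strength to
inject known effects. Every participant draws an independent seeded stream;
identical seeds reproduce cohorts bit-for-bit.

The generator does *not* model volume conduction or realistic EEG
topography, postural sway biomechanics, non-stationary muscle activation,
1/f background spectra, or ocular artifacts. Passing benchmarks on this
data shows that the estimators recover the coupling structure they were
built for under controlled noise; it does not certify performance on real
recordings, where pathway mixing and artifact structure are richer.

## Benchmark problem sizes

The validation suite uses scaled study conditions chosen for a single CPU:
delay recovery uses 50 seeds per delay in {8, 16, 24, 32, 48} ms; direction
classification 52 one-directional trials; surrogate calibration 200
independent pairs × 100 surrogates; PERMANOVA type-I calibration 400 null
profile cohorts × 499 permutations (the permutation count scaled down from
the 5000 used for real analyses); end-to-end detection 50 cohorts of 4 + 4
participants × 3 tasks × 2 trials with the trunk muscle set, 12 surrogates
per channel and 199 permutations. Defaults in the package remain at study
scale (7 trials, 100 surrogates, 5000 permutations).

## Known limitations

- The lag-scan delay resolution degrades for narrow coupling bands and at
  low coherence; delays printed for weakly coupled bands should be read as
  order-of-magnitude.
- AAFT percentile thresholds are mildly anticonservative (see above).
- Sequential sums of squares make term order meaningful in unbalanced
  designs; the shipped order matches the fixed analysis layout.
- The EDF writer emits plain EDF with 1-s records and requires integer
  sampling rates and whole-second durations.
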