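# Methods

This note documents the models and procedures implemented in `painfeat`,
the parameter choices that matter, and what the synthetic experiments do
and do not demonstrate.

## Experimental protocol and its simulation

The pipeline targets a calibrated phasic heat-pain experiment: per subject,
four individually calibrated temperature levels (T1 = pain threshold,
T4 = pain tolerance, T2/T3 interpolated) are each applied 20 times in
randomized order; plateaus last 4 s, pauses are uniform on 8–12 s and the
non-pain baseline is 32 °C. Five channels are recorded: zygomaticus,
corrugator and trapezius EMG, skin conductance level, ECG. The standard
dataset size is 85 subjects × (80 stimulus + 20 baseline) windows = 8500
classification units.

The simulator reproduces the *statistical structure these features
measure*, not biophysical morphology:

* **EMG** — zero-mean Gaussian noise band-limited to 20–250 Hz with
  baseline scale σ₀ = 10 µV. During a stimulus the scale is multiplied by
  a level-dependent burst gain (defaults 1.10 / 1.30 / 1.70 / 2.50 for the
  facial muscles) with 0.5 s raised-cosine on/off ramps; the trapezius
  responds at 60 % of the facial gain excess, reflecting its weaker
  stimulus-locking.
* **SCL** — a per-subject tonic level (log-normal around 5 µS) plus a
  bounded slow drift (random-phase sinusoids below 0.03 Hz, 0.1 µS RMS)
  and, per stimulus, a phasic response with onset latency uniform on
  1–3 s, exponential rise (0.8 s) and decay (3 s), and level-dependent
  amplitude (0.05 / 0.12 / 0.25 / 0.50 µS).
* **ECG** — a narrow QRS-like impulse train. RR intervals are Gaussian
  (mean 800 ms, SDNN 40 ms) with an AR(1) successive-difference structure
  (φ = 0.8); during a stimulus the mean RR shortens by 5 / 12 / 30 / 60 ms.

Three nuisance mechanisms make the classification problem realistically
hard rather than trivially separable:

* **non-response trials** — a stimulus elicits a measurable EMG/SCL
  response only with probability 0.6 / 0.75 / 0.9 / 1.0 by level; near
  threshold, a large fraction of trials is physiologically silent;
* **trial-to-trial variability** — log-normal jitter of burst-gain excess
  (σ = 0.25) and phasic amplitude (σ = 0.5);
* **spontaneous activity** — non-specific skin-conductance responses
  (3/min, ~0.04 µS) and short EMG bursts (2/min, gain 1.6), independent of
  the stimuli, so baseline windows are not perfectly quiet.

Per-subject baseline scales are log-normally randomized (σ = 0.25) so the
per-person z-normalization downstream is consequential. A single root seed
fans out into per-subject `SeedSequence` streams; identical configuration
implies bit-identical data, and any subject is reproducible in isolation.

**What this does not emulate:** motor-unit EMG structure, ECG waveform
morphology and artifacts, electrode drift/motion artifacts, habituation
and sensitization trends over the session, thermode temperature dynamics,
and between-channel physiological coupling beyond the shared stimulus.
Passing tests on this generator demonstrate that the pipeline recovers
planted class structure of the kind these features measure — they are not
evidence about recognition rates on real recordings.

## Preprocessing

* Butterworth band-passes are zero-phase (`sosfiltfilt`, order 4): EMG
  20–250 Hz, ECG 0.1–250 Hz. When a band edge reaches Nyquist (e.g. at
  512 Hz sampling) it is clipped to 0.99 × Nyquist with a warning.
* **EMD denoising** (EMG only): standard sifting with cubic-spline
  envelopes through the extrema (mirrored ends), Cauchy stop criterion
  SD < 0.2, at most 6 siftings per mode and 5 modes (noise occupies the
  leading modes; the reconstruction subtracts only the discarded leading
  modes from the original signal, so deeper modes never need sifting).
  The rejection rule
  works on mode energies: broadband noise spreads over the leading modes
  with monotonically decaying energy, while a narrowband signal breaks the
  decay. Leading modes up to the first energy increase are discarded; if
  E₂/E₁ < 0.1 the first mode is itself signal-dominated and nothing is
  discarded; a fully monotone cascade loses only the first mode. The
  operator is applied per analysis window (the classification unit), which
  keeps the cost linear in the number of windows. Degenerate inputs
  (constants, too few extrema) pass through unchanged.
* **Windows**: the pain window spans 5.5 s from stimulus onset (4 s
  plateau + 1.5 s after — the response outlasts the plateau); non-pain
  windows start 2 s after a plateau ends, mid-pause, 20 per subject to
  balance the classes. Windows that would cross the recording end are
  dropped with a warning.
* **Burst detection**: smoothed (50 ms moving average) Hilbert envelope;
  a burst is ≥ 0.1 s above median + 3.5 × MAD-σ of the envelope. The
  median/MAD baseline is robust against the bursts themselves. On the
  simulator this yields no false bursts in ≥ 95 % of stationary-noise
  trials while localizing planted bursts to ±0.25 s.
* **RR detection**: squared first difference, 20 ms smoothing, peak
  picking with a 250 ms refractory period and a 0.3 × max height floor,
  with beat refinement to the local ECG extremum. Fewer than two beats
  yields an empty series; windows with < 3 RR intervals carry sentinels.
* SCL is not band-pass filtered; it is linearly detrended per window
  before the frequency-domain operators.

## The feature space

Each of the four waveform channels contributes 39 features (10 amplitude,
6 frequency, 6 stationarity, 5 entropy, 2 linearity, 4 variability,
6 similarity); the ECG contributes meanRR, RMSSD and the OLS slope of RR
against beat index. Total 4 × 39 + 3 = 159, partitioned
40/24/24/20/8/19/24 across the seven groups.

Numerical conventions and choices:

* All logarithms are natural (entropies and mutual information in nats).
* Template entropies use m = 2, r = 0.2 × std, fuzzy exponent 2 — standard
  literature defaults. ApEn includes self-matches (Pincus convention);
  SampEn excludes them (Richman–Moorman); FuzzyEn removes each template's
  own mean and weights similarity by exp(−(d/r)²). They are evaluated on a
  coarse-grained copy of the window (non-overlapping block means, ≤ 256
  samples): template matching is O(N²), and at 2816 samples the extra cost
  buys no additional discriminative information for these noise-like
  signals. Constant segments return 0; underdetermined counts return NaN
  sentinels.
* Spectral estimates (Welch / spectrogram / coherence) use 256-sample
  Hann segments with 50 % overlap. The stationarity degree is
  DS(ω) = mean over frames of (1 − H(ω,t)/h(ω))² with h the time-averaged
  spectrogram; its four aggregates are the median, the frequency-weighted
  mean, the area and the power-weighted area. The dispersion features
  ("me"/"sd") use 0.5 s subsegments.
* The central frequency is the mean of the −3 dB band edges (fh + fl)/2;
  a config switch (`cf_printed_variant`) provides the half-difference
  (fh − fl)/2 variant instead.
* Coherence is the magnitude-squared coherence |Sxy|²/(Sxx·Syy)
  (non-squared coherency is complex-valued and cannot be aggregated).
  With a uniform frequency grid the power-weighted area equals the
  power-weighted mean; both columns are emitted and the correlation
  pruning stage removes the redundancy. Windows too short for 4 averaging
  segments yield sentinels (a single-segment coherence is identically 1).
* Lag-dependence values regress x(t) on x(t−k) for k = 1…10, linearly
  (ldf) and quadratically (pldf, the nonlinear variant), and average
  √max(R², 0) over lags.
* Local extrema are strict sign changes of the first difference; plateaus
  contribute their first sample. `mavfdn`/`mavsdn` are the
  first/second-difference mean absolute values of the z-scored segment.

**Similarity reference.** Similarity features compare each window with the
subject's mean baseline signal. Every window — baseline or pain — uses a
leave-one-out mean over the 20 baseline windows. A baseline window
excludes itself: comparing a window against an average containing itself
injects a spurious ≈ 1/√20 positive self-correlation into every baseline
row, which the per-person z-transform then converts into an artifactual,
near-perfect class separator. A pain window excludes one rotating baseline
window, so both classes see references of identical construction (same
averaging count, same residual-noise level); with an asymmetric reference
(19-window mean for baseline rows, 20-window mean for pain rows) a weak
but systematic class signal survives even in zero-effect simulations.
With the symmetric construction, similarity features carry only genuine
stimulus-locked dissimilarity.

After extraction, every feature column is z-transformed within subject
(zero-variance columns become zeros and are dropped as static later).

## Selection and classification

Static pruning removes all-zero/constant columns and columns containing
sentinels. Correlation pruning scans columns in canonical order and drops
any later column correlated at |r| ≥ 0.95 with a retained earlier column
(the earlier column survives; Pearson r is invariant to the per-person
z-transform's affine rescaling only within subject, so pruning operates on
the pooled normalized matrix).

Forward selection wraps the classifier: each round scores every remaining
candidate by 3-fold stratified cross-validated accuracy of (current set +
candidate), adds the best (ties toward the lower column index) and stops
at the first round without strict improvement. To keep wrapper run-times
at desk scale the wrapper uses a fixed (C, γ) found by a coarse 3 × 3 grid
on all pruned candidates; the full 11 × 10 grid (C = 2⁻⁵…2¹⁵,
γ = 2⁻¹⁵…2³, steps of 2²) is then re-tuned on the selected set, and the
winning pair (ties toward smaller C, then smaller γ) is refit on all
training data. A cap of 22 selected features bounds the wrapper.

The 75/25 split is stratified by class label (this makes the 6375/2125
arithmetic exact at the standard size); a `group_by_subject` switch splits
by subject instead for subject-independent evaluation. Feature selection
and grid search see training data only. Multi-class problems use the
standard one-vs-one SVM decomposition; sensitivity and specificity for
k > 2 classes are one-vs-others from the k-class confusion matrix.

Cramér's V = √(χ²/(n·(min(r,c)−1))) uses the uncorrected Pearson χ² of the
confusion table after removing zero-margin rows/columns; interpretation
bands are < 0.1 negligible, 0.1–0.2 weak, 0.2–0.4 moderate, 0.4–0.6
relatively strong, 0.6–0.8 strong, ≥ 0.8 very strong.

## Problem sizes in the reproduction harness

The seeded harness (`scripts/acceptance.py`, `tests/test_acceptance.py`)
runs the end-to-end sweep on ten datasets of 10 subjects each, restricted
to the classes the two-class tasks need (B, T1, T4 — 600 windows per
dataset), and a five-dataset zero-effect null (B, T4 — 400 windows each).
The zero-effect Cramér's V is evaluated on the confusion matrix pooled
over the null runs: under independence the plug-in estimator is biased
upward by ≈ 1/√n, so per-run values at n = 100 would measure estimator
bias rather than association. Structural counts (159 features, 80 + 20
windows, 6375/2125 split) are computed at the standard sizes, which cost
nothing.

## Known limitations

* The simulator's class effects are stylized; absolute synthetic
  accuracies are not comparable to real-data recognition rates, only the
  qualitative structure (difficulty ordering, chance-level nulls, feature
  families selected) is meaningful.
* EMD denoising of an already broadband signal (EMG) is conservative by
  construction (at most the first mode is removed when energies decay
  monotonically); it mainly protects against superimposed narrowband
  interference, which the simulator does not generate.
* The stationarity-degree aggregates for a stationary process converge to
  the periodogram's relative variance (≈ 1 per frequency), not to zero;
  only contrasts between windows are informative, which is all the
  classifier uses.
* Window-level (rather than subject-level) splitting follows the standard
  protocol arithmetic; subject-grouped splitting is available but not the
  default, and synthetic accuracies under it are lower.
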