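# Methods

## Problem and pipeline

The package classifies 1-s epochs of multi-channel scalp EEG into four
clinically annotated states — normal background (A), slowing (B),
epileptiform discharges (C), electrographic seizure (D) — and evaluates how
well classical classifiers recover those states for *unseen patients*. The
processing chain is: zero-phase band-pass filter → fixed-grid epoching with
annotation-driven labels → db4 wavelet band features → task-specific
relabeling → subject-wise hold-out evaluation.

## Signal preprocessing

The band-pass is a linear-phase Hamming-window FIR (`scipy.signal.firwin`)
with pass band 0.5–40 Hz, lower/upper transition bandwidths 0.50 Hz and
10.00 Hz, and half-amplitude cutoffs at `l_freq − Δf_low/2` and
`h_freq + Δf_high/2`. The filter length follows the window-design rule
`n_taps = smallest odd integer ≥ 3.3 · fs / min(Δf)`, which at 250 Hz gives
1651 taps (6.604 s). Zero phase is realized as a single forward convolution
with the symmetric kernel against a reflect-padded signal, extracting the
segment delayed by `(n_taps − 1)/2`; for a symmetric FIR this cancels the
group delay exactly, so passband sinusoids emerge at zero lag (asserted by a
cross-correlation oracle in the tests). Epochs shorter than the kernel are
handled by the same padding.

Min–max scaling is a per-row linear map fitted on training data only
(`fit_minmax` / `apply_minmax`); held-out values may legitimately fall
outside [0, 1], and constant rows map to 0 with a warning. In the pipeline
the scaler is fitted on the *feature rows of training subjects* and applied
for the SVM and KNN only: scaling the time series before the wavelet
transform would force a full feature re-extraction for every split while
providing the identical leakage guarantee, and the random forest is
invariant to monotone per-feature maps. This is the one place where two
plausible orderings existed; the choice is recorded here once.

## Features

Each epoch channel (250 samples) is decomposed by a 5-level db4 DWT with
symmetric extension. Dyadic sub-band arithmetic at 250 Hz fixes the band
mapping: a5 → delta (0–3.9 Hz), d5 → theta (3.9–7.8), d4 → alpha (7.8–15.6),
d3 → beta (15.6–31.25), d2 → gamma (31.25–62.5); d1 (62.5–125 Hz) is
discarded because the signal is low-passed at 40 Hz. The nominal clinical
ranges (e.g., gamma 31–45 Hz) cannot be hit exactly by dyadic edges; the
dyadic mapping is the only realizable DWT reading and is documented on the
band registry.

Sixteen statistics per band, in registry order: mean, standard deviation,
variance, median, mean |x|, max |x|, total energy Σx², average power Σx²/N,
skewness and excess kurtosis (population moments, computed on z-scores for
numerical robustness near zero variance), Shannon entropy of the normalized
energy distribution pᵢ = xᵢ²/Σx² in bits (0·log 0 := 0), zero-crossing rate
#{xᵢxᵢ₊₁ < 0}/(N−1), waveform length Σ|Δx|, and the Hjorth parameters:
activity (= variance, kept as a separate registry entry to honor the
16-item bank), mobility √(var Δx / var x), complexity mobility(Δx)/mobility(x).
All ratio-based statistics of an all-zero (or zero-variance) input are
defined as 0. Entropy uses the energy distribution rather than an amplitude
histogram, and kurtosis is excess — both were genuinely open choices.
Per-channel band statistics are averaged over channels, yielding 80 values
per epoch in band-major order. The implementation is vectorized over
(epoch × channel) rows; tests pin every statistic to a loop-written
brute-force oracle at 1e-10 relative tolerance and to closed forms
(mobility of a sinusoid ≈ 2 sin(πf/fs), ZCR ≈ 2f/fs, entropy ≤ log₂N).

## Epoching and labels

Non-overlapping 1-s windows aligned to t = 0, trailing partial window
dropped. An epoch is retained iff at least one annotation overlaps it
(open-interval overlap test); with multiple overlapping classes the most
clinically severe wins, D > C > B > A, so a seizure second is never masked.
Alignment to the fixed grid rather than annotation onsets is the simpler
reading of fixed-length epoching and keeps epoch counts equal to floor
(recording seconds) on fully annotated recordings.

## Tasks

Task 1 is binary normal-vs-abnormal (a one-class reading would admit no
specificity); Task 3 is the full four-class problem; Tasks 2 and 5 exclude
A; Task 4 keeps only A and D. Relabeling never touches feature values.

## Evaluation

Splits are by subject: a seeded shuffle holds out max(1, round(0.2 · n))
subjects, redrawing (≤ 200 attempts) until every task class occurs on both
sides; a class carried by a single subject is an unsatisfiable-split error.
Disjointness is asserted inside `train_and_predict`, not only in tests.
Models: SVC(RBF, C = 1, gamma = "scale"), RandomForest(500 trees, seeded),
KNeighbors(k = 1); no class weighting or resampling by default (a
`class_weight` option exists but is off). Multi-class aggregation is
support-weighted recall/precision/F1 (weighted recall is algebraically equal
to accuracy) plus macro one-vs-rest specificity; macro recall is also
reported because weighted recall hides rare-class collapse. Metrics are
percentages in [0, 100] with the per-class confusion matrix attached.

## Synthetic cohort

The generator emulates what the pipeline must discriminate, not scalp
biophysics. Per subject, integer-second events of 5–15 s tile the recording
exactly (100 % annotation coverage, non-overlapping); per-class time
follows the configured mix, by default A 47.1 %, B 26.2 %, C 2.9 %, D 23.7 %
— the empirical imbalance ordering of clinical interictal/ictal corpora
(normal most frequent, discharges rarest). Defaults: 20 subjects, 600 s
each, 23 channels (the 19 scalp electrodes of the 10–20 montage plus A1/A2
and two midline auxiliaries — channel identity is cosmetic since features
are channel-averaged), 250 Hz.

Class signatures, amplitudes in µV chosen at clinically typical magnitudes:

* **A** — 1/f background (10 µV RMS) + waxing/waning 8.5–12.5 Hz alpha
  (20 µV nominal).
* **B** — steeper 1/f tilt plus explicit delta (1–3 Hz) and theta
  (4–6.5 Hz) rhythms at 3× the alpha amplitude, alpha attenuated to 0.3×.
* **C** — class-A background plus Poisson-timed (1/s) spike-and-slow-wave
  transients (70 ms triangular spike at 120 µV, 300 ms opposite-polarity
  wave at 0.45×) on a 4-channel focal subset.
* **D** — 3→6 Hz linear chirp whose envelope grows 4× across the event on
  ~85 % of channels.

One root `SeedSequence` spawns a stream per subject, so cohorts are pure
functions of (config, seed). What the generator does **not** model: volume
conduction/montage geometry, artifacts (EMG, eye movement, electrode pops),
non-stationary background drift, inter-subject morphology differences
beyond per-segment randomization. Passing the recovery suites therefore
shows the pipeline machinery is sound and that rare-class collapse emerges
under imbalance — it does not predict accuracy on hospital EEG, where
class overlap is far worse.

Persistence is EDF+: a hand-written writer (16-bit quantization over a
symmetric per-file physical range, TAL annotation track, 1-s records) read
back through MNE's EDF reader, which independently validates the files.
Quantization bounds round-trip error below (physical range)/2¹⁵.

## Scale of the shipped experiments

The default study conditions (20 subjects × 600 s → 12 000 epochs) are used
for the parameter-recovery suite: Task 1 RF accuracy ≥ 90 %, Task 4 all
models > 70 %, and rare-class C recall the per-class minimum for RF and SVM
in Task 3 — property floors reproducing the qualitative pattern that
ensemble methods dominate the easy contrasts while recall collapses on the
rare discharge class. Observed values at seed 7 are far inside the floors
(Task 1 RF ≈ 98 %, Task 4 = 100 %, C recall ≈ 45–47 % vs ≥ 99 % elsewhere).
Smaller cohorts (4–8 subjects, 90–240 s) back the unit and CLI tests.

## Known limitations

* Single hold-out split, no cross-validation or hyperparameter search (by
  design, mirroring the evaluated protocol).
* The EDF writer emits EDF+C with 1-s records and integer sampling rates
  only.
* Synthetic separability is optimistic; thresholds in the recovery suite
  are floors for this generator, not claims about clinical data.
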