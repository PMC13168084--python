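# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `speechmark`, in the order of the processing chain.

## Audio handling

Input is mono PCM WAV (16/24/32-bit), nominally 22,050 Hz, one read sentence
per file. All analysis operates on **peak-normalized** amplitude in [−1, 1]:
the pause detector's fixed amplitude threshold (0.04) is only meaningful on a
fixed amplitude scale, and peak normalization is the weakest assumption that
provides one (recordings are assumed gain-stable within a session but not
calibrated across sessions). RMS normalization was rejected because pause
proportion would then feed back into the normalization constant. Resampling
uses polyphase band-limited interpolation; times are in seconds, sample
indices 0-based, intervals half-open [onset, offset).

## Pause detection and temporal features

The amplitude envelope is the moving RMS of the signal over a 10 ms window.
Samples below the threshold are silence candidates; supra-threshold runs
shorter than the minimum speech duration (35 ms) are merged into the
surrounding silence, and silent runs of at least the minimum pause duration
(150 ms) become pauses — so the utterance/pause partition is exhaustive.
Merging (rather than discarding) short speech bursts keeps the two-event
partition exact. Boundaries are reported at sample resolution but are
physically accurate only to about half the envelope window (±5 ms).

Pause statistics use the population SD (denominator n; switchable to n−1 via
config). A sentence with no pauses reports all four pause features as 0, not
NaN, so the factor analysis never sees missing values. Articulation rate is
words per minute of articulation time (total duration minus pauses); word
counts come from the manifest, not from recognition.

## Prosodic features

**Filterbank.** The pause-excised waveform is split into 28 channels with
contiguous edges equally spaced on the ERB-rate map
(E = 21.4 log₁₀(1 + 0.00437 f)) between 100 and 10,000 Hz. Channels are
Butterworth band-passes applied forward–backward (zero phase). The Hilbert
envelope of each channel is downsampled to 100 Hz and smoothed by a
second-order zero-lag Butterworth low-pass at 40 Hz, then clipped at 0.

**Rate normalization.** Envelopes are linearly time-scaled by
`ar / ar_norm` (duration factor), where `ar_norm` is the mean articulation
rate of the healthy-control rows of the manifest (config-overridable). A
slower-than-norm speaker is thus compressed in time, shifting their
modulation rhythms *up* toward normative rates; the identity holds exactly
when `ar == ar_norm`.

**Critical bands.** Envelopes are *summed* (preserving additivity of band
energy) into 100–300, 300–800, 1,000–3,000 and 3,000–8,000 Hz bands by
channel center frequency. Channels whose centers fall in the 800–1,000 and
8,000–10,000 Hz gaps belong to no band and are dropped.

**Modulation depth** per band and rhythm range (delta 0.9–2.5 Hz, theta
2.5–12 Hz, beta/gamma 12–40 Hz) is the fraction of the envelope's power
spectrum (Hamming-windowed 2,048-point FFT; Welch averaging for longer
envelopes) inside the range, with the DC bin excluded from the denominator —
otherwise the constant envelope level dominates and all depths collapse
toward 0. The three depths per band therefore lie in [0, 1] and sum to ≤ 1.

**Phase synchronization.** Each narrow-band envelope is band-pass filtered
at the three rhythm ranges (zero-lag Butterworth), the filtered oscillations
are summed into the four critical bands per rhythm, and
PSI = |⟨exp(i(nφ₁ − mφ₂))⟩| is computed between matched critical-band
signals at neighboring rhythms with n multiplying the **slower** rhythm's
phase — 2φ_delta − φ_theta and 3φ_theta − φ_beta/gamma — which is the only
orientation for which harmonic n:m locking yields a constant generalized
phase difference (PSI = 1). Instantaneous phase comes from the analytic
signal. Under independent phases PSI concentrates near N^(−1/2).

**Visibility density.** The waveform is reduced to a local-SD series
(non-overlapping 10 ms windows, denominator L−1); two points are joined in
the natural visibility graph iff the straight line between them passes
strictly above every intermediate point (adjacent points always connect;
exactly collinear runs connect only adjacent points). Density = 2m/(M(M−1)).
The implementation is an O(M²) running-max-slope scan, verified exactly
against an O(M³) all-pairs oracle.

**Intonation.** F0 is estimated by normalized cross-correlation with a
20 ms window for male and 10 ms for female speakers (search ranges 60–300
and 100–500 Hz; both config-exposed), a 10 ms hop, voicing threshold 0.6 on
the peak correlation, parabolic lag interpolation, and a subharmonic guard:
if a submultiple (1/2, 1/3) of the best period is at least 90% as periodic,
the shorter period wins — this removes octave-down errors that otherwise
inflate sdevF0 on discontinuous waveforms. sdevF0 and iqrF0 are computed
over voiced frames only; an unvoiced-only sample imputes both as 0 with an
`unvoiced` flag column.

## Complexity features

**Wavelet-packet entropy.** Depth-3 WPD with db4 (the Daubechies family
member chosen; order 4 balances support against frequency selectivity)
yields 8 terminal nodes in natural frequency order. Coefficients of each
node are normalized to unit energy before ShanEn = −Σ s²log s², making the
feature gain-invariant; the literal unnormalized form would vary with
recording level. Values lie in [0, log n]. Note an implication of this
definition: within a node, a constant-amplitude tone spreads energy evenly
over the time coefficients and so attains near-maximal entropy, while iid
noise sits ≈ 0.42 nats below the bound; entropy here measures the
*within-node temporal energy spread*, not spectral peakedness.

**Delta-MFCC determinism.** MFCCs use 25 ms Hamming frames, 10 ms hop,
pre-emphasis 0.97, 26 mel filters, orthonormal DCT-II, coefficients 0–12
(so a global gain change shifts only coefficient 0); deltas are ±2-frame
regression slopes. Each delta series is cut into 1-s segments
(approximately stationary), z-normalized per segment, delay-embedded
(m = 3, τ = 5), and thresholded at ε = 0.2 (in SD units because of the
z-normalization; a fixed-radius option exists in config). Determinism is
the fraction of recurrence points on diagonal lines of length ≥ 2, identity
line excluded, averaged over segments; zero recurrence reports DET = 0. The
implementation matches an O(N²) brute-force oracle exactly.

## Cepstral peak prominence

40 ms Hamming frames with 20 ms hop; per frame the real cepstrum of the dB
log power spectrum is searched for its peak in the 1/330–1/60 s quefrency
band, and a regression line fitted from 1 ms to the 60 Hz quefrency is
subtracted at the peak. CPP is the frame average over all frames of the
pause-excised sample (voiced-frame restriction was considered and rejected
to avoid coupling CPP to the voicing detector).

## Factor model

Features are z-standardized; the correlation matrix is factored by minres
(uniquenesses optimized by L-BFGS-B to minimize off-diagonal residuals; a
singular correlation matrix is ridge-regularized with a warning), rotated
with direct oblimin at γ = 0 (quartimin) via oblique gradient projection.
The factor count defaults to Horn parallel analysis: 100 random-normal
resamples, 95th-percentile eigenvalue criterion, counting stopped at the
first failure — the automated rule decides; scree output is advisory only.
Factor scores use the Ten Berge correlation-preserving estimator, so score
variances are ≈ 1 and score correlations match Φ.

Factors are auto-labeled X1–X6 when more than half of their salient
(|loading| > 0.4) features come from a single construct group (dynamics =
determinism + AR; entropy; pause; rhythm = modulation depths; regularity =
density + PSI; intonation = F0 spread); unresolved factors keep generic
names, since the construct mapping is an empirical result and is not
guaranteed on new data. CPP belongs to no group (empirically it
cross-loads), so a planted-factor table built from the six groups leaves
CPP as a noise column.

## Evaluation harness

**Regression.** OLS with bidirectional AIC stepwise search from the
intercept-only model, on z-standardized markers and metric (coefficients
are standardized). Sentence-level rows are the default, matching the
study design in which each participant contributes 19 sentences with a
repeated metric value; a participant-mean mode exists because repeated rows
understate uncertainty. Note the statistical character of AIC selection:
each irrelevant candidate enters with probability ≈ P(χ²₁ > 2) ≈ 0.16, so
occasional spurious terms are expected; the tests therefore assert support
recovery of true predictors and near-zero explained variance under the
null, not exact support sets.

**Classification.** Repeated stratified 5-fold CV (10 repeats by default);
per fold, the scaler and the SVM hyperparameters (C, γ by inner 3-fold grid
search; the RBF kernel is fixed) are fitted on the training split only.
The random forest uses 500 trees with √p features per split. Multiclass
AUC is macro one-vs-rest on predicted probabilities;
sensitivity/specificity/PPV/NPV are macro-averaged from per-fold confusion
matrices; pairwise ROC curves pool fold predictions restricted to each
class pair. Fold isolation is demonstrated by the label-permutation null
(AUC ≈ 0.5) — a feature equal to the label cannot detect leakage, since it
yields perfect AUC under both leaky and clean CV. All results are
deterministic given the seed. An optional grouped mode keeps all sentences
of a subject in the same fold, since sentence-level CV optimistically
ignores within-speaker dependence.

**Phenotyping.** Markers are residualized on age and sex (linear model over
all samples pooled; an HC-normative variant is a config alternative). The
adjusted markers plus the diagnosis (categorical) are clustered by PAM
(deterministic BUILD + SWAP on the precomputed Gower matrix;
range-normalized Manhattan for continuous, simple matching for categorical
columns, unweighted mean over columns). The cluster count is chosen by the
Gap statistic with B = 100 uniform reference sets (continuous columns
uniform over their range, categorical uniform over levels) and the
first-SE-max rule; ties in assignment break toward the lower cluster index.
Participants are subgrouped by majority vote over their sentences. Subgroup
profiles fit, per marker, a linear mixed model with subgroup fixed effect
and subject random intercept (Powell optimizer — the default gradient path
can silently mis-estimate fixed effects when the random-intercept variance
is on the 0 boundary), contrast each subgroup against the healthy-control
baseline via the estimated marginal-mean difference, convert to Cohen's d
using the model's total SD √(σ²_subject + σ²_residual), and apply
Benjamini–Hochberg FDR across all subgroup × marker tests. When subjects
lack repeated samples the model falls back to OLS with subject-clustered
robust errors.

## Synthetic fixtures

Surrogate sentences are built from a sawtooth-like glottal source with a
low-pass-filtered random F0 wander (target mean and SD), three formant
resonators (500/1,500/2,500 Hz), multiplicative amplitude modulation at one
rate per rhythm band, additive white noise at a target
harmonics-to-noise ratio, and planted silent pauses at stratified cut
points (≥ ~0.2 s of speech between pauses so each is individually
recoverable). Every generator is a pure function of its seed.

The paper-shape cohort emulates the study design: 39 speakers (14 ALS-like,
15 PD-like, 10 HC-like) × 19 sentences, 2 samples discarded, i.e. 739
usable rows; sentence word counts follow the 330-word/19-sentence reading
passage. Class recipes follow the respective clinical pictures — ALS-like:
slower articulation (≈140 wpm), longer and more variable pauses, reduced
modulation depth; PD-like: flattened F0 (monopitch) and reduced
harmonics-to-noise ratio; HC-like: ≈180 wpm, short regular pauses — with
demographics and functional metrics drawn around the reported group
summaries. **These surrogates exercise the signal-processing and
statistical contracts only.** They contain no phonetics, no coarticulation,
no true vocal pathology; separability of synthetic classes shows the
pipeline is sound, not that the markers discriminate real disease. Real
cohort sizes at this scale also do not support the 50-feature factor
model's asymptotics; recovery claims are made on the planted-factor tables.

## Problem sizes and numerical conventions

The test suite runs the planted-factor recovery at the full 739 × 50 design
across 20 seeds, the pause closed loop on 100 surrogates, phenotype
recovery at n = 200 with B = 100 Gap references, and the end-to-end
pipeline on a 24-sentence cohort with reduced CV repeats and Gap
references; `scripts/acceptance.py` runs the full 739-sentence cohort end
to end with 5 CV repeats. Degenerate inputs are handled explicitly:
zero-length audio and empty manifests are errors; all-silent sentences
yield a single whole-file pause; constant feature columns are dropped (with
a warning) before factoring; zero recurrence reports DET = 0; unvoiced
samples impute intonation features as 0 with a flag.

## Known limitations

- Pause detection is amplitude-only: filled pauses ("um") count as speech.
- The envelope construction for pause detection (10 ms moving RMS) is this
  package's choice; the upstream validated algorithm is not public.
- The F0 tracker is a plain NCC tracker with a subharmonic guard, adequate
  for surrogates and clean read speech, not for severely dysphonic voices.
- Sentence-level CV and sentence-level regression rows ignore within-speaker
  dependence; use `--group-by-subject` / participant-level mode for
  conservative estimates.
- No denoising, diarization, or transcription; word counts must be supplied.
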