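# speechmark

Interpretable acoustic speech markers for progressive communication disorders.

Dysarthria — the motor speech disorder accompanying neurodegenerative diseases
such as amyotrophic lateral sclerosis (ALS, mixed flaccid–spastic) and
Parkinson's disease (PD, hypokinetic) — changes the temporal, prosodic,
spectral and voice-quality structure of connected speech long before
intelligibility collapses. `speechmark` implements an automated,
clinically grounded analysis chain for sentence-length read-speech
recordings:

1. **Feature extraction** — 50 named acoustic features per sentence:
   - *Temporal organization* (5): pause mean/SD/CV/percentage from
     amplitude-threshold silence detection (minimum pause 150 ms, minimum
     speech 35 ms, threshold 0.04 on peak-normalized audio) and the
     articulation rate AR = words / articulation time.
   - *Prosody* (23): modulation depth of four critical-band Hilbert
     envelopes (100–300, 300–800, 1 000–3 000, 3 000–8 000 Hz; 28 ERB-spaced
     channels, envelopes at 100 Hz, articulation-rate normalized) in the
     delta (0.9–2.5 Hz), theta (2.5–12 Hz) and beta/gamma (12–40 Hz) rhythm
     bands; eight n:m phase-synchronization indices
     PSI = |⟨e^{i(nφ₁−mφ₂)}⟩| with 2:1 (delta–theta) and 3:1
     (theta–beta/gamma) coupling; natural-visibility-graph density
     2m/(M(M−1)) of the 10 ms local-SD series; SD and IQR of the F0
     contour (normalized cross-correlation, sex-specific windows).
   - *Complexity* (21): Shannon entropy −Σ s²log s² of the eight depth-3
     wavelet-packet nodes (db4), and recurrence-quantification determinism
     (m = 3, τ = 5, ε = 0.2, l_min = 2, 1-s segments) of the 13 delta-MFCC
     series.
   - *Voice quality* (1): cepstral peak prominence (dB).
2. **Composite markers** — exploratory factor analysis (minres factoring,
   oblimin rotation, factor count by Horn parallel analysis, Ten Berge
   factor scores) reduces the 50 features to six interpretable markers:
   X1 dynamics, X2 entropy, X3 pause, X4 rhythm, X5 regularity,
   X6 intonation.
3. **Evaluation** — stepwise-AIC regression of functional metrics (MoCA,
   intelligibility, communication efficiency) on the markers; SVM-RBF and
   random-forest multiclass classification under repeated stratified 5-fold
   cross-validation; and unsupervised phenotyping via PAM clustering on
   Gower distances with Gap-statistic model selection, majority-rule
   participant subgrouping, and mixed-model subgroup profiles (estimated
   marginal means, Cohen's d, Benjamini–Hochberg FDR).

A synthetic-fixture module generates speech-*like* surrogate sentences
(harmonic source, formant resonators, band-wise amplitude modulation,
planted pauses, controlled F0 spread and harmonics-to-noise ratio) and
tabular cohorts with known ground truth, so every stage is testable without
any recordings. Surrogate separability demonstrates that the pipeline works,
not that the markers are clinically valid — see `docs/methods.md`.

## Worked example

```sh
speechmark synth --preset mini --seed 7 --outdir demo        # 24 synthetic sentences
speechmark run-all demo/manifest.csv --outdir demo_out --seed 7
```

prints (numbers from this exact invocation):

```
wrote 24 samples to demo
artifacts: ['classification', 'clustering', 'features', 'markers', 'profiles', 'regression'] -> demo_out
```

and `demo_out/` then contains `features.csv` (24 × 50 feature table),
`factor_model.json` (loadings, factor correlations, Ten Berge weights),
`markers.csv` (composite scores per sentence), `regression.json`,
`classification.json` + `roc.csv`, `clustering.json` + `profiles.csv`, and
the exact `run_config.yaml` needed to regenerate everything. On this 24-
sentence run the parallel analysis retains 4 factors (labels
`['X2', 'X4', 'F3', 'X1']` — a factor that no construct group dominates
keeps a generic name) and cross-validated multiclass AUC is 0.92 (SVM) /
0.95 (RF): the synthetic class recipes are separable *by construction*,
which demonstrates the plumbing, not clinical validity (see
`docs/methods.md`).

Library use mirrors the CLI:

```python
from speechmark import load_audio, extract_features
audio = load_audio("demo/audio/S01_s01.wav", {"word_count": 17, "sex": "male"})
features, flags = extract_features(audio)   # dict of the 50 named features
```

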