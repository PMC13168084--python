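"""Synthetic fixtures: speech-like audio surrogates and tabular cohorts with
known ground truth.

The surrogates are speech-LIKE, not speech: a harmonic pulse-train source with
a wandering F0 contour is shaped by formant resonators, amplitude-modulated at
prosodic/syllabic/sub-syllabic rates, mixed with noise at a target
harmonics-to-noise ratio, and interrupted by planted silent pauses. They
exercise the signal-processing contracts of the extraction stages (pause
structure, modulation bands, F0 statistics, harmonicity) — separability of
synthetic cohorts says nothing about clinical validity on real dysarthric
speech.

The paper-shape cohort preset emulates the study design: 39 speakers
(14 ALS-like, 15 PD-like, 10 HC-like) x 19 read sentences with 2 samples
discarded, i.e. 739 usable rows, with class recipes following the clinical
picture (ALS-like: longer and more variable pauses, slower articulation,
reduced modulation depth; PD-like: flattened F0, reduced harmonicity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, sosfiltfilt

from speechmark.audio import AudioSample, write_wav
from speechmark.features import CONSTRUCT_GROUPS, FEATURE_NAMES

RATE = 22050

# word counts of the 19 read sentences (330 words total, passage-shaped)
SENTENCE_WORDS = [22, 18, 15, 19, 16, 17, 20, 14, 18, 17, 16, 19, 15, 18, 17, 21, 16, 14, 18]


@dataclass
class SpeechSurrogateSpec:
    """Parameters of one speech-like surrogate sentence.

    ``duration`` is articulation time in seconds (pauses extend the total);
    AM depths/rates are per rhythm band; ``hnr_db`` sets the
    harmonics-to-noise ratio; ``seed`` fixes all randomness.
    """

    duration: float = 2.5
    f0_mean: float = 120.0
    f0_sd: float = 15.0
    formants: tuple = ((500.0, 80.0), (1500.0, 120.0), (2500.0, 200.0))
    am_depth: dict = field(default_factory=lambda: {"delta": 0.3, "theta": 0.5, "beta.gamma": 0.15})
    am_rates: dict = field(default_factory=lambda: {"delta": 1.8, "theta": 4.5, "beta.gamma": 20.0})
    pause_plan: tuple = (0.3,)
    hnr_db: float = 20.0
    seed: int = 0


def _resonator(x: np.ndarray, freq: float, bw: float, rate: float) -> np.ndarray:
    """Second-order all-pole formant resonator."""
    r = np.exp(-np.pi * bw / rate)
    theta = 2.0 * np.pi * freq / rate
    a = [1.0, -2.0 * r * np.cos(theta), r**2]
    gain = (1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2 * theta) + r**2)
    return lfilter([gain], a, x)


def synth_speech(spec: SpeechSurrogateSpec, rate: float = RATE) -> tuple[np.ndarray, dict]:
    """Generate one surrogate sentence. Returns (samples, ground truth).

    Ground truth records the planted pause intervals in the output timeline,
    the AM parameters, and the generated F0 contour statistics.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * rate))
    if n < rate // 10:
        raise ValueError("duration too short")
    t = np.arange(n) / rate

    # F0 contour: slow wander with SD ~ f0_sd around f0_mean
    if spec.f0_sd > 0:
        wander = rng.standard_normal(n)
        sos = butter(2, 3.0 / (rate / 2.0), btype="low", output="sos")
        wander = sosfiltfilt(sos, wander)
        sd = wander.std()
        wander = wander / sd * spec.f0_sd if sd > 0 else wander * 0.0
    else:
        wander = np.zeros(n)
    f0 = np.clip(spec.f0_mean + wander, 40.0, 600.0)

    phase = np.cumsum(f0) / rate
    source = 2.0 * (phase % 1.0) - 1.0  # sawtooth-like glottal source
    voiced = source.copy()
    for freq, bw in spec.formants:
        voiced = _resonator(voiced, freq, bw, rate)
    voiced /= np.max(np.abs(voiced)) + 1e-12

    mod = np.ones(n)
    am_phases = {}
    for band, depth in spec.am_depth.items():
        ph = rng.uniform(0, 2 * np.pi)
        am_phases[band] = ph
        mod *= 1.0 + depth * np.sin(2 * np.pi * spec.am_rates[band] * t + ph)
    mod = np.clip(mod, 0.0, None)
    x = voiced * mod

    sig_power = np.mean(x**2)
    noise_power = sig_power / (10.0 ** (spec.hnr_db / 10.0))
    x = x + rng.standard_normal(n) * np.sqrt(noise_power)

    # insert pauses at interior cut points of the articulated timeline
    total_pause = float(np.sum(spec.pause_plan))
    if total_pause >= spec.duration:
        raise ValueError("pause plan exceeds duration")
    pauses = []
    plan = list(spec.pause_plan)
    if plan:
        # stratified cut placement: >= ~0.2 s of speech between planted
        # pauses so they stay individually recoverable
        margin = 0.2
        max_pauses = max(1, int((spec.duration - 2 * margin) / 0.35))
        plan = plan[:max_pauses]
        span = (spec.duration - 2 * margin) / len(plan)
        cuts = np.array(
            [margin + (i + rng.uniform(0.3, 0.7)) * span for i in range(len(plan))]
        )
        segments = []
        prev = 0
        offset = 0.0
        truth_pauses = []
        for cut, pdur in zip(cuts, plan):
            ci = int(round(cut * rate))
            segments.append(x[prev:ci])
            onset = ci / rate + offset
            truth_pauses.append((onset, onset + pdur))
            segments.append(np.zeros(int(round(pdur * rate))))
            offset += pdur
            prev = ci
        segments.append(x[prev:])
        x = np.concatenate(segments)
        pauses = truth_pauses
    peak = np.max(np.abs(x))
    x = x / peak if peak > 0 else x
    truth = {
        "pauses": [(float(a), float(b)) for a, b in pauses],
        "duration": len(x) / rate,
        "articulation_s": spec.duration,
        "am_depth": dict(spec.am_depth),
        "am_rates": dict(spec.am_rates),
        "f0_mean": float(np.mean(f0)),
        "f0_sd": float(np.std(f0)),
        "hnr_db": spec.hnr_db,
    }
    return x, truth


# per-class generator recipes (study conditions; see docs/methods.md)
CLASS_RECIPES = {
    "HC": dict(ar=(180.0, 15.0), n_pauses=(1, 2), pause_dur=(0.25, 0.05),
               f0_sd=(25.0, 5.0), hnr=(25.0, 2.0),
               am=({"delta": 0.35, "theta": 0.50, "beta.gamma": 0.15}),
               female_frac=0.70, age=(66.8, 13.0),
               moca=(26.8, 1.3), intel=(99.5, 0.6), eff=(182.7, 23.3)),
    "ALS": dict(ar=(140.0, 20.0), n_pauses=(2, 4), pause_dur=(0.45, 0.15),
                f0_sd=(18.0, 5.0), hnr=(18.0, 3.0),
                am=({"delta": 0.25, "theta": 0.35, "beta.gamma": 0.10}),
                female_frac=0.29, age=(57.2, 14.7),
                moca=(25.4, 3.7), intel=(96.3, 3.4), eff=(139.2, 25.4)),
    "PD": dict(ar=(165.0, 15.0), n_pauses=(1, 3), pause_dur=(0.30, 0.10),
               f0_sd=(8.0, 3.0), hnr=(12.0, 3.0),
               am=({"delta": 0.32, "theta": 0.45, "beta.gamma": 0.13}),
               female_frac=0.40, age=(69.9, 6.5),
               moca=(24.7, 4.2), intel=(94.9, 3.0), eff=(156.5, 32.6)),
}

PAPER_SHAPE = {"ALS": 14, "PD": 15, "HC": 10, "sentences": 19, "discard": 2}


def synth_cohort(
    outdir: str | Path,
    seed: int = 0,
    n_subjects: dict[str, int] | None = None,
    n_sentences: int | None = None,
    n_discard: int | None = None,
    shuffle_labels: bool = False,
) -> pd.DataFrame:
    """Generate a labeled cohort of surrogate sentences on disk.

    Defaults reproduce the paper-shape design (739 usable samples). Writes
    WAV files, ``manifest.csv`` and per-sample ground truth
    (``truth.json``); returns the manifest. Bit-reproducible from ``seed``.
    """
    outdir = Path(outdir)
    (outdir / "audio").mkdir(parents=True, exist_ok=True)
    n_subjects = n_subjects or {k: PAPER_SHAPE[k] for k in ("ALS", "PD", "HC")}
    n_sentences = PAPER_SHAPE["sentences"] if n_sentences is None else n_sentences
    n_discard = PAPER_SHAPE["discard"] if n_discard is None else n_discard
    rng = np.random.default_rng(seed)
    rows = []
    truth_all = {}
    subj_num = 0
    for group in ("ALS", "PD", "HC"):
        recipe = CLASS_RECIPES[group]
        for _ in range(n_subjects.get(group, 0)):
            subj_num += 1
            subject_id = f"S{subj_num:02d}"
            sex = "female" if rng.random() < recipe["female_frac"] else "male"
            age = float(np.clip(rng.normal(*recipe["age"]), 35, 90))
            f0_mean = rng.normal(200, 15) if sex == "female" else rng.normal(120, 10)
            ar_subj = max(80.0, rng.normal(*recipe["ar"]))
            f0_sd_subj = max(2.0, rng.normal(*recipe["f0_sd"]))
            moca = float(np.clip(rng.normal(*recipe["moca"]), 0, 30))
            intel = float(np.clip(rng.normal(*recipe["intel"]), 50, 100))
            eff = float(max(40.0, rng.normal(*recipe["eff"])))
            for s in range(n_sentences):
                words = SENTENCE_WORDS[s % len(SENTENCE_WORDS)]
                ar_sent = max(70.0, ar_subj + rng.normal(0, 8))
                duration = 60.0 * words / ar_sent
                n_p = int(rng.integers(recipe["n_pauses"][0], recipe["n_pauses"][1] + 1))
                pause_plan = tuple(
                    float(max(0.16, rng.normal(*recipe["pause_dur"]))) for _ in range(n_p)
                )
                spec = SpeechSurrogateSpec(
                    duration=duration,
                    f0_mean=float(f0_mean),
                    f0_sd=f0_sd_subj,
                    am_depth={k: max(0.02, v + rng.normal(0, 0.04))
                              for k, v in recipe["am"].items()},
                    hnr_db=float(rng.normal(*recipe["hnr"])),
                    pause_plan=pause_plan,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                sample_id = f"{subject_id}_s{s + 1:02d}"
                x, truth = synth_speech(spec)
                write_wav(outdir / "audio" / f"{sample_id}.wav", x, RATE)
                truth["ar_true"] = 60.0 * words / duration
                truth_all[sample_id] = truth
                rows.append({
                    "sample_id": sample_id,
                    "path": f"audio/{sample_id}.wav",
                    "subject_id": subject_id,
                    "sentence_index": s + 1,
                    "word_count": words,
                    "sex": sex,
                    "age": round(age, 1),
                    "group": group,
                    "moca": round(moca, 1),
                    "intelligibility": round(intel, 1),
                    "efficiency": round(eff, 1),
                })
    manifest = pd.DataFrame(rows)
    if n_discard:
        drop = rng.choice(len(manifest), size=n_discard, replace=False)
        dropped = manifest.iloc[sorted(drop)]["sample_id"].tolist()
        manifest = manifest.drop(manifest.index[sorted(drop)]).reset_index(drop=True)
        for sid in dropped:
            (outdir / "audio" / f"{sid}.wav").unlink()
            truth_all.pop(sid)
    if shuffle_labels:
        perm = rng.permutation(len(manifest))
        manifest["group"] = manifest["group"].to_numpy()[perm]
        for sid, g in zip(manifest["sample_id"], manifest["group"]):
            truth_all[sid]["shuffled_group"] = g
    manifest.to_csv(outdir / "manifest.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth_all, indent=1))
    return manifest


def planted_loadings(value: float = 0.8, k: int = 6) -> np.ndarray:
    """Block loading matrix (50 x k) mirroring the six construct groups.

    Delta-band modulation depths load negatively on the rhythm factor,
    matching the slow-vs-fast rhythm balance interpretation.
    """
    groups = list(CONSTRUCT_GROUPS)[:k]
    L = np.zeros((len(FEATURE_NAMES), k))
    for j, grp in enumerate(groups):
        for feat in CONSTRUCT_GROUPS[grp]:
            sign = -1.0 if feat.startswith("hbenvlp_mod_depth_delta") else 1.0
            L[FEATURE_NAMES.index(feat), j] = sign * value
    return L


def synth_feature_table(
    n: int,
    loadings: np.ndarray | None = None,
    noise_sd: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table with planted factor structure: rows = L f + noise.

    Factors are standard normal; returns (table, generating factors) so
    recovery can be scored.
    """
    rng = np.random.default_rng(seed)
    L = planted_loadings() if loadings is None else np.asarray(loadings)
    p, k = L.shape
    factors = rng.standard_normal((n, k))
    X = factors @ L.T + rng.standard_normal((n, p)) * noise_sd
    names = FEATURE_NAMES if p == len(FEATURE_NAMES) else [f"v{i+1}" for i in range(p)]
    return pd.DataFrame(X, columns=names), factors
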