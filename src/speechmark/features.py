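"""The 50-feature acoustic inventory and single-sample extraction.

Feature keys and order are fixed: 5 temporal, 12 modulation depths, 8 PSI,
1 visibility density, 2 intonation, 8 wavelet-packet entropies, 13 delta-MFCC
determinisms, 1 CPP. Construct groups map features to the six composite
markers (X1 dynamics, X2 entropy, X3 pause, X4 rhythm, X5 regularity,
X6 intonation) used for factor labeling.
"""

from __future__ import annotations

import numpy as np

from speechmark import complexity, prosody, temporal, voice
from speechmark.audio import AudioSample
from speechmark.config import DEFAULT_CONFIG

_PAUSE = ["MeanDur_pause", "SdevDur_pause", "CvDur_pause", "pct_pause"]
_MOD = [
    f"hbenvlp_mod_depth_{rhythm}_{band}"
    for rhythm in prosody.RHYTHM_NAMES
    for band in prosody.BAND_NAMES
]
_PSI = [
    f"hbenvlp_PSI_{pair}_{band}"
    for pair in ("delta_theta", "theta_beta.gamma")
    for band in prosody.BAND_NAMES
]
_ENTROPY = [f"ShanEn_{i}" for i in range(1, 9)]
_DET = [f"DET_dmfcc_{i}" for i in range(1, 14)]

FEATURE_NAMES: list[str] = (
    _PAUSE + ["AR"] + _MOD + _PSI + ["density", "sdevF0", "iqrF0"] + _ENTROPY + _DET + ["CPP"]
)
assert len(FEATURE_NAMES) == 50

CONSTRUCT_GROUPS: dict[str, list[str]] = {
    "dynamics": _DET + ["AR"],
    "entropy": _ENTROPY,
    "pause": _PAUSE,
    "rhythm": _MOD,
    "regularity": ["density"] + _PSI,
    "intonation": ["sdevF0", "iqrF0"],
}

# canonical composite-marker codes per construct
MARKER_CODES: dict[str, str] = {
    "dynamics": "X1",
    "entropy": "X2",
    "pause": "X3",
    "rhythm": "X4",
    "regularity": "X5",
    "intonation": "X6",
}


def extract_features(
    audio: AudioSample,
    ar_norm: float | None = None,
    config: dict | None = None,
) -> tuple[dict[str, float], dict[str, bool]]:
    """Extract all 50 features from one peak-normalized sentence recording.

    ``ar_norm`` is the normative articulation rate used for envelope
    time-scaling (cohort HC mean in pipeline runs); with ``None`` the
    sample's own rate is used, i.e. no rescaling. Returns the feature dict
    (keys = FEATURE_NAMES, canonical order) and imputation flags.
    """
    cfg = config or DEFAULT_CONFIG
    flags: dict[str, bool] = {"unvoiced": False}
    feats: dict[str, float] = {}

    p = cfg["pause"]
    seg = temporal.detect_pauses(
        audio,
        min_pause=p["min_pause_s"],
        min_speech=p["min_speech_s"],
        amp_thresh=p["amp_thresh"],
        env_window=p["env_window_s"],
    )
    feats.update(temporal.pause_statistics(seg, ddof=p["sd_ddof"]))
    ar = temporal.articulation_rate(seg, audio.word_count)
    feats["AR"] = ar
    speech = temporal.excise_pauses(audio, seg)
    if len(speech) < audio.rate:
        raise ValueError("less than 1 s of speech after pause excision")

    r = cfg["rhythm"]
    bank = prosody.cochlear_filterbank(
        speech, audio.rate, n_channels=r["n_channels"], fmin=r["fmin"],
        fmax=r["fmax"], env_rate=r["env_rate"],
    )
    bank = prosody.rate_normalize(bank, ar, ar_norm if ar_norm else ar)
    crit = prosody.aggregate_critical_bands(bank)
    feats.update(prosody.modulation_depth(crit, env_rate=r["env_rate"], nfft=r["nfft"]))
    feats.update(prosody.psi_features(bank))

    sd_series = prosody.local_sd_series(speech, audio.rate, L_ms=cfg["visibility"]["L_ms"])
    feats["density"] = prosody.visibility_density(sd_series)

    f0cfg = cfg["f0"]
    intonation = prosody.f0_contour(
        speech, audio.rate, audio.sex,
        window_ms=f0cfg["window_ms"],
        pitch_range={k: tuple(v) for k, v in f0cfg["range_hz"].items()},
        hop_s=f0cfg["hop_s"],
        voicing_threshold=f0cfg["voicing_threshold"],
    )
    if intonation["voiced"]:
        feats["sdevF0"] = intonation["sdevF0"]
        feats["iqrF0"] = intonation["iqrF0"]
    else:  # unvoiced-only sample: impute 0, flag
        feats["sdevF0"] = 0.0
        feats["iqrF0"] = 0.0
        flags["unvoiced"] = True

    w = cfg["wpd"]
    feats.update(complexity.wpd_entropy(speech, wavelet=w["wavelet"], level=w["level"]))

    mc = cfg["mfcc"]
    dmfcc = complexity.delta_mfcc(
        speech, audio.rate, n_mfcc=mc["n_mfcc"], frame_s=mc["frame_s"],
        hop_s=mc["hop_s"], n_filters=mc["n_filters"], preemphasis=mc["preemphasis"],
    )
    q = cfg["rqa"]
    feats.update(
        complexity.determinism_features(
            dmfcc, frame_rate=1.0 / mc["hop_s"], segment_s=q["segment_s"],
            m=q["m"], tau=q["tau"], eps=q["eps"], lmin=q["lmin"],
        )
    )

    c = cfg["cpp"]
    feats["CPP"] = voice.cpp(
        speech, audio.rate, frame_ms=c["frame_ms"], hop_ms=c["hop_ms"],
        qmin_hz=c["qmin_hz"], qmax_hz=c["qmax_hz"],
    )["CPP"]

    ordered = {name: float(feats[name]) for name in FEATURE_NAMES}
    if not all(np.isfinite(v) for v in ordered.values()):
        bad = [k for k, v in ordered.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite features: {bad}")
    return ordered, flags
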