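"""Audio I/O, normalization, and speaker metadata.

Recordings are one read sentence per file, mono PCM WAV, nominally 22,050 Hz.
All amplitudes are handled on a peak-normalized scale in [-1, 1] because the
downstream pause detector uses a fixed amplitude threshold that is only
meaningful once gain differences have been removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

MANIFEST_COLUMNS = [
    "sample_id",
    "path",
    "subject_id",
    "sentence_index",
    "word_count",
    "sex",
    "age",
    "group",
    "moca",
    "intelligibility",
    "efficiency",
]

_REQUIRED_COLUMNS = ["sample_id", "path", "subject_id", "sentence_index", "word_count", "sex", "age"]


@dataclass
class AudioSample:
    """One sentence recording with its speaker metadata.

    ``samples`` is a float array in [-1, 1] (peak-normalized), ``rate`` the
    sampling frequency in Hz. ``group`` is the diagnostic label (ALS/PD/HC)
    or ``None`` for unlabeled samples.
    """

    samples: np.ndarray
    rate: float
    sample_id: str = ""
    subject_id: str = ""
    sentence_index: int = 1
    word_count: int = 1
    sex: str = "male"
    age: float = 0.0
    group: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")


def _to_float(data: np.ndarray) -> np.ndarray:
    """Convert integer PCM to float in [-1, 1)."""
    if data.dtype == np.int16:
        return data / 32768.0
    if data.dtype == np.int32:
        return data / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64)


def peak_normalize(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x)) if len(x) else 0.0
    if peak == 0:
        return np.asarray(x, dtype=np.float64)
    return np.asarray(x, dtype=np.float64) / peak


def load_audio(
    path: str | Path,
    manifest_row: dict | pd.Series | None = None,
    *,
    downmix: bool = False,
    normalize: bool = True,
) -> AudioSample:
    """Read a PCM WAV file, optionally downmix to mono, and peak-normalize.

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` for
    zero-length audio or for multichannel input without ``downmix=True``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    rate, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError("zero-length audio")
    x = _to_float(np.asarray(data))
    if x.ndim == 2:
        if not downmix:
            raise ValueError("non-mono input; pass downmix=True to average channels")
        x = x.mean(axis=1)
    if normalize:
        x = peak_normalize(x)
    meta = {}
    kwargs: dict = {}
    if manifest_row is not None:
        row = dict(manifest_row)
        for key in ("sample_id", "subject_id", "sex"):
            if key in row and pd.notna(row[key]):
                kwargs[key] = str(row[key])
        for key, caster in (("sentence_index", int), ("word_count", int), ("age", float)):
            if key in row and pd.notna(row[key]):
                kwargs[key] = caster(row[key])
        if "group" in row and pd.notna(row["group"]):
            kwargs["group"] = str(row["group"])
        for key in ("moca", "intelligibility", "efficiency"):
            if key in row and pd.notna(row[key]):
                meta[key] = float(row[key])
    return AudioSample(samples=x, rate=float(rate), meta=meta, **kwargs)


def write_wav(path: str | Path, samples: np.ndarray, rate: float) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM WAV."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(rate), pcm)


def resample(audio: AudioSample, target_rate: float) -> AudioSample:
    """Band-limited resampling conserving duration to within one sample period."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == audio.rate:
        return audio
    from fractions import Fraction

    frac = Fraction(int(round(target_rate)), int(round(audio.rate))).limit_denominator(10000)
    y = resample_poly(audio.samples, frac.numerator, frac.denominator)
    return replace(audio, samples=y, rate=float(target_rate))


def load_manifest(path: str | Path, *, check_files: bool = True) -> pd.DataFrame:
    """Read and validate a sample manifest CSV.

    Required columns: sample_id, path, subject_id, sentence_index, word_count,
    sex, age. Optional: group, moca, intelligibility, efficiency. Relative
    audio paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dupes}")
    if (df["word_count"] < 1).any():
        raise ValueError("word_count must be >= 1 for every row")
    df = df.copy()
    df["path"] = [
        str(p) if Path(p).is_absolute() else str(path.parent / p) for p in df["path"]
    ]
    if check_files:
        absent = [p for p in df["path"] if not Path(p).exists()]
        if absent:
            raise FileNotFoundError(f"manifest references missing files: {absent[:5]}")
    return df
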