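"""Pause detection and temporal-organization features.

A read sentence is partitioned exhaustively into two event types, utterances
and pauses, by thresholding a smoothed amplitude envelope. Defaults follow
the validated silence-detection settings: minimum pause duration 150 ms,
minimum speech duration 35 ms, amplitude threshold 0.04 on peak-normalized
audio. Four pause statistics plus the articulation rate (words per minute of
articulation time) summarize temporal organization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from speechmark.audio import AudioSample


@dataclass
class Segmentation:
    """Exhaustive two-event partition of a recording.

    ``pauses`` and ``speech`` are sorted, non-overlapping half-open intervals
    [onset, offset) in seconds whose union is [0, total_duration).
    """

    pauses: list[tuple[float, float]]
    speech: list[tuple[float, float]]
    total_duration: float

    @property
    def pause_durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.pauses])

    @property
    def total_pause(self) -> float:
        return float(self.pause_durations.sum()) if self.pauses else 0.0


def amplitude_envelope(x: np.ndarray, rate: float, window_s: float = 0.010) -> np.ndarray:
    """Moving-RMS envelope of the rectified signal (window 10 ms by default)."""
    w = max(1, int(round(window_s * rate)))
    power = uniform_filter1d(x.astype(np.float64) ** 2, size=w, mode="nearest")
    return np.sqrt(np.clip(power, 0.0, None))  # filter rounding can dip below 0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_pauses(
    audio: AudioSample,
    min_pause: float = 0.150,
    min_speech: float = 0.035,
    amp_thresh: float = 0.04,
    env_window: float = 0.010,
) -> Segmentation:
    """Detect silent pauses by amplitude-envelope thresholding.

    The smoothed envelope is compared to ``amp_thresh`` sample-by-sample;
    supra-threshold runs shorter than ``min_speech`` are merged into the
    surrounding silence (they cannot stand as utterances), and sub-threshold
    runs of at least ``min_pause`` become pauses. Everything else is speech,
    so the partition is exhaustive.
    """
    x = audio.samples
    rate = audio.rate
    if len(x) < max(1, int(round(env_window * rate))):
        raise ValueError("audio shorter than one envelope frame")
    env = amplitude_envelope(x, rate, env_window)
    silent = env < amp_thresh

    min_speech_n = int(round(min_speech * rate))
    for start, stop in _runs(~silent):
        if stop - start < min_speech_n:
            silent[start:stop] = True

    min_pause_n = int(round(min_pause * rate))
    pauses = [
        (start / rate, stop / rate)
        for start, stop in _runs(silent)
        if stop - start >= min_pause_n
    ]
    total = len(x) / rate
    speech: list[tuple[float, float]] = []
    cursor = 0.0
    for a, b in pauses:
        if a > cursor:
            speech.append((cursor, a))
        cursor = b
    if cursor < total:
        speech.append((cursor, total))
    return Segmentation(pauses=pauses, speech=speech, total_duration=total)


def pause_statistics(seg: Segmentation, ddof: int = 0) -> dict[str, float]:
    """Mean, SD (population by default), CV and percentage of pause duration.

    With zero pauses all four features are 0 by convention, so the feature
    table never carries missing values into the factor analysis.
    """
    durs = seg.pause_durations
    if durs.size == 0:
        return {"MeanDur_pause": 0.0, "SdevDur_pause": 0.0, "CvDur_pause": 0.0, "pct_pause": 0.0}
    mean = float(durs.mean())
    sd = float(durs.std(ddof=ddof)) if durs.size > ddof else 0.0
    cv = sd / mean if mean > 0 else 0.0
    pct = 100.0 * float(durs.sum()) / seg.total_duration
    return {"MeanDur_pause": mean, "SdevDur_pause": sd, "CvDur_pause": cv, "pct_pause": pct}


def articulation_rate(seg: Segmentation, word_count: int) -> float:
    """Words per minute of articulation time (total duration minus pauses)."""
    if word_count < 1:
        raise ValueError("word_count must be >= 1")
    art_time = seg.total_duration - seg.total_pause
    if art_time <= 0:
        raise ValueError("articulation time is non-positive")
    return word_count / (art_time / 60.0)


def excise_pauses(audio: AudioSample, seg: Segmentation) -> np.ndarray:
    """Concatenate the speech intervals, dropping all pauses."""
    rate = audio.rate
    parts = [audio.samples[int(round(a * rate)) : int(round(b * rate))] for a, b in seg.speech]
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)
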