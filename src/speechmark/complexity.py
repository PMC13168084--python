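"""Complexity features: wavelet-packet Shannon entropy and delta-MFCC
recurrence determinism.

Spectral complexity is measured by the Shannon entropy of the eight terminal
nodes of a depth-3 wavelet packet decomposition (Daubechies-4), with node
coefficients normalized to unit energy so the measure is gain-invariant.
Vocal-tract movement complexity is measured by recurrence quantification of
the delta (first-derivative) series of the first 13 mel-frequency cepstral
coefficients: each delta series is embedded (m=3, tau=5), a recurrence plot
is thresholded at radius 0.2 on the z-normalized series, and determinism is
the fraction of recurrence points lying on diagonal lines of length >= 2 —
high determinism means predictable, low-complexity articulatory dynamics.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.fft import dct, next_fast_len
from scipy.spatial.distance import cdist

_ENERGY_FLOOR = 1e-12


def shannon_entropy(coefficients: np.ndarray) -> float:
    """Shannon entropy of energy-normalized coefficients, in nats.

    0 for a single nonzero coefficient; log(n) for n equal-energy ones.
    """
    c = np.asarray(coefficients, dtype=np.float64)
    energy = float(np.sum(c**2))
    if energy < _ENERGY_FLOOR:
        return 0.0
    p = c**2 / energy
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def wpd_entropy(
    samples: np.ndarray, wavelet: str = "db4", level: int = 3
) -> dict[str, float]:
    """Shannon entropy of the 2**level terminal WPD nodes in frequency order.

    Coefficients of each node are energy-normalized (sum s_i^2 = 1) before
    ShanEn = -sum s_i^2 log(s_i^2); values lie in [0, log n_coeffs]. A node
    below the energy floor (e.g. silence) contributes 0.
    """
    x = np.asarray(samples, dtype=np.float64)
    wav = pywt.Wavelet(wavelet)
    if len(x) < wav.dec_len * 2**level:
        raise ValueError("input too short for the requested decomposition depth")
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="symmetric", maxlevel=level)
    out: dict[str, float] = {}
    for i, node in enumerate(wp.get_level(level, order="freq"), start=1):
        out[f"ShanEn_{i}"] = shannon_entropy(np.asarray(node.data, dtype=np.float64))
    return out


def _mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_inv(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, rate: float) -> np.ndarray:
    """Triangular mel filterbank (n_filters, nfft//2 + 1) from 0 to Nyquist."""
    points = np.asarray(_mel_inv(np.linspace(0.0, _mel(rate / 2.0), n_filters + 2)))
    bins = np.floor((nfft + 1) * points / rate).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for j in range(n_filters):
        left, center, right = bins[j], bins[j + 1], bins[j + 2]
        center = max(center, left + 1)
        right = max(right, center + 1)
        fb[j, left:center] = (np.arange(left, center) - left) / (center - left)
        fb[j, center:right] = (right - np.arange(center, right)) / (right - center)
    return fb


def mfcc(
    samples: np.ndarray,
    rate: float,
    n_mfcc: int = 13,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    n_filters: int = 26,
    preemphasis: float = 0.97,
) -> np.ndarray:
    """Mel-frequency cepstral coefficients, shape (n_mfcc, n_frames).

    25 ms Hamming frames, 10 ms hop (100 Hz frame rate), 26 mel filters,
    orthonormal DCT-II; coefficients 0..n_mfcc-1 are returned (a global gain
    change shifts only coefficient 0).
    """
    x = np.asarray(samples, dtype=np.float64)
    x = np.append(x[0], x[1:] - preemphasis * x[:-1])
    frame_len = int(round(frame_s * rate))
    hop = int(round(hop_s * rate))
    if len(x) < frame_len:
        raise ValueError("input shorter than one analysis frame")
    n_frames = (len(x) - frame_len) // hop + 1
    idx = np.arange(n_frames)[:, None] * hop + np.arange(frame_len)[None, :]
    frames = x[idx] * np.hamming(frame_len)[None, :]
    nfft = next_fast_len(frame_len)
    power = np.abs(np.fft.rfft(frames, nfft)) ** 2 / nfft
    fb = mel_filterbank(n_filters, nfft, rate)
    feats = np.log(power @ fb.T + 1e-12)
    coeffs = dct(feats, type=2, norm="ortho", axis=1)[:, :n_mfcc]
    return coeffs.T


def delta(series: np.ndarray, width: int = 2) -> np.ndarray:
    """Delta (regression slope over +/-width frames) along the last axis."""
    c = np.atleast_2d(np.asarray(series, dtype=np.float64))
    padded = np.pad(c, ((0, 0), (width, width)), mode="edge")
    denom = 2.0 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(c)
    for n in range(1, width + 1):
        out += n * (padded[:, width + n : padded.shape[1] - width + n]
                    - padded[:, width - n : padded.shape[1] - width - n])
    out /= denom
    return out if series.ndim > 1 else out[0]


def delta_mfcc(samples: np.ndarray, rate: float, n_mfcc: int = 13, **kwargs) -> np.ndarray:
    """Delta coefficients of the first ``n_mfcc`` MFCCs, shape (n_mfcc, n_frames)."""
    if len(samples) < rate:
        raise ValueError("need at least 1 s of audio for delta-MFCC analysis")
    return delta(mfcc(samples, rate, n_mfcc=n_mfcc, **kwargs))


def recurrence_matrix(
    series: np.ndarray, m: int = 3, tau: int = 5, eps: float = 0.2, znorm: bool = True
) -> np.ndarray:
    """Boolean recurrence plot of a delay-embedded series (Euclidean norm).

    With ``znorm`` the series is z-scored first, so the radius is in SD
    units; a (near-)constant series maps to all zeros and recurs everywhere.
    """
    u = np.asarray(series, dtype=np.float64)
    if znorm:
        sd = u.std()
        u = (u - u.mean()) / sd if sd > 1e-12 else np.zeros_like(u)
    n_vec = len(u) - (m - 1) * tau
    if n_vec < 2:
        raise ValueError("series too short for the embedding")
    X = np.stack([u[i * tau : i * tau + n_vec] for i in range(m)], axis=1)
    return cdist(X, X) <= eps


def _diagonal_counts(R: np.ndarray, lmin: int) -> tuple[int, int]:
    """(points on diagonals >= lmin, all points), identity line excluded."""
    n = R.shape[0]
    on_lines = 0
    total = 0
    for d in range(1, n):
        diag = np.diagonal(R, offset=d)
        total += int(diag.sum())
        padded = np.concatenate(([False], diag, [False])).astype(np.int8)
        changes = np.diff(padded)
        run_lengths = np.flatnonzero(changes == -1) - np.flatnonzero(changes == 1)
        on_lines += int(run_lengths[run_lengths >= lmin].sum())
    return 2 * on_lines, 2 * total  # symmetric: both triangles


def rqa_determinism(
    series: np.ndarray,
    m: int = 3,
    tau: int = 5,
    eps: float = 0.2,
    lmin: int = 2,
    znorm: bool = True,
) -> float:
    """Determinism of a recurrence plot: the fraction of recurrence points
    forming diagonal lines of length >= ``lmin`` (identity line excluded).

    Returns 0 when the plot has no recurrence points at all.
    """
    R = recurrence_matrix(series, m=m, tau=tau, eps=eps, znorm=znorm)
    on_lines, total = _diagonal_counts(R, lmin)
    return on_lines / total if total > 0 else 0.0


def determinism_features(
    dmfcc: np.ndarray,
    frame_rate: float = 100.0,
    segment_s: float = 1.0,
    m: int = 3,
    tau: int = 5,
    eps: float = 0.2,
    lmin: int = 2,
) -> dict[str, float]:
    """Mean determinism of each delta-MFCC series over 1-s segments.

    Each series is cut into consecutive ``segment_s`` windows (approximately
    stationary); determinism is computed per window and averaged.
    """
    dmfcc = np.atleast_2d(dmfcc)
    seg_len = int(round(segment_s * frame_rate))
    n_seg = dmfcc.shape[1] // seg_len
    if n_seg < 1:
        raise ValueError("need at least one full segment of delta-MFCC frames")
    out: dict[str, float] = {}
    for i, series in enumerate(dmfcc, start=1):
        vals = [
            rqa_determinism(series[s * seg_len : (s + 1) * seg_len], m, tau, eps, lmin)
            for s in range(n_seg)
        ]
        out[f"DET_dmfcc_{i}"] = float(np.mean(vals))
    return out
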