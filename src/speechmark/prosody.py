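"""Prosodic features: envelope rhythm, phase synchronization, waveform
regularity, and intonation.

The pause-excised waveform is decomposed into 28 narrow bands spaced evenly on
the cochlear (ERB-rate) map between 100 and 10,000 Hz. Each band's Hilbert
envelope is downsampled to 100 Hz, low-pass smoothed at 40 Hz, and linearly
time-scaled by the speaker's articulation rate relative to a normative rate so
that rhythm measurements are comparable across speaking rates. Envelopes are
aggregated into four critical bands (100-300, 300-800, 1,000-3,000,
3,000-8,000 Hz) carrying source, vowel-formant, and consonant-noise
information.

Rhythm is quantified as modulation depth in three nested timescales — delta
(0.9-2.5 Hz, prosodic), theta (2.5-12 Hz, syllabic), beta/gamma (12-40 Hz,
sub-syllabic). Harmonic coupling between neighboring rhythms is quantified by
the n:m phase synchronization index; waveform regularity by the density of a
natural visibility graph on a local-SD transform; intonation by the spread of
the F0 contour estimated with normalized cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt, welch

RHYTHM_BANDS = {"delta": (0.9, 2.5), "theta": (2.5, 12.0), "beta.gamma": (12.0, 40.0)}
CRITICAL_BANDS = {
    "100_300": (100.0, 300.0),
    "300_800": (300.0, 800.0),
    "1000_3000": (1000.0, 3000.0),
    "3000_8000": (3000.0, 8000.0),
}
BAND_NAMES = list(CRITICAL_BANDS)
RHYTHM_NAMES = list(RHYTHM_BANDS)
PSI_RATIOS = {"delta_theta": (2, 1), "theta_beta.gamma": (3, 1)}


def erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """Frequency (Hz) to ERB-rate (Cams)."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f, dtype=float))


def erb_rate_inv(e: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 0.00437


@dataclass
class EnvelopeBank:
    """Narrow-band Hilbert envelopes sampled at ``env_rate`` Hz."""

    envelopes: np.ndarray  # (n_channels, T), non-negative
    center_freqs: np.ndarray  # Hz, strictly increasing
    env_rate: float = 100.0


def erb_channel_edges(n_channels: int = 28, fmin: float = 100.0, fmax: float = 10000.0) -> np.ndarray:
    """n_channels+1 contiguous band edges equally spaced on the ERB-rate scale."""
    return np.asarray(erb_rate_inv(np.linspace(erb_rate(fmin), erb_rate(fmax), n_channels + 1)))


def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 2):
    nyq = fs / 2.0
    lo_n = max(lo / nyq, 1e-5)
    hi_n = min(hi / nyq, 0.999)
    return butter(order, [lo_n, hi_n], btype="bandpass", output="sos")


def cochlear_filterbank(
    samples: np.ndarray,
    rate: float,
    n_channels: int = 28,
    fmin: float = 100.0,
    fmax: float = 10000.0,
    env_rate: float = 100.0,
) -> EnvelopeBank:
    """Decompose pause-excised speech into narrow-band Hilbert envelopes.

    Channels are zero-phase Butterworth band-passes with contiguous edges on
    the ERB-rate map. Envelopes are downsampled to ``env_rate`` and smoothed
    with a second-order zero-lag Butterworth low-pass at 40 Hz.
    """
    x = np.asarray(samples, dtype=np.float64)
    if len(x) < 0.1 * rate:
        raise ValueError("input shorter than 100 ms")
    edges = erb_channel_edges(n_channels, fmin, fmax)
    centers = np.asarray(erb_rate_inv((erb_rate(edges[:-1]) + erb_rate(edges[1:])) / 2.0))
    nfast = next_fast_len(len(x))
    from fractions import Fraction

    frac = Fraction(int(round(env_rate)), int(round(rate))).limit_denominator(10000)
    sos_lp = butter(2, 40.0 / (env_rate / 2.0), btype="low", output="sos")
    envs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        band = sosfiltfilt(_bandpass_sos(lo, hi, rate), x)
        env = np.abs(hilbert(band, N=nfast)[: len(x)])
        env_ds = resample_poly(env, frac.numerator, frac.denominator)
        env_sm = sosfiltfilt(sos_lp, env_ds)
        envs.append(np.maximum(env_sm, 0.0))
    return EnvelopeBank(envelopes=np.vstack(envs), center_freqs=centers, env_rate=env_rate)


def rate_normalize(bank: EnvelopeBank, ar: float, ar_norm: float) -> EnvelopeBank:
    """Linear time-scaling of the envelope bank by articulation rate.

    Duration is scaled by ``ar / ar_norm``: a slower-than-norm speaker
    (ar < ar_norm) is compressed in time so that their modulation rhythms
    shift up toward normative rates (a 4 Hz rhythm at half the normative rate
    becomes 8 Hz after normalization).
    """
    if not (np.isfinite(ar) and np.isfinite(ar_norm)) or ar <= 0 or ar_norm <= 0:
        raise ValueError("articulation rates must be positive and finite")
    if ar == ar_norm:
        return bank
    T = bank.envelopes.shape[1]
    new_T = max(2, int(round(T * ar / ar_norm)))
    t_old = np.arange(T)
    t_new = np.linspace(0, T - 1, new_T)
    scaled = np.vstack([np.interp(t_new, t_old, env) for env in bank.envelopes])
    return replace(bank, envelopes=scaled)


def aggregate_critical_bands(bank: EnvelopeBank) -> dict[str, np.ndarray]:
    """Sum narrow-band envelopes into the four critical bands.

    Channels whose center frequency falls in the 800-1,000 Hz or
    8,000-10,000 Hz gaps belong to no critical band and are dropped.
    """
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in CRITICAL_BANDS.items():
        mask = (bank.center_freqs >= lo) & (bank.center_freqs <= hi)
        if not mask.any():
            raise ValueError(f"no channels inside critical band {name}")
        out[name] = bank.envelopes[mask].sum(axis=0)
    return out


def modulation_depth(
    critical_envelopes: dict[str, np.ndarray],
    env_rate: float = 100.0,
    nfft: int = 2048,
) -> dict[str, float]:
    """Fraction of envelope modulation power in each rhythm range.

    Power spectra use a Hamming-windowed 2,048-point FFT (Welch averaging for
    longer envelopes). The denominator is total non-DC power up to the
    envelope Nyquist; the DC bin is excluded so that the constant envelope
    level does not dominate.
    """
    out: dict[str, float] = {}
    for band, env in critical_envelopes.items():
        env = np.asarray(env, dtype=np.float64)
        y = env - env.mean()
        if len(y) < 4 or not np.any(y):
            for rhythm in RHYTHM_NAMES:
                out[f"hbenvlp_mod_depth_{rhythm}_{band}"] = 0.0
            continue
        nperseg = min(len(y), nfft)
        freqs, power = welch(
            y, fs=env_rate, window="hamming", nperseg=nperseg, nfft=nfft,
            noverlap=nperseg // 2, detrend=False,
        )
        nonzero = freqs > 0
        total = power[nonzero].sum()
        for rhythm, (lo, hi) in RHYTHM_BANDS.items():
            mask = (freqs >= lo) & (freqs < hi)
            depth = float(power[mask].sum() / total) if total > 0 else 0.0
            out[f"hbenvlp_mod_depth_{rhythm}_{band}"] = depth
    return out


def psi(phase1: np.ndarray, phase2: np.ndarray, n: int, m: int) -> float:
    """n:m phase synchronization index.

    PSI = |time average of exp(i(n*phi1 - m*phi2))| in [0, 1], where phi1 is
    the slower rhythm's instantaneous phase. 1 means perfect harmonic
    coupling; a random phase relation gives ~N^(-1/2).
    """
    phase1 = np.asarray(phase1, dtype=np.float64)
    phase2 = np.asarray(phase2, dtype=np.float64)
    if phase1.shape != phase2.shape:
        raise ValueError("phase series must have equal length")
    if phase1.size < 100:
        raise ValueError("phase series too short (< 100 samples)")
    return float(np.abs(np.mean(np.exp(1j * (n * phase1 - m * phase2)))))


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    return np.angle(hilbert(np.asarray(x, dtype=np.float64)))


def psi_features(bank: EnvelopeBank) -> dict[str, float]:
    """Eight n:m PSI features from a rate-normalized envelope bank.

    Each narrow-band envelope is band-pass filtered at the three rhythm
    ranges (zero-lag Butterworth); the filtered oscillations are summed into
    the four critical bands per rhythm, and PSI is computed between matched
    critical-band signals at neighboring rhythms with ratios 2:1
    (delta-theta) and 3:1 (theta-beta/gamma).
    """
    fs = bank.env_rate
    sos = {r: _bandpass_sos(lo, hi, fs) for r, (lo, hi) in RHYTHM_BANDS.items()}
    agg: dict[tuple[str, str], np.ndarray] = {}
    for band, (lo, hi) in CRITICAL_BANDS.items():
        mask = (bank.center_freqs >= lo) & (bank.center_freqs <= hi)
        sub = bank.envelopes[mask]
        for rhythm in RHYTHM_NAMES:
            filt = sosfiltfilt(sos[rhythm], sub, axis=1)
            agg[(band, rhythm)] = filt.sum(axis=0)
    out: dict[str, float] = {}
    for band in BAND_NAMES:
        phases = {r: instantaneous_phase(agg[(band, r)]) for r in RHYTHM_NAMES}
        out[f"hbenvlp_PSI_delta_theta_{band}"] = psi(phases["delta"], phases["theta"], 2, 1)
        out[f"hbenvlp_PSI_theta_beta.gamma_{band}"] = psi(
            phases["theta"], phases["beta.gamma"], 3, 1
        )
    return out


def local_sd_series(samples: np.ndarray, rate: float, L_ms: float = 10.0) -> np.ndarray:
    """Local standard-deviation transform over non-overlapping windows.

    Windows hold ``L`` samples (10 ms by default); each value is the sample
    SD (denominator L-1) of its window. Output length is floor(N/L).
    """
    x = np.asarray(samples, dtype=np.float64)
    L = max(2, int(round(L_ms / 1000.0 * rate)))
    if len(x) < L:
        raise ValueError("waveform shorter than one window")
    M = len(x) // L
    return x[: M * L].reshape(M, L).std(axis=1, ddof=1)


def visibility_density(series: np.ndarray) -> float:
    """Density of the natural visibility graph of a series.

    Nodes x < y are joined iff the straight line between (x, V_x) and
    (y, V_y) passes strictly above every intermediate point; adjacent nodes
    are always joined (no intermediate exists). Density = 2m / (M(M-1)).
    A strictly convex series is fully connected (density 1); an exactly
    collinear series keeps only adjacent edges (density 2/M).
    """
    V = np.asarray(series, dtype=np.float64)
    M = len(V)
    if M < 2:
        raise ValueError("need at least 2 nodes")
    edges = M - 1  # adjacent nodes always visible
    for x in range(M - 2):
        slopes = (V[x + 1 :] - V[x]) / np.arange(1, M - x)
        # y is visible from x iff its slope strictly exceeds every earlier slope
        running_max = np.maximum.accumulate(slopes[:-1])
        edges += int(np.count_nonzero(slopes[1:] > running_max))
    return 2.0 * edges / (M * (M - 1))


def f0_contour(
    samples: np.ndarray,
    rate: float,
    sex: str,
    *,
    window_ms: dict[str, float] | None = None,
    pitch_range: dict[str, tuple[float, float]] | None = None,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.6,
) -> dict:
    """F0 contour by normalized cross-correlation, and its spread statistics.

    The correlation window is 20 ms for male and 10 ms for female speakers;
    pitch search ranges default to 60-300 Hz (male) and 100-500 Hz (female).
    Frames whose peak normalized correlation falls below the voicing
    threshold are excluded; ``sdevF0`` and ``iqrF0`` are computed over voiced
    frames only. With no voiced frames the statistics are NaN and
    ``voiced`` is False (callers impute 0 with a flag).
    """
    window_ms = window_ms or {"male": 20.0, "female": 10.0}
    pitch_range = pitch_range or {"male": (60.0, 300.0), "female": (100.0, 500.0)}
    sex = str(sex).lower()
    if sex not in window_ms:
        raise ValueError(f"unknown sex {sex!r}")
    floor, ceiling = pitch_range[sex]
    w = int(round(window_ms[sex] / 1000.0 * rate))
    lag_min = max(2, int(np.floor(rate / ceiling)))
    lag_max = int(np.ceil(rate / floor))
    hop = max(1, int(round(hop_s * rate)))
    x = np.asarray(samples, dtype=np.float64)
    frame_len = w + lag_max
    n_frames = (len(x) - frame_len) // hop + 1 if len(x) >= frame_len else 0
    if n_frames <= 0:
        return {"f0": np.array([]), "sdevF0": np.nan, "iqrF0": np.nan, "voiced": False,
                "voiced_fraction": 0.0}
    idx = np.arange(n_frames)[:, None] * hop + np.arange(frame_len)[None, :]
    F = x[idx]  # (n_frames, frame_len)
    A = np.zeros_like(F)
    A[:, :w] = F[:, :w]
    nfft = next_fast_len(2 * frame_len)
    # numerator(lag) = sum_i F[i] F[i+lag] over the first w samples
    num = np.fft.irfft(np.conj(np.fft.rfft(A, nfft)) * np.fft.rfft(F, nfft), nfft)[:, : lag_max + 1]
    e_cum = np.concatenate(
        [np.zeros((n_frames, 1)), np.cumsum(F**2, axis=1)], axis=1
    )
    e0 = e_cum[:, w] - e_cum[:, 0]
    lags = np.arange(lag_min, lag_max + 1)
    e_lag = e_cum[:, lags + w] - e_cum[:, lags]
    denom = np.sqrt(np.maximum(e0[:, None] * e_lag, 1e-300))
    r = num[:, lags] / denom
    silent = e0 < 1e-10 * w
    r[silent] = 0.0
    best = np.max(r, axis=1)
    best_i = np.argmax(r, axis=1)
    f0 = np.full(n_frames, np.nan)
    voiced = best >= voicing_threshold
    for i in np.flatnonzero(voiced):
        j = int(best_i[i])
        # subharmonic guard: if a submultiple of the period is nearly as
        # periodic, the peak is an octave-down error — take the shorter period
        for div in (3, 2):
            j_sub = int(round((lags[j] / div - lag_min)))
            if 0 <= j_sub < len(lags):
                lo, hi = max(0, j_sub - 1), min(len(lags), j_sub + 2)
                if np.max(r[i, lo:hi]) >= 0.90 * r[i, j]:
                    j = lo + int(np.argmax(r[i, lo:hi]))
        lag = float(lags[j])
        if 0 < j < len(lags) - 1:  # parabolic interpolation
            y0, y1, y2 = r[i, j - 1], r[i, j], r[i, j + 1]
            denom_p = y0 - 2 * y1 + y2
            if denom_p < 0:
                lag += 0.5 * (y0 - y2) / denom_p
        f0[i] = rate / lag
    f0_voiced = f0[voiced]
    if f0_voiced.size == 0:
        return {"f0": f0, "sdevF0": np.nan, "iqrF0": np.nan, "voiced": False,
                "voiced_fraction": 0.0}
    sdev = float(np.std(f0_voiced, ddof=1)) if f0_voiced.size > 1 else 0.0
    iqr = float(np.percentile(f0_voiced, 75) - np.percentile(f0_voiced, 25))
    return {
        "f0": f0,
        "sdevF0": sdev,
        "iqrF0": iqr,
        "voiced": True,
        "voiced_fraction": float(voiced.mean()),
    }
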