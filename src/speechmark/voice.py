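"""Voice quality: cepstral peak prominence (CPP).

CPP quantifies the dominance of periodic (harmonic) energy over aperiodic
energy. Per analysis frame the real cepstrum — the inverse Fourier transform
of the dB log power spectrum — is searched for its most prominent peak in the
quefrency band corresponding to plausible vocal F0; the peak height is taken
relative to a linear regression line fitted to the cepstral envelope. Low CPP
indicates breathy/rough/hoarse (dysphonic) voice.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len


def cpp(
    samples: np.ndarray,
    rate: float,
    frame_ms: float = 40.0,
    hop_ms: float = 20.0,
    qmin_hz: float = 60.0,
    qmax_hz: float = 330.0,
) -> dict[str, float]:
    """Frame-averaged cepstral peak prominence in dB.

    The quefrency peak is searched between 1/qmax_hz and 1/qmin_hz seconds
    (the plausible pitch-period range); the regression line is fitted from
    1 ms up to the low-pitch quefrency bound. Returns ``CPP`` (dB, mean over
    frames) and ``peak_quefrency`` (s, mean over frames).
    """
    x = np.asarray(samples, dtype=np.float64)
    frame_len = int(round(frame_ms / 1000.0 * rate))
    hop = int(round(hop_ms / 1000.0 * rate))
    if len(x) < frame_len:
        raise ValueError("input shorter than one analysis frame")
    n_frames = (len(x) - frame_len) // hop + 1
    idx = np.arange(n_frames)[:, None] * hop + np.arange(frame_len)[None, :]
    frames = x[idx] * np.hamming(frame_len)[None, :]
    nfft = next_fast_len(2 * frame_len)
    log_power = 10.0 * np.log10(np.abs(np.fft.rfft(frames, nfft)) ** 2 + 1e-12)
    cepstra = np.fft.irfft(log_power, nfft)  # real cepstrum, dB units

    quefrency = np.arange(nfft // 2 + 1) / rate
    q_lo, q_hi = 1.0 / qmax_hz, 1.0 / qmin_hz
    peak_band = (quefrency >= q_lo) & (quefrency <= q_hi)
    reg_band = (quefrency >= 0.001) & (quefrency <= q_hi)
    q_reg = quefrency[reg_band]

    cpps = np.empty(n_frames)
    peaks_q = np.empty(n_frames)
    half = cepstra[:, : nfft // 2 + 1]
    for i in range(n_frames):
        c = half[i]
        j = np.argmax(c[peak_band])
        q_peak = quefrency[peak_band][j]
        slope, intercept = np.polyfit(q_reg, c[reg_band], 1)
        cpps[i] = c[peak_band][j] - (slope * q_peak + intercept)
        peaks_q[i] = q_peak
    return {"CPP": float(cpps.mean()), "peak_quefrency": float(peaks_q.mean())}
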