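import numpy as np
import pytest

from speechmark import complexity
from tests.conftest import RATE, tone


def brute_force_determinism(u, m=3, tau=5, eps=0.2, lmin=2):
    """O(N^2) recurrence/diagonal-count oracle (z-normalized series)."""
    u = np.asarray(u, dtype=float)
    sd = u.std()
    u = (u - u.mean()) / sd if sd > 1e-12 else np.zeros_like(u)
    nv = len(u) - (m - 1) * tau
    X = np.array([[u[i + j * tau] for j in range(m)] for i in range(nv)])
    R = np.zeros((nv, nv), dtype=bool)
    for i in range(nv):
        for j in range(nv):
            R[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum()) <= eps
    total = on_lines = 0
    for d in range(1, nv):
        diag = [R[i, i + d] for i in range(nv - d)]
        total += sum(diag)
        run = 0
        for v in diag + [False]:
            if v:
                run += 1
            else:
                if run >= lmin:
                    on_lines += run
                run = 0
    return on_lines / total if total else 0.0


class TestEntropy:
    def test_single_coefficient_has_zero_entropy(self):
        assert complexity.shannon_entropy(np.array([0.0, 3.7, 0.0])) == pytest.approx(0.0)

    def test_uniform_energy_reaches_log_n(self):
        for n in (4, 16, 100):
            assert complexity.shannon_entropy(np.full(n, 0.5)) == pytest.approx(np.log(n))

    def test_wpd_has_eight_nodes_and_respects_bound(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(int(rng.uniform(1, 2) * RATE))
            out = complexity.wpd_entropy(x)
            assert set(out) == {f"ShanEn_{i}" for i in range(1, 9)}
            n_coeff = len(x) // 8 + 10
            assert all(0.0 <= v <= np.log(n_coeff) + 0.1 for v in out.values())

    def test_tone_vs_noise_entropy_ordering_per_node(self):
        # 500 Hz lies in the lowest depth-3 node (0 - fs/16). Within that
        # node, a constant-amplitude tone spreads its energy uniformly over
        # the time coefficients (entropy near the log-n bound), while iid
        # noise sits ~0.42 nats below it; in nodes the tone does not excite,
        # noise entropy dominates.
        e_tone = complexity.wpd_entropy(tone(500, 1.0))
        for seed in range(20):
            noise = np.random.default_rng(seed).standard_normal(RATE)
            e_noise = complexity.wpd_entropy(noise / np.abs(noise).max())
            assert e_tone["ShanEn_1"] > e_noise["ShanEn_1"]
            assert e_noise["ShanEn_5"] > e_tone["ShanEn_5"]

    def test_silence_flagged_as_zero(self):
        out = complexity.wpd_entropy(np.zeros(RATE))
        assert all(v == 0.0 for v in out.values())


class TestDeltaMFCC:
    def test_stationary_tone_has_near_zero_deltas(self):
        d = complexity.delta_mfcc(tone(440, 2.0), RATE)
        assert d.shape[0] == 13
        interior = d[:, 10:-10]
        assert np.max(np.abs(interior)) < 0.05 * np.max(np.abs(complexity.mfcc(tone(440, 2.0), RATE)))

    def test_deltas_2_to_13_invariant_to_gain(self):
        x = np.random.default_rng(1).standard_normal(2 * RATE)
        d1 = complexity.delta_mfcc(x, RATE)
        d2 = complexity.delta_mfcc(2.0 * x, RATE)
        assert np.allclose(d1[1:], d2[1:], atol=1e-8)

    def test_alternating_spectra_produce_periodic_deltas(self):
        # switch between two band-limited noises at 2 Hz
        rng = np.random.default_rng(2)
        from scipy.signal import butter, sosfiltfilt

        n = 4 * RATE
        lo = sosfiltfilt(butter(4, [300 / (RATE / 2), 800 / (RATE / 2)], "bandpass", output="sos"),
                         rng.standard_normal(n))
        hi = sosfiltfilt(butter(4, [2000 / (RATE / 2), 4000 / (RATE / 2)], "bandpass", output="sos"),
                         rng.standard_normal(n))
        gate = (np.sin(2 * np.pi * 2.0 * np.arange(n) / RATE) > 0).astype(float)
        x = lo * gate + hi * (1 - gate)
        d = complexity.delta_mfcc(x / np.abs(x).max(), RATE)
        series = d[1] - d[1].mean()
        freqs = np.fft.rfftfreq(len(series), 0.010)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(series)))]
        assert peak == pytest.approx(2.0, abs=freqs[1] + 0.01)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            complexity.delta_mfcc(np.zeros(RATE // 2), RATE)


class TestRQA:
    def test_sinusoid_is_highly_deterministic(self):
        t = np.arange(500)
        assert complexity.rqa_determinism(np.sin(2 * np.pi * t / 100)) >= 0.95

    def test_gaussian_noise_rarely_deterministic(self):
        dets = [complexity.rqa_determinism(np.random.default_rng(s).standard_normal(500))
                for s in range(20)]
        assert sum(d < 0.5 for d in dets) >= 19

    def test_constant_series_fully_recurrent(self):
        assert complexity.rqa_determinism(np.zeros(200)) == pytest.approx(1.0, abs=1e-3)

    def test_matches_brute_force_oracle_exactly(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            u = rng.standard_normal(120) * rng.uniform(0.5, 3.0)
            assert complexity.rqa_determinism(u) == pytest.approx(
                brute_force_determinism(u), abs=1e-12
            )

    def test_recurrence_matrix_symmetric(self):
        R = complexity.recurrence_matrix(np.random.default_rng(0).standard_normal(150))
        assert np.array_equal(R, R.T)
        assert R.dtype == bool

    def test_determinism_invariant_to_amplitude(self):
        u = np.random.default_rng(5).standard_normal(300)
        assert complexity.rqa_determinism(u) == complexity.rqa_determinism(10 * u)


class TestDeterminismFeatures:
    def test_thirteen_bounded_features(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal((13, 250))
        out = complexity.determinism_features(d)
        assert set(out) == {f"DET_dmfcc_{i}" for i in range(1, 14)}
        assert all(0.0 <= v <= 1.0 for v in out.values())

    def test_periodic_surrogate_more_deterministic_than_noise(self):
        t = np.arange(300)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            periodic = np.sin(2 * np.pi * t[None, :] / 60 + rng.uniform(0, 6, (13, 1)))
            noise = rng.standard_normal((13, 300))
            dp = complexity.determinism_features(periodic)
            dn = complexity.determinism_features(noise)
            wins += all(dp[k] > dn[k] for k in dp)
        assert wins >= 9

    def test_constant_delta_series_is_fully_deterministic(self):
        out = complexity.determinism_features(np.zeros((13, 200)))
        assert all(v == pytest.approx(1.0, abs=1e-3) for v in out.values())

    def test_needs_one_full_segment(self):
        with pytest.raises(ValueError):
            complexity.determinism_features(np.zeros((13, 50)))
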