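import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechmark import prosody
from tests.conftest import RATE, sawtooth, tone


def brute_force_visibility(V):
    """O(M^3) all-pairs natural-visibility oracle (strict inequality)."""
    M = len(V)
    edges = 0
    for x in range(M):
        for y in range(x + 1, M):
            if all(
                (V[y] - V[z]) / (y - z) > (V[y] - V[x]) / (y - x)
                for z in range(x + 1, y)
            ):
                edges += 1
    return 2.0 * edges / (M * (M - 1))


class TestFilterbank:
    def test_pure_tone_energy_concentrates_in_one_channel(self):
        bank = prosody.cochlear_filterbank(tone(1000, 3.0), RATE)
        assert bank.envelopes.shape[0] == 28
        energy = (bank.envelopes**2).sum(axis=1)
        top = np.argmax(energy)
        assert energy[top] / energy.sum() > 0.9
        # center frequency of the winning channel is the one nearest 1 kHz
        assert top == np.argmin(np.abs(bank.center_freqs - 1000))

    def test_white_noise_excites_all_channels(self):
        x = np.random.default_rng(0).standard_normal(3 * RATE)
        bank = prosody.cochlear_filterbank(x / np.abs(x).max(), RATE)
        assert np.all(bank.envelopes.mean(axis=1) > 0)

    def test_silence_gives_null_envelopes(self):
        bank = prosody.cochlear_filterbank(np.zeros(RATE), RATE)
        assert np.all(bank.envelopes < 1e-6)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            prosody.cochlear_filterbank(np.zeros(100), RATE)


class TestRateNormalize:
    def _bank(self, env):
        env2 = np.atleast_2d(env)
        return prosody.EnvelopeBank(envelopes=env2, center_freqs=np.array([200.0] * len(env2)))

    def test_identity_when_rate_matches_norm(self):
        env = 1 + 0.5 * np.sin(2 * np.pi * 4 * np.arange(1000) / 100)
        out = prosody.rate_normalize(self._bank(env), 150.0, 150.0)
        assert np.allclose(out.envelopes[0], env, atol=1e-9)

    def test_slow_speaker_compressed_so_rhythm_doubles(self):
        T = 3000
        env = 1 + 0.5 * np.sin(2 * np.pi * 4 * np.arange(T) / 100)
        out = prosody.rate_normalize(self._bank(env), ar=80.0, ar_norm=160.0)
        assert out.envelopes.shape[1] == round(T * 80.0 / 160.0)
        y = out.envelopes[0] - out.envelopes[0].mean()
        freqs = np.fft.rfftfreq(len(y), 1 / 100)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(y)))]
        assert abs(peak - 8.0) <= freqs[1]

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            prosody.rate_normalize(self._bank(np.ones(200)), 0.0, 150.0)


class TestCriticalBands:
    def test_tone_energy_lands_in_containing_band(self):
        bank = prosody.cochlear_filterbank(tone(2000, 2.0), RATE)
        crit = prosody.aggregate_critical_bands(bank)
        energies = {k: float((v**2).sum()) for k, v in crit.items()}
        assert energies["1000_3000"] / sum(energies.values()) > 0.9

    def test_two_tones_split_between_extreme_bands(self):
        x = tone(200, 2.0) + tone(5000, 2.0)
        crit = prosody.aggregate_critical_bands(
            prosody.cochlear_filterbank(x / np.abs(x).max(), RATE)
        )
        energies = {k: float((v**2).sum()) for k, v in crit.items()}
        total = sum(energies.values())
        assert energies["100_300"] / total > 0.2
        assert energies["3000_8000"] / total > 0.2
        assert (energies["100_300"] + energies["3000_8000"]) / total > 0.9

    def test_silence_gives_zero_envelopes(self):
        crit = prosody.aggregate_critical_bands(
            prosody.cochlear_filterbank(np.zeros(RATE), RATE)
        )
        for env in crit.values():
            assert np.all(env < 1e-6)


class TestModulationDepth:
    def test_single_line_in_theta_band(self):
        t = np.arange(3000) / 100
        d = prosody.modulation_depth({"100_300": 1 + 0.5 * np.sin(2 * np.pi * 4 * t)})
        assert d["hbenvlp_mod_depth_theta_100_300"] > 0.95
        assert d["hbenvlp_mod_depth_delta_100_300"] < 0.05
        assert d["hbenvlp_mod_depth_beta.gamma_100_300"] < 0.05

    def test_single_line_in_delta_band(self):
        t = np.arange(3000) / 100
        d = prosody.modulation_depth({"100_300": 1 + 0.5 * np.sin(2 * np.pi * 1.5 * t)})
        assert d["hbenvlp_mod_depth_delta_100_300"] > 0.95

    def test_constant_envelope_has_zero_depth(self):
        d = prosody.modulation_depth({"100_300": np.ones(1000)})
        assert all(v == 0.0 for v in d.values())


class TestPSI:
    def test_exact_harmonic_locking_gives_one(self):
        rng = np.random.default_rng(0)
        phi1 = np.cumsum(rng.uniform(0, 0.1, 10000))
        assert prosody.psi(phi1, 2 * phi1 + 1.3, 2, 1) == pytest.approx(1.0)
        assert prosody.psi(phi1, phi1, 1, 1) == pytest.approx(1.0)

    def test_random_phase_null_is_small(self):
        vals = [
            prosody.psi(
                np.random.default_rng(s).uniform(0, 2 * np.pi, 10000),
                np.random.default_rng(1000 + s).uniform(0, 2 * np.pi, 10000),
                2, 1,
            )
            for s in range(50)
        ]
        assert sum(v < 0.05 for v in vals) >= 49

    def test_length_preconditions(self):
        with pytest.raises(ValueError):
            prosody.psi(np.zeros(50), np.zeros(50), 2, 1)
        with pytest.raises(ValueError):
            prosody.psi(np.zeros(200), np.zeros(100), 2, 1)


def _bank_with_band0_envelope(env):
    """EnvelopeBank whose 100-300 Hz channels carry `env`, others tiny noise."""
    edges = prosody.erb_channel_edges()
    centers = prosody.erb_rate_inv(
        (prosody.erb_rate(edges[:-1]) + prosody.erb_rate(edges[1:])) / 2
    )
    rng = np.random.default_rng(9)
    envs = 1e-6 * np.abs(rng.standard_normal((28, len(env))))
    for i, cf in enumerate(centers):
        if 100 <= cf <= 300:
            envs[i] = env
    return prosody.EnvelopeBank(envelopes=envs, center_freqs=np.asarray(centers))


class TestPSIFeatures:
    def test_phase_locked_am_components_synchronize(self):
        t = np.arange(4000) / 100
        env = 1 + 0.4 * np.sin(2 * np.pi * 1.5 * t) + 0.4 * np.sin(2 * np.pi * 3.0 * t + 0.7)
        out = prosody.psi_features(_bank_with_band0_envelope(env))
        assert out["hbenvlp_PSI_delta_theta_100_300"] > 0.9

    def test_drifting_phases_do_not_synchronize(self):
        rng = np.random.default_rng(4)
        t = np.arange(4000) / 100
        drift1 = np.cumsum(rng.normal(0, 0.08, len(t)))
        drift2 = np.cumsum(rng.normal(0, 0.08, len(t)))
        env = (1 + 0.4 * np.sin(2 * np.pi * 1.5 * t + drift1)
               + 0.4 * np.sin(2 * np.pi * 3.3 * t + drift2))
        out = prosody.psi_features(_bank_with_band0_envelope(env))
        assert out["hbenvlp_PSI_delta_theta_100_300"] < 0.2

    def test_eight_features_all_in_unit_interval(self):
        rng = np.random.default_rng(5)
        env = 1 + 0.3 * rng.standard_normal(2000)
        out = prosody.psi_features(_bank_with_band0_envelope(np.abs(env)))
        assert len(out) == 8
        assert all(0.0 <= v <= 1.0 for v in out.values())


def test_depths_and_psi_bounded_on_random_banks():
    """Fuzz: all 12 modulation depths and 8 PSI values stay in [0, 1]."""
    edges = prosody.erb_channel_edges()
    centers = np.asarray(prosody.erb_rate_inv(
        (prosody.erb_rate(edges[:-1]) + prosody.erb_rate(edges[1:])) / 2
    ))
    for seed in range(200):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(250, 600))
        envs = np.abs(rng.standard_normal((28, T))) * rng.uniform(0, 2, (28, 1))
        bank = prosody.EnvelopeBank(envelopes=envs, center_freqs=centers)
        depths = prosody.modulation_depth(prosody.aggregate_critical_bands(bank))
        assert all(0.0 <= v <= 1.0 for v in depths.values())
        if seed < 30:  # PSI needs the hilbert/filter chain; subsample for runtime
            psis = prosody.psi_features(bank)
            assert all(0.0 <= v <= 1.0 for v in psis.values())


class TestLocalSD:
    def test_constant_waveform_gives_zeros(self):
        V = prosody.local_sd_series(np.ones(2200), RATE)
        assert np.allclose(V, 0.0)

    def test_alternating_window_closed_form(self):
        L = int(round(0.010 * RATE))  # 220 samples
        x = np.concatenate([np.ones(L), np.tile([1.0, -1.0], L // 2)])
        V = prosody.local_sd_series(x, RATE)
        assert V[0] == pytest.approx(0.0)
        assert V[1] == pytest.approx(np.sqrt(L / (L - 1)), abs=1e-9)  # ~1.0023 for L=220

    def test_length_is_floor_n_over_l(self):
        V = prosody.local_sd_series(np.random.default_rng(0).standard_normal(5000), RATE)
        assert len(V) == 5000 // int(round(0.010 * RATE))


class TestVisibilityDensity:
    def test_two_nodes_fully_connected(self):
        assert prosody.visibility_density(np.array([1.0, 5.0])) == 1.0

    def test_strictly_convex_series_fully_connected(self):
        assert prosody.visibility_density(np.arange(20.0) ** 2) == pytest.approx(1.0)

    def test_collinear_series_keeps_only_adjacent_edges(self):
        assert prosody.visibility_density(3 * np.arange(20.0) + 1) == pytest.approx(0.1)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            prosody.visibility_density(np.array([1.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=5, max_value=60))
    def test_matches_brute_force_oracle(self, seed, M):
        V = np.random.default_rng(seed).standard_normal(M)
        assert prosody.visibility_density(V) == pytest.approx(brute_force_visibility(V))


class TestF0:
    def test_constant_sawtooth_pitch(self):
        r = prosody.f0_contour(sawtooth(150, 3.0), RATE, "male")
        f0 = r["f0"][~np.isnan(r["f0"])]
        assert np.median(f0) == pytest.approx(150, abs=2)
        assert r["sdevF0"] < 2.0
        assert r["iqrF0"] < 2.0

    def test_linear_glide_iqr_is_half_range(self):
        t = np.arange(3 * RATE) / RATE
        phase = np.cumsum(120 + 40 * t) / RATE  # 120 -> 240 Hz over 3 s
        r = prosody.f0_contour(2 * (phase % 1.0) - 1, RATE, "male")
        assert r["iqrF0"] == pytest.approx(60, abs=6)

    def test_white_noise_has_no_voiced_frames(self):
        x = np.random.default_rng(2).standard_normal(2 * RATE)
        r = prosody.f0_contour(x / np.abs(x).max(), RATE, "male")
        assert not r["voiced"]

    def test_statistics_invariant_to_amplitude_scaling(self):
        x = sawtooth(180, 2.0)
        a = prosody.f0_contour(x, RATE, "male")
        b = prosody.f0_contour(0.05 * x, RATE, "male")
        assert a["sdevF0"] == pytest.approx(b["sdevF0"])
        assert a["iqrF0"] == pytest.approx(b["iqrF0"])

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            prosody.f0_contour(sawtooth(150, 1.0), RATE, "other")
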