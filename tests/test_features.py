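"""Feature battery: closed forms, independent oracles, scaling laws, count."""

import math

import numpy as np
import pytest

from emofuse.data_model import WindowedDataset
from emofuse.features import (
    ALPHA,
    BETA,
    GAMMA,
    FeatureRecipe,
    FeatureTable,
    approximate_entropy,
    band_energy,
    band_ratio,
    bandpass,
    differential_entropy,
    extract_all,
    higuchi_fd,
    hjorth,
    hurst_rs,
    lyapunov_max,
    power_sum,
    rasm,
    relative_energy_entropy,
    sample_entropy,
    time_domain_stats,
    wavelet_entropy,
)

FS = 128.0
T = np.arange(1280)


def tone(freq, n=1280, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


# ---------------------------------------------------------------------------
# naive oracles, independent of the package's compiled kernels
# ---------------------------------------------------------------------------

def naive_sampen(x, m, r):
    n = len(x)
    def matches(length, exclude_self):
        cnt = 0
        for i in range(n - m):
            for j in range(n - m):
                if exclude_self and i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    cnt += 1
        return cnt
    b = matches(m, True)
    a = matches(m + 1, True)
    return -math.log(a / b)


def naive_apen(x, m, r):
    n = len(x)
    def phi(mm):
        total = 0.0
        nt = n - mm + 1
        for i in range(nt):
            c = sum(
                1 for j in range(nt)
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r
            )
            total += math.log(c / nt)
        return total / nt
    return phi(m) - phi(m + 1)


class TestTimeDomain:
    def test_arithmetic_progression(self):
        mu, sd, d1, d2 = time_domain_stats([1, 2, 3, 4])
        assert mu == 2.5 and d1 == 1.0
        assert d2 == pytest.approx(2.0)  # lag-2 gaps of an arithmetic ramp

    def test_constant(self):
        assert time_domain_stats([3.0] * 10) == (3.0, 0.0, 0.0, 0.0)

    def test_hand_example(self):
        _, _, d1, d2 = time_domain_stats([0, 2, 1])
        assert d1 == pytest.approx(1.5)
        assert d2 == pytest.approx(1.0)

    def test_population_std(self):
        _, sd, _, _ = time_domain_stats([1.0, 2.0, 3.0])
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_too_short(self):
        with pytest.raises(ValueError):
            time_domain_stats([1, 2])


class TestBandpass:
    def test_passband_tone_preserved(self):
        x = tone(10.0)
        y = bandpass(x, ALPHA, FS)
        ratio = np.sqrt(np.mean(y**2) / np.mean(x**2))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_tone_suppressed(self):
        x = tone(50.0)
        y = bandpass(x, ALPHA, FS)
        assert np.sqrt(np.mean(y**2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(bandpass(np.zeros(1280), BETA, FS), 0.0)

    def test_band_above_nyquist_rejected(self):
        from emofuse.features import BandDefinition

        with pytest.raises(ValueError):
            bandpass(tone(10), BandDefinition("hi", 50.0, 70.0), FS)


class TestBandEnergy:
    def test_zero_signal(self):
        assert band_energy(np.zeros(1280), ALPHA, FS) == 0.0

    def test_unit_tone_parseval(self):
        # sum of squares of a unit sine over 1280 samples = T/2
        e = band_energy(tone(10.0), ALPHA, FS)
        assert e == pytest.approx(640.0, rel=0.05)

    def test_band_energies_bounded_by_total(self, rng):
        x = rng.standard_normal(1280)
        total = float(np.sum(x**2))
        assert sum(band_energy(x, b, FS) for b in (ALPHA, BETA, GAMMA)) <= total

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.standard_normal(1280)
        assert band_energy(2 * x, ALPHA, FS) == pytest.approx(
            4 * band_energy(x, ALPHA, FS))


class TestRatioFeatures:
    @pytest.mark.parametrize("pl,pr,expect", [(2.0, 2.0, 1.0), (3.0, 1.5, 2.0)])
    def test_rasm_values(self, pl, pr, expect):
        assert rasm(pl, pr) == pytest.approx(expect)

    def test_rasm_guard(self):
        assert rasm(1.0, 0.0) > 1e6  # floored denominator, finite

    def test_beta_alpha_ratio_tones(self):
        assert band_ratio(tone(10.0), FS) < 0.05
        assert band_ratio(tone(20.0), FS) > 20
        mix = tone(10.0) + tone(20.0)
        assert band_ratio(mix, FS) == pytest.approx(1.0, abs=0.1)

    def test_power_sum(self):
        w = np.zeros((3, 1280))
        assert power_sum(w) == 0.0
        w[1] = tone(10.0)
        assert power_sum(w) == pytest.approx(0.5, rel=1e-3)
        assert power_sum(2 * w) == pytest.approx(4 * power_sum(w))


class TestEntropies:
    def test_sampen_constant_is_zero(self):
        assert sample_entropy(np.ones(50)) == 0.0

    def test_sampen_matches_naive_oracle(self):
        x = np.tile([1.0, 2.0, 3.0], 10)
        expected = naive_sampen(list(x), 2, 0.1)
        assert sample_entropy(x, m=2, r=0.1) == pytest.approx(expected)

    def test_sampen_apen_match_naive_on_random_short_series(self, rng):
        for _ in range(3):
            x = rng.standard_normal(50)
            r = 0.6
            assert sample_entropy(x, 2, r) == pytest.approx(naive_sampen(list(x), 2, r))
            assert approximate_entropy(x, 2, r) == pytest.approx(naive_apen(list(x), 2, r))

    def test_regularity_ordering(self, rng):
        noise = rng.standard_normal(1280)
        s = tone(10.0) * noise.std() / tone(10.0).std()
        assert sample_entropy(noise) > sample_entropy(s)

    def test_scale_invariance_with_relative_r(self, rng):
        x = rng.standard_normal(300)
        assert sample_entropy(5 * x) == pytest.approx(sample_entropy(x))
        assert approximate_entropy(5 * x) == pytest.approx(approximate_entropy(x))

    def test_de_closed_forms(self, rng):
        x = rng.standard_normal(100000)
        assert differential_entropy(x) == pytest.approx(
            0.5 * math.log(2 * math.pi * math.e), abs=0.01)
        y = rng.standard_normal(5000)
        assert differential_entropy(2 * y) - differential_entropy(y) == pytest.approx(
            math.log(2), abs=1e-9)

    def test_de_exact_unit_variance(self):
        # variance exactly 1 by construction
        x = np.array([-1.0, 1.0, -1.0, 1.0, -1.0])
        x = x / x.std(ddof=1)
        assert differential_entropy(x) == pytest.approx(1.41894, abs=1e-4)

    def test_wavelet_entropy_closed_forms(self):
        assert relative_energy_entropy(np.array([1.0, 0, 0])) == 0.0
        assert relative_energy_entropy(np.full(5, 0.2)) == pytest.approx(math.log(5))
        assert relative_energy_entropy(np.array([0.5, 0.5])) == pytest.approx(math.log(2))

    def test_wavelet_entropy_bounds(self, rng):
        we = wavelet_entropy(rng.standard_normal(1280))
        assert 0 <= we <= math.log(6)

    def test_wavelet_entropy_zero_energy(self):
        assert wavelet_entropy(np.zeros(1280)) == 0.0


class TestChaosFeatures:
    def test_logistic_map_lyapunov(self):
        x = np.empty(2000)
        x[0] = 0.4
        for i in range(1999):
            x[i + 1] = 4 * x[i] * (1 - x[i])
        lam = lyapunov_max(x, dim=2, delay=1, fit_steps=5)
        assert lam == pytest.approx(math.log(2), rel=0.15)

    def test_periodic_signal_near_zero(self):
        lam = lyapunov_max(tone(10.0))
        assert lam < 0.05  # indistinguishable from zero at the chaotic scale

    def test_constant_guard(self):
        assert lyapunov_max(np.ones(500)) == 0.0

    def test_higuchi_line(self):
        assert higuchi_fd(np.arange(1280.0)) == pytest.approx(1.0, abs=0.05)

    def test_higuchi_noise(self, rng):
        fd = higuchi_fd(rng.standard_normal(1280))
        assert fd == pytest.approx(2.0, abs=0.15)

    def test_higuchi_complexity_ordering(self, rng):
        line = higuchi_fd(np.arange(1280.0))
        sine = higuchi_fd(tone(10.0))
        noise = higuchi_fd(rng.standard_normal(1280))
        assert line < sine < noise

    def test_hurst_iid_band(self):
        vals = [hurst_rs(np.random.default_rng(s).standard_normal(1280))
                for s in range(50)]
        assert 0.45 <= np.mean(vals) <= 0.65

    def test_hurst_persistence_ordering(self):
        g = np.random.default_rng(9)
        iid = g.standard_normal(1280)
        integ = np.cumsum(g.standard_normal(1280))
        anti = np.diff(g.standard_normal(1281))
        h_int, h_iid, h_anti = hurst_rs(integ), hurst_rs(iid), hurst_rs(anti)
        assert h_int > 0.85
        assert h_int > h_iid > h_anti

    def test_hurst_constant_guard(self):
        assert hurst_rs(np.ones(1280)) == 0.5


class TestHjorth:
    def test_mobility_tracks_angular_frequency(self):
        w = 0.1
        x = np.sin(w * np.arange(2000))
        assert hjorth(x)[0] == pytest.approx(w, rel=0.02)

    def test_sine_complexity_near_one(self):
        x = np.sin(0.1 * np.arange(2000))
        assert hjorth(x)[1] == pytest.approx(1.0, abs=0.05)

    def test_spectral_spread_ordering(self, rng):
        noise = rng.standard_normal(1280)
        s = tone(10.0) * noise.std() / tone(10.0).std()
        assert hjorth(noise)[0] > hjorth(s)[0]

    def test_constant_guard(self):
        assert hjorth(np.ones(10)) == (0.0, 0.0)


class TestExtractAll:
    def test_default_recipe_is_249(self):
        recipe = FeatureRecipe()
        assert recipe.n_features == 249
        names = recipe.feature_names()
        assert len(set(names)) == 249

    def test_family_count_arithmetic(self):
        assert FeatureRecipe(families=("time_domain",),
                             channels=("F3",)).n_features == 4
        assert FeatureRecipe(families=("band_energy",)).n_features == 45
        assert FeatureRecipe(families=("nonlinear",)).n_features == 135

    def test_extraction_shape_and_determinism(self, small_windows):
        sub = WindowedDataset(
            windows=small_windows.windows[:2],
            labels=small_windows.labels[:2],
            subject_ids=small_windows.subject_ids[:2],
            trial_ids=small_windows.trial_ids[:2],
            window_index=small_windows.window_index[:2],
            sampling_rate=small_windows.sampling_rate,
            channel_names=small_windows.channel_names,
        )
        t1 = extract_all(sub)
        assert t1.values.shape == (2, 249)
        assert np.isfinite(t1.values).all()
        t2 = extract_all(sub)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_identical_windows_identical_rows(self, small_windows):
        w = small_windows.windows[0]
        dup = WindowedDataset(
            windows=np.stack([w, w]),
            labels=np.array([0, 0]),
            subject_ids=np.array(["a", "a"]),
            trial_ids=np.array([0, 0]),
            window_index=np.array([0, 1]),
            sampling_rate=small_windows.sampling_rate,
            channel_names=small_windows.channel_names,
        )
        t = extract_all(dup, FeatureRecipe(families=("time_domain", "band_energy")))
        np.testing.assert_array_equal(t.values[0], t.values[1])

    def test_missing_channel_rejected(self, small_windows):
        with pytest.raises(KeyError):
            extract_all(small_windows, FeatureRecipe(channels=("ZZ",)))

    def test_csv_round_trip(self, tmp_path, small_windows):
        sub = WindowedDataset(
            windows=small_windows.windows[:3],
            labels=small_windows.labels[:3],
            subject_ids=small_windows.subject_ids[:3],
            trial_ids=small_windows.trial_ids[:3],
            window_index=small_windows.window_index[:3],
            sampling_rate=small_windows.sampling_rate,
            channel_names=small_windows.channel_names,
        )
        t = extract_all(sub, FeatureRecipe(families=("time_domain",)))
        path = tmp_path / "feat.csv"
        t.to_csv(path)
        back = FeatureTable.from_csv(path)
        np.testing.assert_allclose(back.values, t.values)
        assert back.feature_names == t.feature_names
        np.testing.assert_array_equal(back.labels, t.labels)
        # binary mirror is lossless
        npz = tmp_path / "feat.npz"
        t.to_npz(npz)
        mirror = FeatureTable.from_npz(npz)
        np.testing.assert_array_equal(mirror.values, t.values)
        assert mirror.feature_names == t.feature_names
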