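"""Windowing arithmetic, time-domain statistics, sample entropy, band
powers, and per-minute aggregation."""


import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drowsefuse import (
    BandProfile,
    DegenerateInputError,
    EmptyDataError,
    ParameterError,
    SampleEntropyParams,
    WindowingScheme,
    band_powers,
    eeg_minute_features,
    generate_eeg_segment,
    sample_entropy,
    time_stats,
    windows,
)
from drowsefuse.eeg import SAMPEN_INF, to_minute_vectors

from conftest import sampen_bruteforce

FS = 500.0


class TestWindowing:
    @pytest.mark.parametrize("n_samples,n,overlap,expected", [
        (30000, 1000, 0.5, 60),   # 60 s at 500 Hz -> 60 windows
        (1000, 1000, 0.5, 2),
        (2500, 1000, 0.0, 3),     # no overlap -> ceil(length / N)
        (3000, 1000, 0.0, 3),
        (150000, 1000, 0.5, 300),  # a full 5-min segment
    ])
    def test_window_counts(self, n_samples, n, overlap, expected):
        scheme = WindowingScheme(n=n, overlap=overlap)
        wins = list(windows(np.zeros(n_samples), scheme))
        assert len(wins) == expected

    def test_starts_at_hop_multiples_and_final_truncation(self):
        scheme = WindowingScheme(n=1000, overlap=0.5)
        wins = list(windows(np.arange(30000), scheme))
        starts = [s for s, _ in wins]
        assert starts == list(range(0, 30000, 500))
        assert len(wins[-1][1]) == 500  # truncated to available samples
        assert all(len(w) == 1000 for _, w in wins[:-1])

    def test_every_sample_covered(self):
        scheme = WindowingScheme(n=1000, overlap=0.5)
        covered = np.zeros(7340, dtype=bool)
        for s, w in windows(np.zeros(7340), scheme):
            covered[s:s + len(w)] = True
        assert covered.all()

    def test_segment_shorter_than_hop_rejected(self):
        with pytest.raises(EmptyDataError):
            list(windows(np.zeros(100), WindowingScheme(n=1000,
                                                        overlap=0.5)))

    def test_fractional_hop_rejected(self):
        with pytest.raises(ParameterError):
            WindowingScheme(n=1000, overlap=1 / 3)


class TestTimeStats:
    def test_hand_computed_example(self):
        out = time_stats(np.array([1.0, 2.0, 3.0]))
        assert out["energy"] == 14.0
        assert out["mean"] == 2.0
        assert out["min"] == 1.0
        assert out["max"] == 3.0
        assert out["var"] == pytest.approx(2.0 / 3.0)

    def test_all_zero_window(self):
        out = time_stats(np.zeros(10))
        assert all(v == 0.0 for v in out.values())

    @given(st.floats(min_value=-50, max_value=50,
                     allow_nan=False).filter(lambda c: abs(c) > 1e-3))
    def test_quadratic_homogeneity(self, c):
        rng = np.random.default_rng(12)
        x = rng.normal(size=64)
        base, scaled = time_stats(x), time_stats(c * x)
        assert scaled["energy"] == pytest.approx(c ** 2 * base["energy"])
        assert scaled["var"] == pytest.approx(c ** 2 * base["var"])

    def test_empty_window_rejected(self):
        with pytest.raises(EmptyDataError):
            time_stats(np.array([]))


class TestSampleEntropy:
    def test_alternating_signal_is_fully_regular(self):
        x = np.tile([1.0, 0.0], 50)
        assert sample_entropy(x, SampleEntropyParams(m=2)) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        params = SampleEntropyParams(m=2, r_factor=0.2)
        for _ in range(25):
            n = int(rng.integers(60, 400))
            x = rng.uniform(size=n)
            expected = sampen_bruteforce(x, 2, 0.2 * x.std())
            assert sample_entropy(x, params) == pytest.approx(
                expected, abs=1e-12)

    def test_narrowband_sine_more_regular_than_noise(self):
        rng = np.random.default_rng(5)
        t = np.arange(1000) / FS
        sine = np.sin(2 * np.pi * 10 * t) + 0.05 * rng.normal(size=1000)
        noise = rng.normal(size=1000)
        assert sample_entropy(sine) < sample_entropy(noise)

    def test_zero_variance_window_rejected(self):
        with pytest.raises(DegenerateInputError, match="zero-variance"):
            sample_entropy(np.full(100, 3.14))

    def test_no_extending_match_returns_sentinel_not_exception(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(size=50)
        val = sample_entropy(x, SampleEntropyParams(m=2, r_factor=1e-9))
        assert val == SAMPEN_INF

    def test_too_short_window_rejected(self):
        with pytest.raises(ParameterError):
            sample_entropy(np.array([1.0, 2.0, 3.0]),
                           SampleEntropyParams(m=2))


class TestBandPowers:
    def _tone(self, freq, seconds=60):
        t = np.arange(0, seconds, 1 / FS)
        return np.sin(2 * np.pi * freq * t)

    @pytest.mark.parametrize("freq,band", [(10.0, "alpha"), (6.0, "theta"),
                                           (2.0, "delta"), (20.0, "beta"),
                                           (35.0, "gamma")])
    def test_pure_tone_lands_in_its_band(self, freq, band):
        bp = band_powers(self._tone(freq), FS)
        assert bp.rel_powers[band] >= 0.98
        assert all(v <= 0.02 for b, v in bp.rel_powers.items() if b != band)

    def test_equal_power_mixture_splits_in_thirds(self):
        x = self._tone(2.0) + self._tone(6.0) + self._tone(10.0)
        bp = band_powers(x, FS)
        for band in ("delta", "theta", "alpha"):
            assert bp.rel_powers[band] == pytest.approx(1 / 3, abs=0.02)

    def test_relative_powers_partition_total(self):
        rng = np.random.default_rng(9)
        x = generate_eeg_segment(BandProfile.alert_default(), 10, FS,
                                 seed=rng, channels=["O1"])[0]
        bp = band_powers(x, FS)
        assert all(0 <= v <= 1 for v in bp.rel_powers.values())
        assert sum(bp.rel_powers.values()) == pytest.approx(1.0, abs=0.02)
        assert sum(bp.abs_powers.values()) == pytest.approx(
            bp.total_power, rel=1e-9)
        assert 0.95 * bp.total_power <= sum(bp.abs_powers.values()) \
            <= 1.0000001 * bp.total_power

    def test_sampling_rate_too_low_rejected(self):
        with pytest.raises(ParameterError):
            band_powers(np.zeros(1000), 70.0)


class TestMinuteFeatures:
    def test_95_absolute_power_features_for_full_montage(self):
        seg = generate_eeg_segment(BandProfile.alert_default(), 60, FS,
                                   seed=0)
        from drowsefuse.io import EEG_1020
        tidy = eeg_minute_features(seg, EEG_1020, FS,
                                   feature_set=("bandpower",))
        abs_rows = tidy[tidy.feature.str.startswith("p_abs_")]
        assert len(abs_rows[["channel", "feature"]].drop_duplicates()) == 95
        rel_rows = tidy[tidy.feature.str.startswith("p_rel_")]
        assert len(rel_rows[["channel", "feature"]].drop_duplicates()) == 95

    def test_drowsy_alpha_exceeds_alert_alpha_on_o2(self):
        alert = generate_eeg_segment(BandProfile.alert_default(), 60, FS,
                                     seed=21, channels=["O2"])
        drowsy = generate_eeg_segment(BandProfile.drowsy_default(), 60, FS,
                                      seed=22, channels=["O2"])
        def rel_alpha(seg):
            tidy = eeg_minute_features(seg, ["O2"], FS,
                                       feature_set=("bandpower",))
            return tidy[tidy.feature == "p_rel_alpha"]["value"].mean()
        assert rel_alpha(drowsy) > rel_alpha(alert)

    def test_stationary_input_gives_stable_minutes(self):
        seg = generate_eeg_segment(BandProfile.alert_default(), 300, FS,
                                   seed=3, channels=["Pz"])
        tidy = eeg_minute_features(seg, ["Pz"], FS,
                                   feature_set=("time", "bandpower"))
        # broadband statistics stabilize well within a minute's 60
        # windows; narrow-band powers keep larger sampling spread
        for feat in ("var", "energy", "max", "p_rel_beta"):
            vals = tidy[tidy.feature == feat].sort_values("minute")["value"]
            assert len(vals) == 5
            spread = (vals.max() - vals.min()) / vals.mean()
            assert spread < 0.10

    def test_minute_with_majority_invalid_windows_flagged_missing(self):
        seg = generate_eeg_segment(BandProfile.alert_default(), 120, FS,
                                   seed=4, channels=["Cz"])
        mask = np.ones(seg.shape[1], dtype=bool)
        mask[:int(50 * FS)] = False  # 50 of minute 0's 60 s invalid
        tidy = eeg_minute_features(seg, ["Cz"], FS, mask=mask,
                                   feature_set=("bandpower",))
        assert set(tidy["minute"]) == {1}

    def test_all_invalid_raises_informative_empty_error(self):
        seg = generate_eeg_segment(BandProfile.alert_default(), 60, FS,
                                   seed=5, channels=["Cz"])
        with pytest.raises(EmptyDataError, match="no valid windows"):
            eeg_minute_features(seg, ["Cz"], FS,
                                mask=np.zeros(seg.shape[1], bool))

    def test_minute_vector_map_round_trip(self):
        seg = generate_eeg_segment(BandProfile.alert_default(), 60, FS,
                                   seed=6, channels=["O1", "O2"])
        tidy = eeg_minute_features(seg, ["O1", "O2"], FS,
                                   feature_set=("time",))
        vecs = to_minute_vectors(tidy)
        assert set(vecs) == {0}
        assert ("O1", "energy") in vecs[0]
        row = tidy[(tidy.channel == "O1") & (tidy.feature == "energy")]
        assert vecs[0][("O1", "energy")] == row["value"].iloc[0]
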