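"""Wavelet band decomposition and the 16-statistic feature bank."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eegrisk.epoching import Epoch, EpochSet
from eegrisk.features import (
    BANDS,
    FEATURE_NAMES,
    band_feature_vector,
    build_feature_matrix,
    dwt_band_decompose,
    epoch_feature_vector,
)

from .oracles import brute_force_features


class TestDecomposition:
    def test_five_bands_keyed_delta_to_gamma(self, rng):
        out = dwt_band_decompose(rng.standard_normal(250))
        assert list(out) == ["delta", "theta", "alpha", "beta", "gamma"]

    def test_alpha_sinusoid_energy_lands_in_alpha_node(self):
        t = np.arange(250) / 250.0
        out = dwt_band_decompose(np.sin(2 * np.pi * 10.0 * t))
        energies = {band: float(np.sum(c**2)) for band, c in out.items()}
        assert max(energies, key=energies.get) == "alpha"

    def test_perfect_reconstruction_including_discarded_d1(self, rng):
        x = rng.standard_normal(250)
        coeffs = pywt.wavedec(x, "db4", level=5, mode="symmetric")
        recon = pywt.waverec(coeffs, "db4", mode="symmetric")[: len(x)]
        assert np.abs(recon - x).max() / np.abs(x).max() < 1e-8

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            dwt_band_decompose(np.zeros(16))


class TestFeatureBank:
    def test_exactly_sixteen_statistics(self, rng):
        out = band_feature_vector(rng.standard_normal(64))
        assert len(out) == 16

    def test_hand_computed_alternating_sequence(self):
        out = band_feature_vector(np.array([1.0, -1.0, 1.0, -1.0]))
        assert out["zero_crossing_rate"] == 1.0
        assert out["waveform_length"] == 6.0
        assert out["energy"] == 4.0
        assert out["mean"] == 0.0
        assert out["avg_power"] == 1.0
        assert out["max_abs"] == 1.0

    def test_uniform_energy_entropy_is_three_bits(self):
        out = band_feature_vector(np.array([1.0, -1, 1, 1, -1, 1, -1, 1]))
        assert out["shannon_entropy"] == pytest.approx(3.0)

    def test_all_zero_input_degenerates_to_zero(self):
        out = band_feature_vector(np.zeros(32))
        for name in ("mean", "energy", "shannon_entropy", "zero_crossing_rate",
                     "waveform_length", "hjorth_mobility", "hjorth_complexity",
                     "skewness", "kurtosis"):
            assert out[name] == 0.0

    def test_fewer_than_three_coefficients_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            band_feature_vector(np.array([1.0, 2.0]))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            x = rng.standard_normal(rng.integers(4, 128))
            got = band_feature_vector(x)
            want = brute_force_features(x)
            for name in FEATURE_NAMES[:16]:
                stat = name.split("_", 1)[1]
                assert got[stat] == pytest.approx(want[stat], rel=1e-10, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        x=hnp.arrays(
            float, st.integers(8, 64),
            elements=st.floats(-100, 100, allow_nan=False).map(
                lambda v: 0.0 if abs(v) < 1e-6 else v  # keep away from subnormals
            ),
        ),
        c=st.floats(0.1, 50.0),
    )
    def test_scaling_behavior(self, x, c):
        """x -> c*x scales energy by c^2 and leaves shape statistics alone."""
        base = band_feature_vector(x)
        scaled = band_feature_vector(c * x)
        assert scaled["energy"] == pytest.approx(c**2 * base["energy"], rel=1e-8)
        for inv in ("shannon_entropy", "zero_crossing_rate", "hjorth_mobility",
                    "hjorth_complexity", "skewness", "kurtosis"):
            assert scaled[inv] == pytest.approx(base[inv], rel=1e-6, abs=1e-9)

    def test_entropy_bounded_by_log2_n(self, rng):
        for n in (8, 32, 128):
            x = rng.standard_normal(n)
            h = band_feature_vector(x)["shannon_entropy"]
            assert 0.0 <= h <= np.log2(n) + 1e-12

    @pytest.mark.parametrize("f", [5.0, 10.0, 25.0])
    def test_hjorth_mobility_closed_form_for_sinusoid(self, f):
        fs = 250.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * f * t)
        got = band_feature_vector(x)["hjorth_mobility"]
        assert got == pytest.approx(2 * np.sin(np.pi * f / fs), rel=0.05)

    @pytest.mark.parametrize("f", [5.0, 10.0, 25.0])
    def test_zero_crossing_rate_tracks_frequency(self, f):
        fs = 250.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * f * t + 0.1)
        got = band_feature_vector(x)["zero_crossing_rate"]
        assert got == pytest.approx(2 * f / fs, rel=0.10)


class TestEpochVector:
    def test_vector_is_eighty_dimensional(self, rng):
        vec = epoch_feature_vector(rng.standard_normal((23, 250)))
        assert vec.shape == (80,)
        assert len(FEATURE_NAMES) == 80
        assert np.all(np.isfinite(vec))

    def test_identical_channels_equal_single_channel_vector(self, rng):
        one = rng.standard_normal(250)
        stacked = np.tile(one, (23, 1))
        np.testing.assert_allclose(
            epoch_feature_vector(stacked),
            epoch_feature_vector(one[None, :]),
            rtol=1e-12,
        )

    def test_channel_permutation_invariance(self, rng):
        epoch = rng.standard_normal((8, 250))
        perm = rng.permutation(8)
        np.testing.assert_allclose(
            epoch_feature_vector(epoch),
            epoch_feature_vector(epoch[perm]),
            rtol=1e-12,
        )

    def test_names_are_band_major(self):
        assert FEATURE_NAMES[0] == "delta_mean"
        assert FEATURE_NAMES[16] == "theta_mean"
        assert FEATURE_NAMES[-1] == "gamma_hjorth_complexity"


class TestFeatureMatrix:
    def test_one_row_per_epoch(self, rng):
        eps = EpochSet([
            Epoch("s1", float(i), rng.standard_normal((4, 250)), "A")
            for i in range(5)
        ])
        fm = build_feature_matrix(eps)
        assert fm.values.shape == (5, 80)
        assert list(fm.labels) == ["A"] * 5
        assert list(fm.subjects) == ["s1"] * 5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_feature_matrix(EpochSet([]))

    def test_row_count_matches_epoching_tally(self, small_cohort, small_feature_matrix):
        expected = sum(int(rec.duration) for rec in small_cohort)
        assert len(small_feature_matrix) == expected

    def test_rows_align_with_direct_per_epoch_extraction(self, rng):
        data = rng.standard_normal((3, 4, 250))
        eps = EpochSet([
            Epoch("s", float(i), data[i], "B") for i in range(3)
        ])
        fm = build_feature_matrix(eps)
        for i in range(3):
            np.testing.assert_allclose(fm.values[i], epoch_feature_vector(data[i]),
                                       rtol=1e-12)

    def test_dataframe_round_trip_columns(self, small_feature_matrix):
        df = small_feature_matrix.to_dataframe()
        assert list(df.columns[:80]) == list(FEATURE_NAMES)
        assert {"label", "subject"} <= set(df.columns)
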