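"""Sifting algorithm: extrema, envelopes, IMF conditions, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdnet.emd import (
    IMFTensorizer,
    MonotoneResidual,
    SiftConfig,
    build_imf_tensor,
    emd_decompose,
    envelope_mean,
    find_extrema,
    sift_imf,
    zero_crossings,
)
from emdnet.records import ClassLabel, Epoch

from conftest import (
    band_limited_noise,
    count_extrema_bruteforce,
    count_zero_crossings_bruteforce,
    fft_peak_hz,
    two_tone,
)


class TestFindExtrema:
    def test_single_oscillation(self):
        max_i, max_v, min_i, min_v = find_extrema(np.array([0.0, 1, 0, -1, 0]))
        assert list(max_i) == [1] and list(min_i) == [3]
        assert max_v[0] == 1 and min_v[0] == -1

    def test_monotone_ramp_has_no_extrema(self):
        max_i, _, min_i, _ = find_extrema(np.linspace(0, 1, 50))
        assert len(max_i) == 0 and len(min_i) == 0

    def test_sinusoid_four_cycles_alternating(self):
        t = np.arange(256) / 256.0
        x = np.sin(2 * np.pi * 4 * t)
        max_i, _, min_i, _ = find_extrema(x)
        assert len(max_i) == 4 and len(min_i) == 4
        merged = sorted([(i, "M") for i in max_i] + [(i, "m") for i in min_i])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))  # alternation

    def test_plateau_counts_once_at_midpoint(self):
        x = np.array([0.0, 1, 2, 2, 2, 1, 0, -1, 0])
        max_i, _, min_i, _ = find_extrema(x)
        assert list(max_i) == [3]  # midpoint of the flat top
        assert list(min_i) == [7]

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_counts_match_bruteforce_scan(self, values):
        x = np.asarray(values)
        max_i, _, min_i, _ = find_extrema(x)
        assert len(max_i) + len(min_i) == count_extrema_bruteforce(x)
        assert zero_crossings(x) == count_zero_crossings_bruteforce(x)


class TestEnvelopeMean:
    def test_pure_sinusoid_mean_near_zero(self):
        t = np.arange(2560) / 256.0
        A = 3.0
        m = envelope_mean(A * np.sin(2 * np.pi * 8 * t))
        interior = m[256:-256]
        assert np.max(np.abs(interior)) < 0.05 * A

    def test_offset_sinusoid_mean_near_offset(self):
        t = np.arange(2560) / 256.0
        c = 2.0
        m = envelope_mean(np.sin(2 * np.pi * 8 * t) + c)
        interior = m[256:-256]
        assert np.max(np.abs(interior - c)) < 0.05 * c

    def test_two_extrema_minimum_case_runs(self):
        t = np.arange(400) / 256.0
        x = np.sin(2 * np.pi * 1.2 * t)  # barely two maxima/minima
        m = envelope_mean(x)
        assert m.shape == x.shape

    def test_monotone_signal_raises(self):
        with pytest.raises(MonotoneResidual):
            envelope_mean(np.linspace(0, 1, 100))


class TestSiftIMF:
    def test_two_tone_first_imf_is_the_fast_tone(self):
        imf, residual = sift_imf(two_tone())
        assert fft_peak_hz(imf) == pytest.approx(16.0, abs=0.5)

    def test_residual_identity_is_exact(self):
        x = two_tone()
        imf, residual = sift_imf(x)
        assert np.array_equal(residual, x - imf)

    def test_imf_satisfies_count_condition(self, rng):
        for _ in range(5):
            x = band_limited_noise(rng)
            imf, _ = sift_imf(x)
            n_ext = count_extrema_bruteforce(imf)
            n_zc = count_zero_crossings_bruteforce(imf)
            assert abs(n_ext - n_zc) <= 1


class TestDecompose:
    def test_constant_input_yields_no_imfs(self):
        dec = emd_decompose(np.full(1280, 3.14))
        assert dec.n_imfs == 0
        assert np.array_equal(dec.residual, np.full(1280, 3.14))

    def test_two_tone_frequency_ordering(self):
        dec = emd_decompose(two_tone(), SiftConfig(max_imfs=3))
        assert dec.n_imfs >= 2
        assert fft_peak_hz(dec.imfs[0]) == pytest.approx(16.0, abs=0.5)
        peaks = [fft_peak_hz(h) for h in dec.imfs[:2]]
        assert peaks[0] > peaks[1]
        assert any(fft_peak_hz(h) == pytest.approx(1.0, abs=0.5)
                   for h in dec.imfs[1:])

    def test_reconstruction_on_noise(self, rng):
        x = band_limited_noise(rng)
        dec = emd_decompose(x, SiftConfig(max_imfs=3))
        err = np.max(np.abs(x - dec.reconstruct()))
        assert err < 1e-8 * np.max(np.abs(x))

    def test_deterministic_bit_for_bit(self, rng):
        x = band_limited_noise(rng)
        a = emd_decompose(x)
        b = emd_decompose(x)
        assert all(np.array_equal(p, q) for p, q in zip(a.imfs, b.imfs))
        assert np.array_equal(a.residual, b.residual)

    def test_zero_crossing_rate_decreases_with_imf_index(self, rng):
        t = np.arange(1280) / 256.0
        x = np.sin(2 * np.pi * 24 * t) + np.sin(2 * np.pi * 6 * t) + 0.5 * np.sin(
            2 * np.pi * 1.2 * t)
        dec = emd_decompose(x, SiftConfig(max_imfs=3))
        rates = [zero_crossings(h) for h in dec.imfs]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_orthogonality_reported_not_asserted(self, rng):
        dec = emd_decompose(band_limited_noise(rng))
        oi = dec.orthogonality_index()
        assert 0.0 <= oi <= 1.0


class TestIMFTensor:
    @staticmethod
    def _epoch(data):
        return Epoch(subject_id="s", label=ClassLabel.ES, start_sample=0, data=data)

    def test_identical_channels_give_identical_planes(self):
        x = two_tone()
        epoch = self._epoch(np.tile(x, (19, 1)))
        tensor = build_imf_tensor(epoch)
        assert tensor.shape == (19, 1280, 3)
        assert all(np.array_equal(tensor[0], tensor[c]) for c in range(1, 19))

    def test_constant_channel_zero_filled_with_warning(self, rng):
        data = np.array([band_limited_noise(rng) for _ in range(19)])
        data[7] = 5.0
        with pytest.warns(UserWarning, match="zero-filled"):
            tensor = build_imf_tensor(self._epoch(data))
        assert np.array_equal(tensor[7], np.zeros((1280, 3)))
        assert not np.array_equal(tensor[6], np.zeros((1280, 3)))

    def test_transformer_matches_per_epoch_builder(self, rng):
        data = np.array([band_limited_noise(rng) for _ in range(19)])
        X = data[np.newaxis]
        out = IMFTensorizer().fit_transform(X)
        assert out.shape == (1, 19, 1280, 3)
        assert np.array_equal(out[0], build_imf_tensor(self._epoch(data)))

    def test_transformer_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            IMFTensorizer().transform(np.zeros((2, 19, 640)))


class TestSiftConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(stop_threshold=0.0), dict(max_imfs=0),
                   dict(boundary_mode="wrap")]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SiftConfig(**kwargs)
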