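import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from waveclean.config import EEGWindow, PipelineConfig, slide_windows
from waveclean.scaleogram import Scaleogram, normalize
from waveclean.wavelet import (
    DWTCoefficients,
    decompose,
    dereplicate,
    level_bands,
    reconstruct,
    replicate,
)


def _decompose_pair(config, rng):
    signal = rng.standard_normal(2 * config.samples_per_window)
    w0, w1 = slide_windows(signal, config)
    return w1, decompose(w1, w0, config)


class TestDecompose:
    def test_dyadic_detail_lengths_full_depth(self, rng):
        cfg = PipelineConfig(window_ms=1000, sampling_rate=1024)
        _, coeffs = _decompose_pair(cfg, rng)
        assert [len(d) for d in coeffs.detail_levels] == [
            1024 // 2**m for m in range(1, 11)
        ]
        assert len(coeffs.approximation) == 1

    def test_constant_window_has_vanishing_details(self, small_config):
        n = small_config.samples_per_window
        w = EEGWindow(np.full(n, 7.25), 0, 0)
        coeffs = decompose(w, None, small_config)
        for detail in coeffs.detail_levels:
            np.testing.assert_allclose(detail, 0.0, atol=1e-9)
        # the approximation carries the signal's energy
        assert np.sum(coeffs.approximation**2) == pytest.approx(
            n * 7.25**2, rel=1e-9
        )

    def test_unknown_wavelet_rejected(self, small_config, random_windows):
        cfg = small_config.with_overrides(mother_wavelet="nosuchwavelet")
        cfg.mother_wavelet = "nosuchwavelet"
        with pytest.raises(ValueError, match="wavelet"):
            decompose(random_windows[0], None, cfg)

    def test_level_bands_halve(self):
        bands = level_bands(1024.0, 10)
        assert bands[0] == (256.0, 512.0)
        assert bands[1] == (128.0, 256.0)
        assert bands[-1] == (0.5, 1.0)

    def test_impulse_energy_localised(self, small_config):
        n = small_config.samples_per_window
        x = np.zeros(n)
        x[n // 2] = 1.0
        w = EEGWindow(x, 0, 0)
        coeffs = decompose(w, None, small_config)
        # level-1 energy concentrated near the impulse column
        d1 = np.abs(coeffs.detail_levels[0])
        centre = n // 4  # column units
        window = d1[centre - 8 : centre + 8]
        assert window.sum() > 0.9 * d1.sum()

    def test_trim_matches_long_signal_interior(self, rng):
        # coefficients attributable to a window agree with those of a
        # longer periodized decomposition away from window boundaries
        cfg = PipelineConfig(
            window_ms=1000, sampling_rate=256, max_level=3, if_subsample=128
        )
        n = cfg.samples_per_window
        signal = rng.standard_normal(4 * n)
        windows = slide_windows(signal, cfg)
        coeffs = decompose(windows[2], windows[1], cfg)
        long = pywt.wavedec(signal, cfg.mother_wavelet, mode="periodization", level=3)
        guard = 10
        for m in range(1, 4):
            mine = coeffs.detail_levels[m - 1]
            offset = 2 * n // 2**m
            theirs = long[3 - m + 1][offset : offset + n // 2**m]
            np.testing.assert_allclose(
                mine[guard:-guard], theirs[guard:-guard], atol=1e-10
            )


class TestReconstruct:
    def test_perfect_reconstruction_with_context(self, small_config, random_windows):
        prev = None
        for w in random_windows:
            coeffs = decompose(w, prev, small_config)
            rec = reconstruct(coeffs, small_config)
            scale = np.max(np.abs(w.samples))
            assert np.max(np.abs(rec - w.samples)) < 1e-8 * scale
            prev = w

    def test_zeroed_coefficients_reconstruct_to_zero_standalone(self, small_config):
        M = small_config.levels
        n = small_config.samples_per_window
        coeffs = DWTCoefficients(
            detail_levels=[np.zeros(n // 2**m) for m in range(1, M + 1)],
            approximation=np.zeros(n // 2**M),
            wavelet_name=small_config.mother_wavelet,
            level_bands=level_bands(small_config.sampling_rate, M),
        )
        np.testing.assert_array_equal(reconstruct(coeffs, small_config), np.zeros(n))

    def test_reconstruction_affine_in_band_contributions(
        self, small_config, random_windows
    ):
        # zeroing a level removes exactly that band's contribution:
        # the per-level deltas sum back to the full reconstruction
        coeffs = decompose(random_windows[1], random_windows[0], small_config)
        full = reconstruct(coeffs, small_config)

        def zero_level(c, m):
            details = [d.copy() for d in c.detail_levels]
            approx = c.approximation.copy()
            if m == 0:
                approx[:] = 0.0
            else:
                details[m - 1][:] = 0.0
            return DWTCoefficients(
                detail_levels=details,
                approximation=approx,
                wavelet_name=c.wavelet_name,
                level_bands=c.level_bands,
                boundary_context=c.boundary_context,
            )

        def zero_all(c):
            out = zero_level(c, 0)
            for d in out.detail_levels:
                d[:] = 0.0
            return out

        deltas = sum(
            full - reconstruct(zero_level(coeffs, m), small_config)
            for m in range(small_config.levels + 1)
        )
        base = reconstruct(zero_all(coeffs), small_config)
        np.testing.assert_allclose(base + deltas, full, atol=1e-8)

    def test_inconsistent_level_lengths_rejected(self, small_config):
        with pytest.raises(ValueError):
            DWTCoefficients(
                detail_levels=[np.zeros(64), np.zeros(64)],
                approximation=np.zeros(32),
                wavelet_name="sym4",
                level_bands=[],
            )


class TestReplication:
    def test_replication_factors(self, small_config, random_windows):
        coeffs = decompose(random_windows[0], None, small_config)
        scal = replicate(coeffs)
        cols = small_config.columns_per_window
        assert scal.matrix.shape == (small_config.levels + 1, cols)
        # level 1: no repetition
        np.testing.assert_array_equal(scal.matrix[0], coeffs.detail_levels[0])
        # level 3 coefficient k occupies columns 4k..4k+3
        for k in range(len(coeffs.detail_levels[2])):
            np.testing.assert_array_equal(
                scal.matrix[2, 4 * k : 4 * k + 4],
                np.full(4, coeffs.detail_levels[2][k]),
            )
        # deepest detail level: single coefficient fills every column
        assert np.all(
            scal.matrix[small_config.levels - 1]
            == coeffs.detail_levels[-1][0]
        )

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_replicate_dereplicate_round_trip_exact(self, seed):
        cfg = PipelineConfig(
            sampling_rate=64, buffer_capacity=4, if_subsample=32, seed=0
        )
        rng = np.random.default_rng(seed)
        w = EEGWindow(rng.standard_normal(cfg.samples_per_window), 0, 0)
        coeffs = decompose(w, None, cfg)
        back = dereplicate(replicate(coeffs), template=coeffs)
        for a, b in zip(coeffs.detail_levels, back.detail_levels):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(coeffs.approximation, back.approximation)

    def test_dereplicate_refuses_normalized(self, small_config, random_windows):
        scal = normalize(replicate(decompose(random_windows[0], None, small_config)))
        with pytest.raises(ValueError, match="normaliz"):
            dereplicate(scal)

    def test_dereplicate_rejects_indivisible_columns(self):
        scal = Scaleogram(matrix=np.zeros((4, 6)), levels=3)
        with pytest.raises(ValueError, match="divisible"):
            dereplicate(scal)

    def test_mitigated_round_trip_through_context(self, small_config, random_windows):
        # the streaming path: replicate -> modify -> dereplicate -> invert
        coeffs = decompose(random_windows[1], random_windows[0], small_config)
        scal = replicate(coeffs)
        scal.matrix[:, 10:20] *= 0.5
        back = dereplicate(scal, template=coeffs)
        rec = reconstruct(back, small_config)
        assert rec.shape == (small_config.samples_per_window,)
        assert not np.allclose(rec, random_windows[1].samples)
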