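"""Analytic signal, instantaneous frequency, and Cohen's-class TFDs."""

import numpy as np
import pytest

from tfmra import (Segment, TfdKernelSpec, analytic_signal, compute_tfd,
                   extract_components, instantaneous_freq_amp, tf_to_image)
from tfmra.tfd import KERNEL_KINDS

from conftest import FS


class TestAnalyticSignal:
    def test_tone_has_unit_modulus(self, tone_segment):
        z = analytic_signal(tone_segment.samples, FS).z
        interior = np.abs(z)[4:-4]
        assert np.abs(interior - 1.0).max() < 1e-6

    def test_negative_frequency_bins_vanish(self, rng):
        x = rng.standard_normal(256)
        z = analytic_signal(x, FS).z
        spec = np.fft.fft(z)
        neg = spec[129:]  # strictly negative-frequency bins
        assert np.abs(neg).max() < 1e-10 * np.abs(spec).max()

    def test_real_part_equals_input(self, rng):
        x = rng.standard_normal(300)
        z = analytic_signal(x, FS).z
        np.testing.assert_allclose(z.real, x, rtol=0, atol=1e-10)

    def test_constant_preserved(self):
        z = analytic_signal(np.full(64, 3.5), FS).z
        np.testing.assert_allclose(z.real, 3.5, atol=1e-10)
        np.testing.assert_allclose(z.imag, 0.0, atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            analytic_signal(np.array([1.0, np.nan] + [0.0] * 14), FS)


class TestInstantaneousFreqAmp:
    def test_pure_tone_if(self, tone_segment):
        z = analytic_signal(tone_segment.samples, FS)
        if_hz, _ = instantaneous_freq_amp(z)
        assert np.abs(if_hz[8:-8] - 32.0).max() < 0.5

    def test_linear_chirp_if(self, chirp_segment):
        z = analytic_signal(chirp_segment.samples, FS)
        if_hz, _ = instantaneous_freq_amp(z)
        t = np.arange(256) / FS
        expected = 10 + 40 * t
        sl = slice(26, 230)  # interior 80%
        rmse = np.sqrt(np.mean((if_hz[sl] - expected[sl]) ** 2))
        assert rmse < 1.0

    def test_amplitude_tracks_envelope(self):
        t = np.arange(512) / FS
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 1.5 * t)
        x = env * np.cos(2 * np.pi * 40 * t)
        _, ia = instantaneous_freq_amp(analytic_signal(x, FS))
        sl = slice(51, -51)
        assert np.abs((ia[sl] - env[sl]) / env[sl]).max() < 0.05


class TestComputeTfd:
    def test_wvd_tone_concentrates_at_32hz(self):
        n = np.arange(64)
        seg = Segment(np.cos(2 * np.pi * 32 * n / FS), FS, 0.25)
        tf = compute_tfd(seg, TfdKernelSpec(kind="wvd"))
        df = tf.freq_axis[1] - tf.freq_axis[0]
        argmax = tf.freq_axis[np.argmax(tf.values, axis=0)]
        # columns at the very edges see a fully truncated lag kernel
        assert np.abs(argmax[4:-4] - 32.0).max() <= df

    def test_wvd_time_marginal_is_instantaneous_power(self, tone_segment):
        tf = compute_tfd(tone_segment, TfdKernelSpec(kind="wvd"))
        z = analytic_signal(tone_segment.samples, FS).z
        df = tf.freq_axis[1] - tf.freq_axis[0]
        marginal = tf.values.sum(axis=0) * df
        power = np.abs(z) ** 2
        assert (np.linalg.norm(marginal - power) / np.linalg.norm(power)
                < 1e-6)

    def test_swvd_suppresses_cross_terms(self):
        n = np.arange(256)
        x = np.cos(2 * np.pi * 20 * n / FS) + np.cos(2 * np.pi * 60 * n / FS)
        seg = Segment(x, FS, 1.0)

        def midband_fraction(kind):
            tf = compute_tfd(seg, TfdKernelSpec(kind=kind))
            v = np.abs(tf.values)
            band = (tf.freq_axis >= 35) & (tf.freq_axis <= 45)
            return v[band].sum() / v.sum()

        wvd_frac = midband_fraction("wvd")
        swvd_frac = midband_fraction("swvd")
        assert swvd_frac < 0.25 * wvd_frac

    @pytest.mark.parametrize("kind", KERNEL_KINDS)
    def test_all_kernels_real_and_finite(self, kind, rng):
        seg = Segment(rng.standard_normal(256), FS, 1.0)
        tf = compute_tfd(seg, TfdKernelSpec(kind=kind))
        assert tf.values.dtype.kind == "f"
        assert np.all(np.isfinite(tf.values))
        assert tf.values.shape == (256, 256)

    def test_spectrogram_nonnegative(self, rng):
        seg = Segment(rng.standard_normal(256), FS, 1.0)
        tf = compute_tfd(seg, TfdKernelSpec(kind="spec"))
        assert tf.values.min() >= 0.0

    def test_wvd_total_energy(self, tone_segment):
        tf = compute_tfd(tone_segment, TfdKernelSpec(kind="wvd"))
        z = analytic_signal(tone_segment.samples, FS).z
        df = tf.freq_axis[1] - tf.freq_axis[0]
        assert abs(tf.values.sum() * df - np.sum(np.abs(z) ** 2)) \
            < 0.01 * np.sum(np.abs(z) ** 2)

    @pytest.mark.parametrize("kind", ["wvd", "swvd"])
    def test_chirp_if_rule(self, kind, chirp_segment):
        tf = compute_tfd(chirp_segment, TfdKernelSpec(kind=kind))
        df = tf.freq_axis[1] - tf.freq_axis[0]
        t = np.arange(256) / FS
        expected_bins = (10 + 40 * t) / df
        argmax = np.argmax(tf.values, axis=0)
        sl = slice(26, 230)
        rmse = np.sqrt(np.mean((argmax[sl] - expected_bins[sl]) ** 2))
        assert rmse < 2.0

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="unknown kernel"):
            TfdKernelSpec(kind="nope")

    def test_window_longer_than_segment_rejected(self):
        seg = Segment(np.ones(64), FS, 0.25)
        with pytest.raises(ValueError, match="shorter than twice"):
            compute_tfd(seg, TfdKernelSpec(kind="swvd", window_len=63))


class TestTfToImage:
    def test_constant_maps_to_zero(self):
        assert tf_to_image(np.full((8, 8), 7.0), 8).max() == 0

    def test_minmax_contract(self, rng):
        img = tf_to_image(rng.standard_normal((16, 16)), 8)
        assert img.min() == 0 and img.max() == 7

    def test_argmax_pixel_attains_quantized_maximum(self, rng):
        # monotone mapping: the peak pixel still holds the top gray level
        # (other pixels may share it after quantization)
        mat = rng.standard_normal((16, 16))
        img = tf_to_image(mat, 8)
        assert img[np.unravel_index(mat.argmax(), mat.shape)] == img.max()


def _flood_fill_oracle(mask: np.ndarray, connectivity: int) -> list[set]:
    """Brute-force BFS connected-component labeling."""
    if connectivity == 8:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)
                if (a, b) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    rows, cols = mask.shape
    for i in range(rows):
        for j in range(cols):
            if mask[i, j] and not seen[i, j]:
                comp, queue = set(), [(i, j)]
                seen[i, j] = True
                while queue:
                    a, b = queue.pop()
                    comp.add((a, b))
                    for da, db in nbrs:
                        x, y = a + da, b + db
                        if (0 <= x < rows and 0 <= y < cols
                                and mask[x, y] and not seen[x, y]):
                            seen[x, y] = True
                            queue.append((x, y))
                comps.append(comp)
    return comps


class TestExtractComponents:
    def test_all_below_threshold_gives_none(self):
        tf = compute_tfd(Segment(np.zeros(64) + 1e-12, FS, 0.25),
                         TfdKernelSpec(kind="wvd"))
        tf.values[:] = 0.0
        assert extract_components(tf) == []

    def test_single_tone_single_component(self, tone_segment):
        tf = compute_tfd(tone_segment, TfdKernelSpec(kind="swvd"))
        comps = extract_components(tf, rel_threshold=0.3)
        assert len(comps) == 1
        df = tf.freq_axis[1] - tf.freq_axis[0]
        assert np.abs(comps[0].if_track[:, 1] - 32.0).max() <= df

    def test_two_tones_two_components(self):
        n = np.arange(256)
        x = (np.cos(2 * np.pi * 30 * n / FS)
             + np.cos(2 * np.pi * 60 * n / FS))
        tf = compute_tfd(Segment(x, FS, 1.0), TfdKernelSpec(kind="swvd"))
        comps = extract_components(tf, rel_threshold=0.3, connectivity=8)
        assert len(comps) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_labeling_matches_flood_fill_oracle(self, connectivity,
                                                tone_segment):
        tf = compute_tfd(tone_segment, TfdKernelSpec(kind="swvd"))
        comps = extract_components(tf, rel_threshold=0.2,
                                   connectivity=connectivity)
        # rebuild the mask exactly as documented, then flood-fill it
        vals = tf.values
        above = vals >= 0.2 * vals.max()
        local = np.ones_like(vals, dtype=bool)
        local[1:] &= vals[1:] >= vals[:-1]
        local[:-1] &= vals[:-1] >= vals[1:]
        mask = above & local
        oracle = _flood_fill_oracle(mask, connectivity)
        got = [set((f, t) for t, f in c.pixels) for c in comps]
        assert sorted(map(sorted, got)) == sorted(map(sorted, oracle))
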