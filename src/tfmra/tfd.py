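"""Quadratic time-frequency analysis of EEG segments.

Implements the analytic signal, instantaneous frequency/amplitude, and six
Cohen's-class time-frequency distributions (TFDs): the Wigner-Ville
distribution (WVD), its time-smoothed variant (SWVD), the spectrogram
(SPEC), the Gaussian product-kernel / Choi-Williams-type distribution (GKD),
the modified B-distribution (MBD, cosh-based lag-independent kernel), and a
separable Hamming(time) x Hanning(lag) kernel (SEPK).

All lag-kernel TFDs are computed from the instantaneous autocorrelation
K(n, l) = z(n+l) z*(n-l) of the analytic signal z, smoothed in time and/or
windowed in lag according to the kernel, then Fourier-transformed over lag.
K is Hermitian in the lag index, so every distribution is real up to
floating-point round-off.  Values are scaled as an energy density per Hz:
summing a WVD column over frequency times the bin width recovers |z(n)|^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .preprocess import Segment

KERNEL_KINDS = ("wvd", "swvd", "spec", "gkd", "mbd", "sepk")


@dataclass
class AnalyticSignal:
    """Complex signal with no negative-frequency content."""

    z: np.ndarray
    fs: float


@dataclass
class TfdKernelSpec:
    """Choice of Cohen's-class kernel and its parameters.

    Parameters
    ----------
    kind : str
        One of ``wvd, swvd, spec, gkd, mbd, sepk``.
    sigma : float
        Gaussian product-kernel width (GKD only). Default 0.8.
    mbd_beta : float
        Modified-B smoothing exponent in (0, 1). Default 0.02.
    window_kind : str
        ``hanning`` or ``hamming`` for the windowed kernels.
    window_len : int or None
        Smoothing-window length in samples; ``None`` means ``floor(fs/4)``
        adjusted down to the nearest odd length so the window is symmetric.
    """

    kind: str = "swvd"
    sigma: float = 0.8
    mbd_beta: float = 0.02
    window_kind: str = "hanning"
    window_len: int | None = None

    def __post_init__(self) -> None:
        self.kind = self.kind.lower()
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; "
                             f"choose from {KERNEL_KINDS}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.mbd_beta < 1:
            raise ValueError("mbd_beta must lie in (0, 1)")
        if self.window_kind not in ("hanning", "hamming"):
            raise ValueError("window_kind must be 'hanning' or 'hamming'")

    def resolved_window_len(self, fs: float) -> int:
        n = self.window_len if self.window_len is not None else int(fs) // 4
        if n < 3:
            n = 3
        if n % 2 == 0:
            n -= 1
        return n


@dataclass
class TfImage:
    """Real-valued time-frequency energy image of one segment.

    ``values`` has shape (n_freq_bins, n_time_samples); row k corresponds to
    frequency ``freq_axis[k]`` in Hz on the one-sided axis 0 ... fs/2.
    """

    values: np.ndarray
    fs: float
    freq_axis: np.ndarray
    kernel: TfdKernelSpec

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TF image contains non-finite values")


@dataclass
class TfComponent:
    """One connected ridge in a TF image with its IF track."""

    pixels: list[tuple[int, int]]  # (time_index, freq_index)
    if_track: np.ndarray           # columns: time [s], frequency [Hz]
    peak_energy: float


def analytic_signal(x: np.ndarray, fs: float) -> AnalyticSignal:
    """Analytic signal z(n) = x(n) + i * HT(x(n)) via the FFT method.

    In the frequency domain negative bins are zeroed, strictly positive bins
    doubled, and DC (plus Nyquist for even length) kept, so the real part of
    z equals x exactly and the spectrum vanishes at negative frequencies.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 8:
        raise ValueError("signal too short for analytic-signal construction")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    return AnalyticSignal(signal.hilbert(x), float(fs))


def instantaneous_freq_amp(z: AnalyticSignal) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous frequency (Hz) and amplitude from an analytic signal.

    IF is the derivative of the unwrapped phase (central differences,
    one-sided at the ends) scaled by fs / 2*pi; IA is |z(n)|.
    """
    phase = np.unwrap(np.angle(z.z))
    if_hz = np.gradient(phase) * z.fs / (2 * np.pi)
    ia = np.abs(z.z)
    return if_hz, ia


def _symmetric_window(kind: str, length: int) -> np.ndarray:
    if kind == "hanning":
        return signal.windows.hann(length, sym=True)
    return signal.windows.hamming(length, sym=True)


def _instantaneous_autocorrelation(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """K[n, l] = z(n+l) z*(n-l) with lags in FFT order; zero off the edges."""
    n_samp = len(z)
    lags = np.fft.fftfreq(n_samp, 1.0 / n_samp).astype(int)  # 0..N/2-1,-N/2..-1
    n = np.arange(n_samp)[:, None]
    l = lags[None, :]
    i1 = n + l
    i2 = n - l
    valid = (i1 >= 0) & (i1 < n_samp) & (i2 >= 0) & (i2 < n_samp)
    i1c = np.clip(i1, 0, n_samp - 1)
    i2c = np.clip(i2, 0, n_samp - 1)
    K = np.where(valid, z[i1c] * np.conj(z[i2c]), 0.0 + 0.0j)
    return K, lags


def _time_smooth(K: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Convolve each lag column of K with the (sum-normalized) kernel g."""
    g = g / g.sum()
    return signal.fftconvolve(K, g[:, None], mode="same", axes=0)


def compute_tfd(seg: Segment, spec: TfdKernelSpec | None = None) -> TfImage:
    """Quadratic TFD of a segment's analytic signal under the chosen kernel.

    The output grid has as many frequency bins as the segment has samples,
    covering 0 ... fs/2 (bin width fs / (2 N)), and one column per sample.
    """
    if spec is None:
        spec = TfdKernelSpec()
    x = seg.samples
    n_samp = len(x)
    fs = seg.fs
    wlen = spec.resolved_window_len(fs)
    if spec.kind in ("swvd", "spec", "sepk") and n_samp < 2 * wlen:
        raise ValueError(
            f"segment ({n_samp} samples) shorter than twice the "
            f"smoothing window ({wlen} samples)")

    z = analytic_signal(x, fs).z

    if spec.kind == "spec":
        values = _spectrogram(z, fs, spec)
        freq_axis = np.arange(n_samp) * fs / (2 * n_samp)
        return TfImage(values, fs, freq_axis, spec)

    K, lags = _instantaneous_autocorrelation(z)

    if spec.kind == "wvd":
        pass
    elif spec.kind == "swvd":
        K = _time_smooth(K, _symmetric_window(spec.window_kind, wlen))
    elif spec.kind == "mbd":
        # cosh^(-2*beta) lag-independent time smoothing, normalized to sum 1
        half = n_samp - 1
        m = np.arange(-half, half + 1, dtype=float)
        K = _time_smooth(K, np.cosh(m) ** (-2.0 * spec.mbd_beta))
    elif spec.kind == "gkd":
        # Choi-Williams-type product kernel applied in the Doppler domain:
        # multiply the time-FFT of K by exp(-(theta * l)^2 / sigma).
        theta = 2 * np.pi * np.fft.fftfreq(n_samp)  # rad/sample
        G = np.exp(-np.square(np.outer(theta, lags)) / spec.sigma)
        K = np.fft.ifft(np.fft.fft(K, axis=0) * G, axis=0)
    elif spec.kind == "sepk":
        # separable kernel: Hamming time smoothing x Hanning lag window
        K = _time_smooth(K, _symmetric_window("hamming", wlen))
        w = _symmetric_window("hanning", wlen)
        lag_win = np.zeros(n_samp)
        half_w = (wlen - 1) // 2
        in_range = np.abs(lags) <= half_w
        lag_win[in_range] = w[half_w + lags[in_range]]
        K = K * lag_win[None, :]

    spectrum = np.fft.fft(K, axis=1)  # over lag -> shape (time, freq)
    resid = np.abs(spectrum.imag).max()
    scale_ref = max(np.abs(spectrum.real).max(), np.finfo(float).tiny)
    if resid > 1e-8 * scale_ref:
        raise AssertionError(
            f"TFD imaginary residue {resid:.3e} exceeds tolerance")
    values = spectrum.real.T * (2.0 / fs)
    freq_axis = np.arange(n_samp) * fs / (2 * n_samp)
    return TfImage(values, fs, freq_axis, spec)


def _spectrogram(z: np.ndarray, fs: float, spec: TfdKernelSpec) -> np.ndarray:
    """|STFT|^2 on the same (N freq bins x N samples) grid as the lag TFDs."""
    n_samp = len(z)
    wlen = spec.resolved_window_len(fs)
    w = _symmetric_window(spec.window_kind, wlen)
    half = (wlen - 1) // 2
    zp = np.pad(z, (half, half))
    frames = np.lib.stride_tricks.sliding_window_view(zp, wlen) * w
    # FFT length 2N so bins line up with the lag-TFD axis f_k = k fs / (2N)
    spec_mat = np.fft.fft(frames, n=2 * n_samp, axis=1)[:, :n_samp]
    values = (np.abs(spec_mat) ** 2).T
    return values * (2.0 / fs) / np.sum(w ** 2)


def tf_to_image(tf: TfImage | np.ndarray, n_gray_levels: int = 8) -> np.ndarray:
    """Min-max quantize a TF matrix to integer gray levels 0..G-1.

    Rounds half up; a constant input maps to the all-zero image.
    """
    if n_gray_levels < 2:
        raise ValueError("need at least 2 gray levels")
    vals = tf.values if isinstance(tf, TfImage) else np.asarray(tf, dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.zeros(vals.shape, dtype=np.intp)
    scaled = (vals - lo) / (hi - lo) * (n_gray_levels - 1)
    return np.floor(scaled + 0.5).astype(np.intp)


def extract_components(tf: TfImage, rel_threshold: float = 0.3,
                       connectivity: int = 8) -> list[TfComponent]:
    """Find connected TF ridges and their instantaneous-frequency tracks.

    Pixels at or above ``rel_threshold * max`` that are local maxima along
    the frequency axis are grouped into connected components (4- or
    8-connectivity); each component carries a per-time argmax IF polyline.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must lie in (0, 1)")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    vals = tf.values
    peak = vals.max()
    if peak <= 0:
        return []
    above = vals >= rel_threshold * peak
    up = np.empty_like(vals)
    down = np.empty_like(vals)
    up[1:] = vals[1:] >= vals[:-1]
    up[0] = True
    down[:-1] = vals[:-1] >= vals[1:]
    down[-1] = True
    mask = above & up.astype(bool) & down.astype(bool)

    structure = (np.ones((3, 3), dtype=int) if connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labels, n_comp = ndimage.label(mask, structure=structure)
    components: list[TfComponent] = []
    for c in range(1, n_comp + 1):
        fidx, tidx = np.nonzero(labels == c)
        pixels = list(zip(tidx.tolist(), fidx.tolist()))
        track = []
        for t in np.unique(tidx):
            sel = tidx == t
            f_best = fidx[sel][np.argmax(vals[fidx[sel], t])]
            track.append((t / tf.fs, tf.freq_axis[f_best]))
        peak_energy = float(vals[fidx, tidx].max())
        components.append(TfComponent(pixels, np.array(track), peak_energy))
    return components
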