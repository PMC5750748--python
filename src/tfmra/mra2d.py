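"""Two-dimensional multi-resolution analysis of time-frequency images.

Two transforms operate on a TF image:

* a separable 2D discrete wavelet transform (Haar, 4 levels by default),
  giving 3N+1 coefficient matrices, via PyWavelets with periodization so
  sub-band shapes halve exactly per level; and
* a discrete curvelet transform implemented as a Parseval tight frame of
  frequency-domain wedges with parabolic scaling (the number of orientations
  doubles every other scale) computed via wrapping: each smoothly windowed
  wedge of the 2D FFT is wrapped (modular re-indexing, chosen collision-free
  per wedge) onto a small rectangle and inverse-transformed.  Because the
  squared windows sum to one at every frequency and the wrapping is
  injective on each wedge's support, the adjoint reconstructs the input
  exactly and total coefficient energy equals image energy (Parseval).

Curvelets at angle theta and theta + pi are complex conjugates of each other
for real input, so half of the orientation sub-bands at the middle scales
carry no extra information; ``select_subbands`` keeps the coarse scale, the
first half of the wedges at the middle scales, and the finest scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

ORIENTATIONS = ("horizontal", "vertical", "diagonal")


# ---------------------------------------------------------------------------
# 2D discrete wavelet transform (separable, PyWavelets backend)
# ---------------------------------------------------------------------------

@dataclass
class WaveletDecomposition:
    """Multilevel separable 2D DWT: one approximation + 3 details per level.

    ``details`` holds (level, orientation, matrix) triples ordered coarsest
    (level = ``levels``) to finest (level = 1); at level k a matrix has shape
    ceil(rows / 2^k) x ceil(cols / 2^k).
    """

    approximation: np.ndarray
    details: list[tuple[int, str, np.ndarray]]
    levels: int
    wavelet_name: str
    input_shape: tuple[int, int]

    @property
    def n_matrices(self) -> int:
        return 3 * self.levels + 1

    def matrices(self) -> list[np.ndarray]:
        """Approximation first, then details by (level desc, orientation)."""
        return [self.approximation] + [m for _, _, m in self.details]


def dwt2(image: np.ndarray, levels: int = 4,
         wavelet: str = "haar") -> WaveletDecomposition:
    """Separable 2D DWT (rows then columns per level, recursing on LL)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if min(image.shape) < 2 ** levels:
        raise ValueError(
            f"image {image.shape} too small for {levels} levels "
            f"(needs both dims >= {2 ** levels})")
    coeffs = pywt.wavedec2(image, wavelet, mode="periodization", level=levels)
    approx = coeffs[0]
    details: list[tuple[int, str, np.ndarray]] = []
    # pywt orders detail tuples coarsest -> finest as (cH, cV, cD)
    for i, (ch, cv, cd) in enumerate(coeffs[1:]):
        level = levels - i
        details.append((level, "horizontal", ch))
        details.append((level, "vertical", cv))
        details.append((level, "diagonal", cd))
    return WaveletDecomposition(approx, details, levels, wavelet, image.shape)


def idwt2(dec: WaveletDecomposition) -> np.ndarray:
    """Exact synthesis inverse of :func:`dwt2`."""
    by_level: dict[int, dict[str, np.ndarray]] = {}
    for level, orient, mat in dec.details:
        by_level.setdefault(level, {})[orient] = mat
    coeffs: list = [dec.approximation]
    for level in range(dec.levels, 0, -1):
        d = by_level.get(level, {})
        if set(d) != set(ORIENTATIONS):
            raise ValueError(f"level {level} is missing detail orientations")
        ref_shape = d["horizontal"].shape
        if any(d[o].shape != ref_shape for o in ORIENTATIONS):
            raise ValueError(f"level {level} sub-band shape mismatch")
        coeffs.append((d["horizontal"], d["vertical"], d["diagonal"]))
    out = pywt.waverec2(coeffs, dec.wavelet_name, mode="periodization")
    return out[: dec.input_shape[0], : dec.input_shape[1]]


# ---------------------------------------------------------------------------
# Discrete curvelet transform via wrapping
# ---------------------------------------------------------------------------

@dataclass
class CurveletDecomposition:
    """Scale/orientation-indexed curvelet coefficients.

    ``scales[0]`` is the single coarse (isotropic low-pass) matrix,
    ``scales[j]`` for middle j is a list of per-wedge complex matrices, and
    ``scales[-1]`` is the single finest (isotropic high-pass) matrix.
    """

    scales: list
    n_scales: int
    n_angles_scale2: int
    input_shape: tuple[int, int]

    @property
    def wedge_counts(self) -> list[int]:
        return [1 if j in (0, self.n_scales - 1) else len(self.scales[j])
                for j in range(self.n_scales)]

    def all_matrices(self) -> list[np.ndarray]:
        out = []
        for j, s in enumerate(self.scales):
            if j in (0, self.n_scales - 1):
                out.append(s)
            else:
                out.extend(s)
        return out


def wedge_counts(n_scales: int, n_angles_scale2: int) -> list[int]:
    """[1, A, 2A, 2A, 4A, ...]: orientations double every other scale;
    coarsest and finest scales are single isotropic bands."""
    counts = [1]
    for j in range(2, n_scales):
        counts.append(n_angles_scale2 * 2 ** ((j - 2 + 1) // 2))
    counts.append(1)
    return counts


def _smooth_step(t: np.ndarray) -> np.ndarray:
    """C-infinity ramp: 0 for t<=0, 1 for t>=1."""
    t = np.clip(t, 0.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        a = np.where(t > 0, np.exp(-1.0 / np.where(t > 0, t, 1.0)), 0.0)
        b = np.where(t < 1, np.exp(-1.0 / np.where(t < 1, 1.0 - t, 1.0)), 0.0)
    return a / (a + b)


def _rise(t: np.ndarray) -> np.ndarray:
    return np.sin(0.5 * np.pi * _smooth_step(t))


def _fall(t: np.ndarray) -> np.ndarray:
    return np.cos(0.5 * np.pi * _smooth_step(t))


def _radial_windows(r: np.ndarray, n_scales: int) -> list[np.ndarray]:
    """Meyer-type radial partition: sum over scales of window^2 == 1.

    Dyadic band edges a_j = 2^(j - n_scales); scale j occupies roughly
    [a_{j-1}/2, a_j] with smooth square-summing transitions.
    """
    a = [2.0 ** (j - n_scales) for j in range(1, n_scales)]
    wins = []
    for j in range(1, n_scales + 1):
        if j == 1:
            w = _fall((r - a[0] / 2) / (a[0] / 2))
        elif j < n_scales:
            lo, hi = a[j - 2], a[j - 1]
            w = _rise((r - lo / 2) / (lo / 2)) * _fall((r - hi / 2) / (hi / 2))
        else:
            lo = a[-1]
            w = _rise((r - lo / 2) / (lo / 2))
        wins.append(w)
    return wins


def _angular_window(theta: np.ndarray, wedge: int, n_wedges: int) -> np.ndarray:
    """Wedge window on the circle; adjacent squared windows sum to one.

    Wedge 0 is centered due "north" (theta = pi/2, the top quadrant); wedge
    index increases with angle.  Support spans two nominal wedge widths.
    """
    delta = 2 * np.pi / n_wedges
    start = np.pi / 2 - delta / 2 + wedge * delta
    u = np.mod(theta - start + np.pi, 2 * np.pi) - np.pi
    u = u / delta
    out = np.zeros_like(theta)
    rising = (u >= -0.5) & (u <= 0.5)
    falling = (u > 0.5) & (u <= 1.5)
    out[rising] = _rise(u[rising] + 0.5)
    out[falling] = _fall(u[falling] - 0.5)
    return out


def _reflect_idx(idx: np.ndarray, n: int) -> np.ndarray:
    """Index of -xi on the fftshifted grid (xi=0 sits at index n//2)."""
    return (2 * (n // 2) - idx) % n


class _Wedge:
    """One frequency wedge: support indices, window values, wrap geometry."""

    __slots__ = ("rows", "cols", "win", "wrows", "wcols", "shape")

    def __init__(self, rows, cols, win, wrap_shape):
        self.rows, self.cols, self.win = rows, cols, win
        L1, L2 = wrap_shape
        self.wrows = (rows - rows.min()) % L1
        self.wcols = (cols - cols.min()) % L2
        self.shape = (L1, L2)


def _collision_free_shape(rows: np.ndarray, cols: np.ndarray) -> tuple[int, int]:
    """Smallest-ish rectangle onto which (rows, cols) wrap injectively.

    Starts from the support bounding box and greedily shrinks each dimension
    while the modular map stays one-to-one, so wrapped wedges stay exactly
    invertible.
    """
    r0, c0 = rows - rows.min(), cols - cols.min()
    L1, L2 = int(r0.max()) + 1, int(c0.max()) + 1

    def injective(l1: int, l2: int) -> bool:
        keys = (r0 % l1).astype(np.int64) * l2 + (c0 % l2)
        return len(np.unique(keys)) == len(keys)

    changed = True
    while changed:
        changed = False
        if L1 > 2 and injective(L1 - 1, L2):
            L1 -= 1
            changed = True
        if L2 > 2 and injective(L1, L2 - 1):
            L2 -= 1
            changed = True
    return L1, L2


@lru_cache(maxsize=8)
def _curvelet_system(shape: tuple[int, int], n_scales: int,
                     n_angles_scale2: int) -> list:
    """Precompute all wedge windows / wrap maps for an image shape."""
    n1, n2 = shape
    xi1 = np.fft.fftshift(np.fft.fftfreq(n1))[:, None]
    xi2 = np.fft.fftshift(np.fft.fftfreq(n2))[None, :]
    r = np.maximum(2 * np.abs(xi1), 2 * np.abs(xi2))  # 1 at the box edge
    theta = np.arctan2(np.broadcast_to(xi1, (n1, n2)),
                       np.broadcast_to(xi2, (n1, n2)))
    radial = _radial_windows(r, n_scales)
    counts = wedge_counts(n_scales, n_angles_scale2)

    system: list = []
    for j in range(n_scales):
        scale_wedges = []
        if counts[j] == 1:
            W = np.where(radial[j] > 1e-12, radial[j], 0.0)
            rows, cols = np.nonzero(W > 0)
            win = W[rows, cols]
            if j == 0:
                wrap = (int(rows.max() - rows.min()) + 1,
                        int(cols.max() - cols.min()) + 1)
            else:  # finest band touches the grid edge; keep full size
                wrap = (n1, n2)
            scale_wedges.append(_Wedge(rows, cols, win, wrap))
        else:
            half = counts[j] // 2
            first_half: list[_Wedge] = []
            for ell in range(half):
                W = radial[j] * _angular_window(theta, ell, counts[j])
                W = np.where(W > 1e-12, W, 0.0)
                rows, cols = np.nonzero(W > 0)
                win = W[rows, cols]
                wrap = _collision_free_shape(rows, cols)
                first_half.append(_Wedge(rows, cols, win, wrap))
            scale_wedges.extend(first_half)
            # theta + pi partners: point-reflect the support so that for a
            # real image the partner's coefficients are conjugate-mirrored
            for ell in range(half):
                w0 = first_half[ell]
                rows = _reflect_idx(w0.rows, n1)
                cols = _reflect_idx(w0.cols, n2)
                wedge = _Wedge(rows, cols, w0.win, w0.shape)
                wedge.wrows, wedge.wcols = w0.wrows, w0.wcols
                scale_wedges.append(wedge)
        system.append(scale_wedges)
    return system


def fdct_wrapping(image: np.ndarray, n_scales: int = 5,
                  n_angles_scale2: int = 8) -> CurveletDecomposition:
    """Forward discrete curvelet transform via wrapping.

    The image's centered 2D FFT is multiplied by each wedge window; the
    wedge is wrapped onto its small rectangle and inverse-FFT'd (unitary
    norms throughout), yielding complex curvelet coefficients.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 32:
        raise ValueError("image must be 2D and at least 32x32")
    if n_scales < 3:
        raise ValueError("need at least 3 scales")
    if n_angles_scale2 % 4 != 0 or n_angles_scale2 < 4:
        raise ValueError("n_angles_scale2 must be a positive multiple of 4")
    X = np.fft.fftshift(np.fft.fft2(image, norm="ortho"))
    system = _curvelet_system(image.shape, n_scales, n_angles_scale2)
    scales: list = []
    for j, wedges in enumerate(system):
        coeffs = []
        for w in wedges:
            wrapped = np.zeros(w.shape, dtype=complex)
            wrapped[w.wrows, w.wcols] = w.win * X[w.rows, w.cols]
            coeffs.append(np.fft.ifft2(wrapped, norm="ortho"))
        scales.append(coeffs[0] if len(wedges) == 1 else coeffs)
    return CurveletDecomposition(scales, n_scales, n_angles_scale2,
                                 image.shape)


def ifdct_wrapping(dec: CurveletDecomposition) -> np.ndarray:
    """Inverse (= adjoint, the frame being Parseval) curvelet transform."""
    n1, n2 = dec.input_shape
    system = _curvelet_system((n1, n2), dec.n_scales, dec.n_angles_scale2)
    expected = wedge_counts(dec.n_scales, dec.n_angles_scale2)
    if dec.wedge_counts != expected:
        raise ValueError(
            f"wedge counts {dec.wedge_counts} != expected {expected}")
    X = np.zeros((n1, n2), dtype=complex)
    for j, wedges in enumerate(system):
        mats = [dec.scales[j]] if expected[j] == 1 else dec.scales[j]
        for w, c in zip(wedges, mats):
            if c.shape != w.shape:
                raise ValueError(
                    f"scale {j} coefficient shape {c.shape} != {w.shape}")
            F = np.fft.fft2(c, norm="ortho")
            X[w.rows, w.cols] += w.win * F[w.wrows, w.wcols]
    img = np.fft.ifft2(np.fft.ifftshift(X), norm="ortho")
    return img.real


def select_subbands(dec: CurveletDecomposition) -> list[np.ndarray]:
    """The 22 informative sub-bands of a 5-scale / 8-angle decomposition.

    Keeps the coarse scale, the first half of the wedges at scales 2-4
    (their theta + pi partners are redundant for real input), and the finest
    scale: 1 + 4 + 8 + 8 + 1 = 22 matrices, ordered coarse to fine.
    """
    expected = [1, dec.n_angles_scale2, 2 * dec.n_angles_scale2,
                2 * dec.n_angles_scale2, 1]
    if dec.n_scales != 5 or dec.wedge_counts != expected:
        raise ValueError(
            f"expected 5 scales with wedge counts {expected}, got "
            f"{dec.wedge_counts}")
    out = [dec.scales[0]]
    for j in (1, 2, 3):
        wedges = dec.scales[j]
        out.extend(wedges[: len(wedges) // 2])
    out.append(dec.scales[4])
    return out


def subband_labels(n_angles_scale2: int = 8) -> list[tuple[int, int]]:
    """(scale, wedge) labels matching :func:`select_subbands` output order."""
    labels = [(1, 0)]
    for scale, count in ((2, n_angles_scale2), (3, 2 * n_angles_scale2),
                         (4, 2 * n_angles_scale2)):
        labels.extend((scale, w) for w in range(count // 2))
    labels.append((5, 0))
    return labels


def resize_tf_image(values: np.ndarray, shape: tuple[int, int] = (256, 256)
                    ) -> np.ndarray:
    """Bilinear resize so MRA input shape is segment-length independent."""
    from skimage.transform import resize

    return resize(np.asarray(values, dtype=float), shape, order=1,
                  mode="reflect", anti_aliasing=False)
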