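"""Per-sub-band texture and moment features, and the assembled vectors.

Every coefficient matrix (curvelet wedge, wavelet sub-band, or raw TF image)
contributes an 8-feature block: four gray-level co-occurrence matrix (GLCM)
properties -- contrast, correlation, energy, homogeneity --

    contrast    = sum_{k,l} |k-l|^2 p(k,l)
    correlation = sum_{k,l} (k-mu_k)(l-mu_l) p(k,l) / (sigma_k sigma_l)
    energy      = sum_{k,l} p(k,l)^2
    homogeneity = sum_{k,l} p(k,l) / (1 + |k-l|)

plus four statistical moments (mean, variance, skewness, Pearson kurtosis).
The curvelet path uses coefficient magnitudes for the GLCM quantization and
real parts for the moments.  Vectors: 8 x 22 = 176 (curvelet),
8 x 13 = 104 (4-level 2D wavelet), and an 18-dim 1D-DWT baseline
(6 sub-bands x {average power, mean, standard deviation}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .mra2d import WaveletDecomposition, subband_labels
from .preprocess import Segment
from .tfd import tf_to_image

DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
GLCM_FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity")
MOMENT_FEATURE_NAMES = ("mean", "variance", "skewness", "kurtosis")
BLOCK_FEATURE_NAMES = GLCM_FEATURE_NAMES + MOMENT_FEATURE_NAMES


@dataclass
class Glcm:
    """Normalized symmetric gray-level co-occurrence matrix."""

    counts: np.ndarray
    n_gray_levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool = True

    def __post_init__(self) -> None:
        total = self.counts.sum()
        if total > 0 and abs(total - 1.0) > 1e-12:
            raise ValueError("GLCM must be normalized to sum 1")
        if (self.counts < 0).any():
            raise ValueError("GLCM entries must be nonnegative")


@dataclass
class FeatureVector:
    """Named per-segment feature values."""

    values: np.ndarray
    names: list[str]
    segment_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.names):
            raise ValueError(
                f"{len(self.values)} values but {len(self.names)} names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def cooccurrence(image: np.ndarray, n_gray_levels: int,
                 offset: tuple[int, int], symmetric: bool = True) -> np.ndarray:
    """Normalized co-occurrence matrix of an integer image for one offset.

    ``offset`` is (dy, dx): pixel (r, c) is paired with (r+dy, c+dx); with
    ``symmetric`` both orderings of each pair are counted.
    """
    img = np.asarray(image)
    dy, dx = offset
    rows, cols = img.shape
    r0 = slice(max(0, -dy), min(rows, rows - dy))
    c0 = slice(max(0, -dx), min(cols, cols - dx))
    r1 = slice(max(0, dy), min(rows, rows + dy))
    c1 = slice(max(0, dx), min(cols, cols + dx))
    a = img[r0, c0].ravel()
    b = img[r1, c1].ravel()
    counts = np.zeros((n_gray_levels, n_gray_levels))
    np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_properties(p: np.ndarray) -> tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity) of a normalized GLCM."""
    g = p.shape[0]
    k = np.arange(g)[:, None]
    l = np.arange(g)[None, :]
    contrast = float((np.abs(k - l) ** 2 * p).sum())
    energy = float((p ** 2).sum())
    homogeneity = float((p / (1.0 + np.abs(k - l))).sum())
    mu_k = float((k * p).sum())
    mu_l = float((l * p).sum())
    var_k = float(((k - mu_k) ** 2 * p).sum())
    var_l = float(((l - mu_l) ** 2 * p).sum())
    if var_k <= 0 or var_l <= 0:
        correlation = 1.0  # degenerate single-level image
    else:
        correlation = float(
            (((k - mu_k) * (l - mu_l) * p).sum())
            / np.sqrt(var_k * var_l))
    return contrast, correlation, energy, homogeneity


def glcm_features(matrix: np.ndarray, n_gray_levels: int = 8,
                  offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
                  ) -> tuple[float, float, float, float]:
    """Four GLCM texture properties of a real matrix, averaged over offsets.

    The matrix is min-max quantized to ``n_gray_levels`` gray levels first; a
    constant matrix yields the degenerate (0, 1, 1, 1).
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite input matrix")
    img = tf_to_image(matrix, n_gray_levels)
    per_offset = [
        glcm_properties(cooccurrence(img, n_gray_levels, off, symmetric=True))
        for off in offsets
    ]
    return tuple(float(np.mean(v)) for v in zip(*per_offset))


def moment_features(matrix: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, Pearson kurtosis) of the flattened values.

    Population moments; a zero-variance input yields skewness 0 and kurtosis
    0 by convention so constant sub-bands stay finite.
    """
    x = np.asarray(matrix, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 elements")
    mean = float(x.mean())
    var = float(x.var())
    if var <= 0:
        return mean, 0.0, 0.0, 0.0
    centered = x - mean
    skew = float((centered ** 3).mean() / var ** 1.5)
    kurt = float((centered ** 4).mean() / var ** 2)
    return mean, var, skew, kurt


def _block(matrix: np.ndarray, n_gray_levels: int,
           offsets: tuple[tuple[int, int], ...]) -> list[float]:
    """8-feature block: GLCM on magnitudes, moments on real parts."""
    mat = np.asarray(matrix)
    glcm_vals = glcm_features(np.abs(mat), n_gray_levels, offsets)
    mom_vals = moment_features(mat.real if np.iscomplexobj(mat) else mat)
    return list(glcm_vals) + list(mom_vals)


def curvelet_feature_vector(selected: list[np.ndarray],
                            n_gray_levels: int = 8,
                            offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
                            segment_label: str | None = None) -> FeatureVector:
    """176-dim vector: 8 features per each of the 22 selected sub-bands."""
    if len(selected) != 22:
        raise ValueError(f"expected 22 selected sub-bands, got {len(selected)}")
    labels = subband_labels()
    values: list[float] = []
    names: list[str] = []
    for (scale, wedge), mat in zip(labels, selected):
        values.extend(_block(mat, n_gray_levels, offsets))
        names.extend(f"scale{scale}_wedge{wedge}_{f}"
                     for f in BLOCK_FEATURE_NAMES)
    return FeatureVector(np.array(values), names, segment_label)


def wavelet_feature_vector(dec: WaveletDecomposition,
                           n_gray_levels: int = 8,
                           offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
                           segment_label: str | None = None) -> FeatureVector:
    """104-dim vector: 8 features per each of the 13 sub-bands (4 levels).

    Block order: approximation first, then details by (level, orientation),
    coarsest level first.
    """
    if dec.levels != 4:
        raise ValueError(f"expected a 4-level decomposition, got {dec.levels}")
    values: list[float] = []
    names: list[str] = []
    values.extend(_block(dec.approximation, n_gray_levels, offsets))
    names.extend(f"approx_{f}" for f in BLOCK_FEATURE_NAMES)
    for level, orient, mat in dec.details:
        values.extend(_block(mat, n_gray_levels, offsets))
        names.extend(f"level{level}_{orient}_{f}" for f in BLOCK_FEATURE_NAMES)
    return FeatureVector(np.array(values), names, segment_label)


def dwt1d_baseline_features(seg: Segment, levels: int = 5,
                            wavelet: str = "db4") -> FeatureVector:
    """18-dim 1D-DWT baseline: per sub-band average power, mean, std.

    Five-level 1D DWT (Daubechies-4, periodization) of the raw segment gives
    one approximation plus five detail bands; each contributes the mean of
    squared coefficients, the mean, and the standard deviation.
    """
    if seg.n_samples < 2 ** levels:
        raise ValueError(
            f"segment of {seg.n_samples} samples too short for "
            f"{levels}-level DWT")
    coeffs = pywt.wavedec(seg.samples, wavelet, mode="periodization",
                          level=levels)
    band_names = [f"approx{levels}"] + [
        f"detail{levels - i}" for i in range(levels)]
    values: list[float] = []
    names: list[str] = []
    for band, c in zip(band_names, coeffs):
        values.extend([float(np.mean(c ** 2)), float(np.mean(c)),
                       float(np.std(c))])
        names.extend(f"{band}_{f}" for f in ("avg_power", "mean", "std"))
    return FeatureVector(np.array(values), names, seg.label)
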