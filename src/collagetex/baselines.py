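"""Comparison texture-feature banks: Haralick, Gabor, and HOG.

These are the classical descriptors the CoLlAGe maps are benchmarked
against.  Each bank produces one row of lesion-level features: per-pixel
values are collapsed to a single number per feature by the median across
ROI pixels (robust to lesion-size and outlier effects).

Bank sizes follow the tabulated configuration: 13 co-occurrence statistics
x 4 window sizes = 52 Haralick features; 6 frequencies x 8 orientations x
9 variance settings = 432 Gabor filters; HOG histograms at
v in {10, 15, 20, 25, 30} bins (bin width 360/v degrees).  The HOG bank's
declared size is kept configurable because tabulations of this bank
conventionally count it as a round 100.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import compute_gradient_field
from .errors import ConfigError, EmptyROIError
from .io_roi import ImageScene, ROIMask

__all__ = [
    "BaselineConfig",
    "GaborFilter",
    "LesionFeatureRow",
    "HARALICK_STAT_NAMES",
    "build_gabor_bank",
    "gabor_response_features",
    "haralick_statistics",
    "haralick_feature_map",
    "hog_feature_vector",
    "aggregate_lesion_feature",
    "bank_sizes",
]

HARALICK_STAT_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_corr_1",
    "info_measure_corr_2",
)


@dataclass(frozen=True)
class BaselineConfig:
    """Parameter grids of the comparison banks.

    ``gabor_frequencies`` are spatial frequencies in cycles/pixel derived
    from the six frequency-shift settings; ``gabor_orientations`` are the 8
    angles k*22.5 degrees; ``gabor_sigmas`` the 9 envelope variance
    settings.  ``hog_v_grid`` are the histogram bin counts with bin width
    360/v degrees.  ``hog_bank_size`` is the declared size of the full HOG
    bank used in bank-total arithmetic.
    """

    haralick_window_sizes: tuple[int, ...] = (3, 5, 7, 9)
    haralick_levels: int = 64
    gabor_frequencies: tuple[float, ...] = (
        1 / 32,
        1 / 16,
        3 / 32,
        1 / 8,
        3 / 16,
        1 / 4,
    )
    gabor_orientations: tuple[float, ...] = tuple(
        k * math.pi / 8 for k in range(8)
    )
    gabor_sigmas: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
    hog_v_grid: tuple[int, ...] = (10, 15, 20, 25, 30)
    hog_bank_size: int = 100

    def __post_init__(self) -> None:
        for name in (
            "haralick_window_sizes",
            "gabor_frequencies",
            "gabor_orientations",
            "gabor_sigmas",
            "hog_v_grid",
        ):
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"{name} grid is empty")
        if self.haralick_levels < 2:
            raise ConfigError("haralick_levels must be >= 2")
        for v in self.hog_v_grid:
            if (360.0 / v) * v != 360.0:
                raise ConfigError(f"hog bin width 360/{v} is not exact")


@dataclass
class GaborFilter:
    """A complex Gabor kernel with its grid parameters."""

    kernel: np.ndarray  # complex
    frequency: float
    orientation: float
    sigma: float

    @property
    def name(self) -> str:
        return (
            f"gabor_f{self.frequency:.4f}_o{math.degrees(self.orientation):.1f}"
            f"_s{self.sigma:.1f}"
        )


@dataclass
class LesionFeatureRow:
    """One lesion's features from one descriptor bank."""

    identifier: str
    group_id: str
    descriptor: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != len(self.values):
            raise ConfigError(
                f"{len(self.values)} values for {len(self.names)} names"
            )


def bank_sizes(config: BaselineConfig | None = None) -> dict[str, int]:
    """Feature-count arithmetic of the comparison banks.

    haralick = 13 statistics x len(window grid); gabor = product of the
    three grid sizes; hog = declared bank size; total = their sum.
    """
    config = config or BaselineConfig()
    sizes = {
        "haralick": len(HARALICK_STAT_NAMES) * len(config.haralick_window_sizes),
        "gabor": len(config.gabor_frequencies)
        * len(config.gabor_orientations)
        * len(config.gabor_sigmas),
        "hog": config.hog_bank_size,
    }
    sizes["total"] = sum(sizes.values())
    return sizes


# ---------------------------------------------------------------------------
# Gabor


def build_gabor_bank(config: BaselineConfig | None = None) -> list[GaborFilter]:
    """One complex filter per element of the frequency x orientation x
    variance Cartesian product."""
    from skimage.filters import gabor_kernel

    config = config or BaselineConfig()
    bank = []
    for f in config.gabor_frequencies:
        for o in config.gabor_orientations:
            for s in config.gabor_sigmas:
                k = gabor_kernel(frequency=f, theta=o, sigma_x=s, sigma_y=s)
                bank.append(
                    GaborFilter(np.asarray(k), frequency=f, orientation=o, sigma=s)
                )
    return bank


def gabor_response_features(
    scene: ImageScene, mask: ROIMask, bank: list[GaborFilter]
) -> LesionFeatureRow:
    """Median ROI response magnitude per filter.

    Each filter is convolved with the image (real and imaginary parts
    separately, replicate boundaries); the per-pixel magnitude
    ``sqrt(real^2 + imag^2)`` is aggregated over the ROI by the median.
    """
    mask.check_aligned(scene)
    img = scene.intensities
    values = np.empty(len(bank))
    for i, filt in enumerate(bank):
        re = ndimage.convolve(img, np.real(filt.kernel), mode="nearest")
        im = ndimage.convolve(img, np.imag(filt.kernel), mode="nearest")
        mag = np.hypot(re, im)
        values[i] = aggregate_lesion_feature(mag[mask.membership])
    return LesionFeatureRow(
        scene.identifier,
        mask.group_id,
        "gabor",
        tuple(f.name for f in bank),
        values,
    )


# ---------------------------------------------------------------------------
# Haralick


def _quantize(img: np.ndarray, roi: np.ndarray, levels: int) -> np.ndarray:
    """Quantize intensities to ``levels`` gray levels on the ROI range.

    Using the ROI range makes the statistics invariant to adding a constant
    to all intensities.  Values outside the ROI range clip into the end
    bins.
    """
    vals = img[roi]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def haralick_statistics(P: np.ndarray) -> np.ndarray:
    """The 13 classical second-order statistics of a normalized GLCM ``P``.

    ``P[i, j]`` is the joint probability of gray levels ``(i, j)`` at the
    configured displacement.  Logarithms are base 2; degenerate
    denominators (zero variance, zero marginal entropy) yield 0 for the
    affected statistic.
    """
    P = np.asarray(P, dtype=np.float64)
    n = P.shape[0]
    i, j = np.indices(P.shape)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = (np.arange(n) * px).sum()
    my = (np.arange(n) * py).sum()
    sx = math.sqrt(((np.arange(n) - mx) ** 2 * px).sum())
    sy = math.sqrt(((np.arange(n) - my) ** 2 * py).sum())

    def _ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    # p_{x+y}(k), k=0..2n-2 and p_{x-y}(k), k=0..n-1
    psum = np.bincount((i + j).ravel(), weights=P.ravel(), minlength=2 * n - 1)
    pdiff = np.bincount(
        np.abs(i - j).ravel(), weights=P.ravel(), minlength=n
    )
    ks = np.arange(2 * n - 1)
    kd = np.arange(n)

    asm = float((P**2).sum())
    contrast = float((kd**2 * pdiff).sum())
    corr = 0.0
    if sx > 0 and sy > 0:
        corr = float(((i * j * P).sum() - mx * my) / (sx * sy))
    variance = float(((i - mx) ** 2 * P).sum())
    idm = float((P / (1.0 + (i - j) ** 2)).sum())
    sum_avg = float((ks * psum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * psum).sum())
    sum_ent = _ent(psum)
    ent = _ent(P.ravel())
    diff_avg = float((kd * pdiff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * pdiff).sum())
    diff_ent = _ent(pdiff)
    # information measures of correlation
    hx, hy = _ent(px), _ent(py)
    with np.errstate(divide="ignore"):
        lpxy = np.where(px[:, None] * py[None, :] > 0,
                        np.log2(np.maximum(px[:, None] * py[None, :], 1e-300)),
                        0.0)
    hxy1 = float(-(P * lpxy).sum())
    hxy2 = float(-((px[:, None] * py[None, :]) * lpxy).sum())
    denom = max(hx, hy)
    imc1 = (ent - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - ent))))
    return np.array(
        [
            asm,
            contrast,
            corr,
            variance,
            idm,
            sum_avg,
            sum_var,
            sum_ent,
            ent,
            diff_var,
            diff_ent,
            imc1,
            imc2,
        ]
    )


def _window_glcm(q: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric distance-1 GLCM of a quantized window, averaged over the
    four directions 0/45/90/135 degrees, normalized."""
    from skimage.feature import graycomatrix

    glcm = graycomatrix(
        q,
        distances=[1],
        angles=[0, math.pi / 4, math.pi / 2, 3 * math.pi / 4],
        levels=levels,
        symmetric=True,
        normed=False,
    )
    counts = glcm[:, :, 0, :].sum(axis=2).astype(np.float64)
    total = counts.sum()
    if total == 0:
        return counts
    return counts / total


def haralick_feature_map(
    scene: ImageScene, mask: ROIMask, config: BaselineConfig | None = None
) -> tuple[np.ndarray, LesionFeatureRow]:
    """Windowed Haralick statistics per ROI pixel and their lesion medians.

    For every window size ``w`` in the grid and every ROI pixel, a
    symmetric distance-1 gray-level co-occurrence matrix is built from the
    ``w x w`` window (clipped at image borders) of the globally quantized
    image, and the 13 statistics are evaluated; the lesion row holds the
    median of each statistic over ROI pixels (13 x len(grid) features).

    Returns
    -------
    maps : array ``(n_features, rows, cols)`` with NaN outside the ROI
    row : the aggregated :class:`LesionFeatureRow`
    """
    config = config or BaselineConfig()
    mask.check_aligned(scene)
    if scene.dims != 2:
        raise ConfigError("haralick_feature_map expects a 2D scene")
    levels = config.haralick_levels
    q = _quantize(scene.intensities, mask.membership, levels)
    coords = np.argwhere(mask.membership)
    n_stats = len(HARALICK_STAT_NAMES)
    n_feat = n_stats * len(config.haralick_window_sizes)
    maps = np.full((n_feat, *scene.shape), np.nan)
    names = []
    for wi, w in enumerate(config.haralick_window_sizes):
        r = w // 2
        names.extend(f"haralick_w{w}_{s}" for s in HARALICK_STAT_NAMES)
        for c in coords:
            sl = tuple(
                slice(max(0, ci - r), min(dim, ci + r + 1))
                for ci, dim in zip(c, scene.shape)
            )
            P = _window_glcm(q[sl], levels)
            stats = haralick_statistics(P)
            maps[wi * n_stats : (wi + 1) * n_stats, c[0], c[1]] = stats
    values = np.array(
        [
            aggregate_lesion_feature(maps[k][mask.membership])
            for k in range(n_feat)
        ]
    )
    row = LesionFeatureRow(
        scene.identifier, mask.group_id, "haralick", tuple(names), values
    )
    return maps, row


# ---------------------------------------------------------------------------
# HOG


def hog_feature_vector(
    scene: ImageScene, mask: ROIMask, v: int,
    config: BaselineConfig | None = None,
) -> LesionFeatureRow:
    """Signed-orientation gradient histogram of the ROI.

    Per-pixel gradient orientations over the full 360-degree range are
    binned into ``v`` equal bins of width 360/v degrees, weighted by
    gradient magnitude, and normalized to sum to 1 — a single ROI-level
    histogram, not the detector-style block layout.  A fully constant ROI
    (zero total magnitude) yields the uniform histogram.
    """
    config = config or BaselineConfig()
    mask.check_aligned(scene)
    if v < 2:
        raise ConfigError("v must be >= 2")
    if v not in config.hog_v_grid:
        warnings.warn(
            f"v={v} is outside the configured grid {config.hog_v_grid}",
            stacklevel=2,
        )
    grads = compute_gradient_field(scene)
    g0 = grads.components[0][mask.membership]
    g1 = grads.components[1][mask.membership]
    ang = np.arctan2(g1, g0)  # 0 along increasing row index
    magnitude = np.hypot(g0, g1)
    width = 2.0 * math.pi / v
    idx = np.clip(np.floor((ang + math.pi) / width).astype(np.int64), 0, v - 1)
    hist = np.bincount(idx, weights=magnitude, minlength=v)
    total = hist.sum()
    hist = np.full(v, 1.0 / v) if total == 0 else hist / total
    return LesionFeatureRow(
        scene.identifier,
        mask.group_id,
        f"hog_v{v}",
        tuple(f"hog_v{v}_bin_{k}" for k in range(v)),
        hist,
    )


def aggregate_lesion_feature(values) -> float:
    """Median of per-pixel feature values across a lesion (even count:
    mean of the central pair)."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise EmptyROIError("no per-pixel values to aggregate")
    return float(np.median(arr))
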