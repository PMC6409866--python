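"""Signal detection, centre-of-mass distances and MS-SSIM* comparisons.

Two complementary quantifications of probe position are provided. At the
single-nucleus level, discrete FISH signals are found by thresholding
within the nucleus and summarised by their intensity-weighted centres of
mass; distances between co-hybridised probes feed Wilcoxon rank-sum
comparisons of probe pairs. At the population level, warped rasters and
composite maps are compared with a multi-scale structural similarity
index (MS-SSIM*), scoring 0 for unrelated and exactly 1 for identical
images. The * variant defines the score at degenerate (zero-variance)
windows — ubiquitous in binarised and composite images — instead of
leaving them 0/0: windows where both images are flat and equal contribute
1, windows where only one image is flat contribute 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import correlate1d
from skimage import measure

from .consensus_mesh import StructuralMismatchError
from .imaging_io import Calibration, ChannelRaster
from .warping import CompositeMap, binarise_signal

log = logging.getLogger(__name__)

#: Canonical per-scale exponents of the 5-scale MS-SSIM.
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
WINDOW_SIZE = 11
WINDOW_SIGMA = 1.5


@dataclass
class SignalDetection:
    """One discrete (8-connected) FISH signal within a nucleus."""

    component_pixels: np.ndarray  # (n, 2) array of (x, y) pixel coords
    centre_of_mass: np.ndarray    # intensity-weighted, (x, y)
    area_um2: float
    probe_label: str
    nucleus_id: str


@dataclass
class SimilarityScore:
    """MS-SSIM* result with the scales and exponents actually used."""

    value: float
    scales_used: int
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"similarity must lie in [0, 1], got {self.value}")

    def __float__(self) -> float:
        return self.value


@dataclass
class PairwiseDistance:
    """Distance between the centres of mass of two co-hybridised probes."""

    nucleus_id: str
    probe_pair: tuple[str, str]
    distance_um: float

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise ValueError("distance must be >= 0")


# ---------------------------------------------------------------------------
# Signal detection and distances
# ---------------------------------------------------------------------------


def detect_signals(
    channel: ChannelRaster | np.ndarray,
    mask: np.ndarray,
    calibration: Calibration,
    threshold: str = "fraction:0.5",
    min_area_um2: float = 0.3,
    probe_label: str = "",
    nucleus_id: str = "",
) -> list[SignalDetection]:
    """Detect discrete signals of one probe within one nucleus.

    The channel is thresholded inside the mask (default: half the in-mask
    maximum), 8-connected components below ``min_area_um2`` are discarded,
    and each surviving component is summarised by its intensity-weighted
    centre of mass.
    """
    pixels = channel.pixels if isinstance(channel, ChannelRaster) else np.asarray(channel)
    binary = binarise_signal(pixels, mask, method=threshold)
    labels = measure.label(binary, connectivity=2)
    mpp2 = calibration.microns_per_pixel**2
    out: list[SignalDetection] = []
    for region in measure.regionprops(labels, intensity_image=pixels.astype(float)):
        area = region.area * mpp2
        if area < min_area_um2:
            continue
        cy, cx = region.centroid_weighted
        coords = np.c_[region.coords[:, 1], region.coords[:, 0]]
        out.append(
            SignalDetection(
                component_pixels=coords,
                centre_of_mass=np.array([cx, cy]),
                area_um2=area,
                probe_label=probe_label,
                nucleus_id=nucleus_id,
            )
        )
    return out


def com_distance(
    a: SignalDetection, b: SignalDetection, cal: Calibration
) -> PairwiseDistance:
    """Euclidean centre-of-mass distance between two signals of one nucleus."""
    if a.nucleus_id != b.nucleus_id:
        raise ValueError(
            f"signals come from different nuclei: {a.nucleus_id!r} vs {b.nucleus_id!r}"
        )
    d = float(np.linalg.norm(a.centre_of_mass - b.centre_of_mass))
    return PairwiseDistance(
        nucleus_id=a.nucleus_id,
        probe_pair=(a.probe_label, b.probe_label),
        distance_um=d * cal.microns_per_pixel,
    )


# ---------------------------------------------------------------------------
# MS-SSIM*
# ---------------------------------------------------------------------------


def _gaussian_kernel(size: int = WINDOW_SIZE, sigma: float = WINDOW_SIGMA) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def _gfilter(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = correlate1d(img, kernel, axis=0, mode="reflect")
    return correlate1d(out, kernel, axis=1, mode="reflect")


def _downsample(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    h2, w2 = h - h % 2, w - w % 2
    v = img[:h2, :w2]
    return 0.25 * (v[0::2, 0::2] + v[1::2, 0::2] + v[0::2, 1::2] + v[1::2, 1::2])


def _ssim_components(
    a: np.ndarray, b: np.ndarray, c1: float, c2: float, kernel: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window luminance and contrast-structure maps with the * rules."""
    mu_a = _gfilter(a, kernel)
    mu_b = _gfilter(b, kernel)
    # variances are left unclamped so that identical inputs give bitwise
    # equal numerator and denominator (and hence a score of exactly 1)
    var_a = _gfilter(a * a, kernel) - mu_a**2
    var_b = _gfilter(b * b, kernel) - mu_b**2
    cov = _gfilter(a * b, kernel) - mu_a * mu_b

    lum_num = 2 * mu_a * mu_b + c1
    lum_den = mu_a**2 + mu_b**2 + c1
    cs_num = 2 * cov + c2
    cs_den = var_a + var_b + c2
    with np.errstate(divide="ignore", invalid="ignore"):
        lum = np.where(lum_den > 0, lum_num / np.where(lum_den > 0, lum_den, 1.0), 0.0)
        cs = np.where(cs_den > 0, cs_num / np.where(cs_den > 0, cs_den, 1.0), 0.0)
    # * rules for degenerate windows (reachable when the stabilising
    # constants are zero): both flat and equal -> 1, one-sided -> 0
    eps = 1e-12
    both_flat = (var_a <= eps) & (var_b <= eps)
    cs = np.where(cs_den <= 0, np.where(both_flat, 1.0, 0.0), cs)
    means_equal = np.abs(mu_a - mu_b) <= eps
    lum = np.where(lum_den <= 0, np.where(means_equal, 1.0, 0.0), lum)
    return lum, cs


def ms_ssim(
    a: np.ndarray,
    b: np.ndarray,
    scales: int = 5,
    weights: tuple[float, ...] = MSSSIM_WEIGHTS,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float | None = None,
) -> SimilarityScore:
    """Multi-scale structural similarity (MS-SSIM*) of two equal-size rasters.

    Contrast/structure terms are computed at each of ``scales`` dyadic
    scales (11x11 Gaussian window, sigma 1.5), the luminance term at the
    coarsest scale only, and combined as a weighted geometric product with
    the canonical exponents. The dynamic range defaults to the maximum
    value of the pair; if the images are too small for the requested
    scales the scale count is reduced with a warning and the exponents
    renormalised. The result is clamped to [0, 1]; identical images score
    exactly 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("ms_ssim expects 2D rasters")
    max_scales = 1
    m = min(a.shape)
    while max_scales < scales and m // 2 >= WINDOW_SIZE:
        m //= 2
        max_scales += 1
    if max_scales < scales:
        log.warning(
            "images of shape %s support only %d of %d scales; reducing",
            a.shape,
            max_scales,
            scales,
        )
        scales = max_scales
    w = np.asarray(weights[:scales], dtype=float)
    w = w / w.sum()
    if dynamic_range is None:
        dynamic_range = float(max(a.max(), b.max()))
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    kernel = _gaussian_kernel()

    value = 1.0
    cur_a, cur_b = a, b
    for s in range(scales):
        lum, cs = _ssim_components(cur_a, cur_b, c1, c2, kernel)
        cs_mean = max(float(cs.mean()), 0.0)
        if s < scales - 1:
            value *= cs_mean ** w[s]
            cur_a = _downsample(cur_a)
            cur_b = _downsample(cur_b)
        else:
            final = max(float((lum * cs).mean()), 0.0)
            value *= final ** w[s]
    return SimilarityScore(
        value=float(np.clip(value, 0.0, 1.0)),
        scales_used=scales,
        weights=tuple(w),
    )


# ---------------------------------------------------------------------------
# Population statistics
# ---------------------------------------------------------------------------


def compare_distance_sets(
    d1: list[PairwiseDistance] | np.ndarray, d2: list[PairwiseDistance] | np.ndarray
) -> dict:
    """Two-sided Wilcoxon rank-sum test between two distance sets.

    Returns group sizes, medians, the Mann-Whitney U statistic and the
    p-value. Groups smaller than 3 are refused.
    """

    def _values(d):
        if len(d) and isinstance(d[0], PairwiseDistance):
            return np.array([x.distance_um for x in d], dtype=float)
        return np.asarray(d, dtype=float)

    x, y = _values(d1), _values(d2)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(
            f"need at least 3 distances per group for a rank-sum test "
            f"(got {len(x)} and {len(y)})"
        )
    # exact null distribution for small untied samples, normal approximation
    # otherwise — the same policy R's wilcox.test follows
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return {
        "n1": len(x),
        "n2": len(y),
        "median1": float(np.median(x)),
        "median2": float(np.median(y)),
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
    }


def similarity_matrix(composites: list[CompositeMap], **ms_kwargs) -> pd.DataFrame:
    """Pairwise MS-SSIM* matrix of composite maps (symmetric, unit diagonal).

    All composites must share a target mesh structure and raster geometry;
    cross-strain comparisons therefore require warping every population
    onto one common template first.
    """
    if not composites:
        raise ValueError("no composites given")
    sigs = {c.target_signature for c in composites}
    if len(sigs) != 1:
        raise StructuralMismatchError(
            "composites target different mesh structures; warp all onto one template"
        )
    shapes = {c.frequencies.shape for c in composites}
    if len(shapes) != 1:
        raise StructuralMismatchError(f"composites have mixed raster shapes: {shapes}")
    labels = [c.probe_label or f"probe_{i}" for i, c in enumerate(composites)]
    n = len(composites)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = ms_ssim(
                composites[i].frequencies, composites[j].frequencies, **ms_kwargs
            ).value
    return pd.DataFrame(mat, index=labels, columns=labels)


def render_similarity_heatmap(matrix: pd.DataFrame, path, cmap: str = "cividis") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(matrix.values, cmap=cmap, vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(len(matrix.index)):
        for j in range(len(matrix.columns)):
            ax.text(j, i, f"{matrix.values[i, j]:.2f}", ha="center", va="center",
                    color="white" if matrix.values[i, j] < 0.6 else "black", fontsize=8)
    fig.colorbar(im, ax=ax, label="MS-SSIM*")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
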