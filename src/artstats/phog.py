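"""Pyramid of Histograms of Orientation Gradients (PHOG) image statistics.

The pipeline computes, for an RGB image, a gradient field in CIE Lab space
(per pixel, the Lab channel with the largest gradient magnitude supplies both
magnitude and orientation), pools magnitude-weighted orientation histograms
over a 4-way recursive spatial subdivision (levels 0-3, i.e. 1/4/16/64
rectangles), and derives four scalar statistics:

self-similarity
    median histogram-intersection similarity between each level-3 subregion
    histogram and the whole-image (level-0) histogram; in [0, 1].
complexity
    mean gradient magnitude over all pixels (Lab units per pixel).
anisotropy
    standard deviation of the normalized bin values pooled over all level-3
    histograms; 0 for orientation-uniform images.
Birkhoff-like measure
    self-similarity / complexity, after Birkhoff's order-over-complexity idea.

Orientations cover the full 360 deg in 16 equal bins. Histograms are
L1-normalized; an all-zero (flat) region is flagged degenerate instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab

N_BINS = 16
BIN_WIDTH_DEG = 360.0 / N_BINS
N_LEVELS = 4  # levels 0..3


@dataclass
class RasterImage:
    """8-bit RGB raster image, the unit of analysis."""

    pixels: np.ndarray  # (H, W, 3) uint8
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"image {self.id!r}: expected H x W x 3 pixels, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.any(px < 0) or np.any(px > 255):
                raise ValueError(f"image {self.id!r}: pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def aspect_ratio(self) -> float:
        """Height over width."""
        return self.height_px / self.width_px


@dataclass
class GradientField:
    """Per-pixel gradient magnitude and orientation (degrees in [0, 360)).

    Zero-magnitude pixels carry the sentinel orientation 0; they contribute
    no mass to any histogram.
    """

    magnitude: np.ndarray
    orientation_deg: np.ndarray

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.orientation_deg.shape:
            raise ValueError("magnitude/orientation shape mismatch")


@dataclass
class OrientationHistogram:
    bins: np.ndarray  # (16,)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.bins.shape}")


@dataclass
class HOGPyramid:
    """Levels 0-3 of magnitude-weighted orientation histograms.

    ``levels[l]`` has shape (4**l, 16), row-major over the 2**l x 2**l
    rectangle grid; ``degenerate[l]`` flags all-zero (unnormalizable) blocks.
    """

    levels: list[np.ndarray] = field(default_factory=list)
    degenerate: list[np.ndarray] = field(default_factory=list)


def preprocess_image(img: RasterImage, pixel_budget: int | None = 100_000) -> RasterImage:
    """Down-sample to ~``pixel_budget`` pixels, preserving aspect ratio.

    Bicubic resampling; ``pixel_budget=None`` returns the image unchanged.
    Images smaller than 16 x 16 are rejected.
    """
    from PIL import Image

    h, w = img.height_px, img.width_px
    if h < 16 or w < 16:
        raise ValueError(f"image {img.id!r} is {h}x{w}; need at least 16x16")
    if pixel_budget is None:
        return img
    if pixel_budget < 256:
        raise ValueError("pixel_budget must be at least 256")
    scale = np.sqrt(pixel_budget / (h * w))
    new_h = max(16, round(h * scale))
    new_w = max(16, round(w * scale))
    if (new_h, new_w) == (h, w):
        return img
    pil = Image.fromarray(img.pixels)
    out = pil.resize((new_w, new_h), Image.BICUBIC)
    return RasterImage(np.asarray(out, dtype=np.uint8), id=img.id)


def _centered_diff(channel: np.ndarray, axis: int) -> np.ndarray:
    # centered differences [-1, 0, 1]/2 with edge replication at the borders
    pad = [(0, 0), (0, 0)]
    pad[axis] = (1, 1)
    p = np.pad(channel, pad, mode="edge")
    if axis == 0:
        return (p[2:, :] - p[:-2, :]) / 2.0
    return (p[:, 2:] - p[:, :-2]) / 2.0


def compute_gradient_field(img: RasterImage) -> GradientField:
    """Lab max-channel gradient field.

    Gradients are computed independently in the L, a and b channels with
    centered differences; for each pixel the channel of maximal magnitude
    supplies both magnitude and orientation.
    """
    lab = rgb2lab(img.pixels)
    mags = np.empty((3,) + lab.shape[:2])
    oris = np.empty_like(mags)
    for c in range(3):
        gy = _centered_diff(lab[:, :, c], axis=0)
        gx = _centered_diff(lab[:, :, c], axis=1)
        mags[c] = np.hypot(gx, gy)
        oris[c] = np.degrees(np.arctan2(gy, gx)) % 360.0
    best = np.argmax(mags, axis=0)
    ii, jj = np.indices(best.shape)
    magnitude = mags[best, ii, jj]
    orientation = oris[best, ii, jj]
    orientation[magnitude == 0] = 0.0  # sentinel
    return GradientField(magnitude=magnitude, orientation_deg=orientation)


def _bin_index(orientation_deg: np.ndarray) -> np.ndarray:
    idx = np.floor(orientation_deg / BIN_WIDTH_DEG).astype(np.intp)
    return np.clip(idx, 0, N_BINS - 1)


def compute_hog(
    field: GradientField,
    region: tuple[int, int, int, int] | None = None,
) -> OrientationHistogram:
    """Magnitude-weighted orientation histogram over ``region`` (r0, r1, c0, c1).

    Bin b accumulates magnitudes of pixels with orientation in
    [b*22.5, (b+1)*22.5) degrees; the histogram is L1-normalized. A region
    with zero total gradient mass is returned unnormalized and flagged
    degenerate.
    """
    if region is None:
        region = (0, field.magnitude.shape[0], 0, field.magnitude.shape[1])
    r0, r1, c0, c1 = region
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty region {region}")
    mag = field.magnitude[r0:r1, c0:c1].ravel()
    ori = field.orientation_deg[r0:r1, c0:c1].ravel()
    hist = np.bincount(_bin_index(ori), weights=mag, minlength=N_BINS)[:N_BINS]
    total = hist.sum()
    if total <= 0:
        return OrientationHistogram(np.zeros(N_BINS), degenerate=True)
    return OrientationHistogram(hist / total, degenerate=False)


def _level_edges(n_pixels: int, n_blocks: int) -> list[tuple[int, int]]:
    # integer division; the last rectangle absorbs remainder pixels
    step = n_pixels // n_blocks
    edges = [(i * step, (i + 1) * step) for i in range(n_blocks)]
    edges[-1] = (edges[-1][0], n_pixels)
    return edges


def build_hog_pyramid(field: GradientField) -> HOGPyramid:
    """Pool the gradient field into level 0-3 orientation histograms.

    The gradient field is computed once globally and pooled per rectangle;
    level l tiles the image with a 2**l x 2**l row-major rectangle grid.
    """
    h, w = field.magnitude.shape
    if h < 8 or w < 8:
        raise ValueError(f"field is {h}x{w}; too small for the 8x8 level-3 partition")
    bin_idx = _bin_index(field.orientation_deg)
    # flat per-pixel code: bin + 16 * block, accumulated in one bincount per level
    pyr = HOGPyramid()
    for level in range(N_LEVELS):
        n = 2**level
        row_id = np.zeros(h, dtype=np.intp)
        for i, (a, b) in enumerate(_level_edges(h, n)):
            row_id[a:b] = i
        col_id = np.zeros(w, dtype=np.intp)
        for j, (a, b) in enumerate(_level_edges(w, n)):
            col_id[a:b] = j
        block = row_id[:, None] * n + col_id[None, :]
        code = block * N_BINS + bin_idx
        flat = np.bincount(code.ravel(), weights=field.magnitude.ravel(), minlength=n * n * N_BINS)
        hists = flat.reshape(n * n, N_BINS)
        totals = hists.sum(axis=1)
        degen = totals <= 0
        safe = np.where(degen, 1.0, totals)
        pyr.levels.append(hists / safe[:, None])
        pyr.degenerate.append(degen)
        # degenerate rows stay all-zero after the safe division
        pyr.levels[-1][degen] = 0.0
    return pyr


def histogram_intersection(h1: OrientationHistogram, h2: OrientationHistogram) -> float:
    """Histogram Intersection Kernel: sum of elementwise minima, in [0, 1].

    Raises on degenerate inputs; callers decide how degenerate regions enter
    aggregate statistics.
    """
    if h1.degenerate or h2.degenerate:
        raise ValueError("histogram intersection of a degenerate histogram is undefined")
    return float(np.minimum(h1.bins, h2.bins).sum())


def self_similarity(pyr: HOGPyramid, aggregate: str = "median") -> float:
    """Aggregate HIK between the 64 level-3 histograms and the level-0 histogram.

    Degenerate level-3 blocks contribute intersection 0. Returns NaN if the
    level-0 histogram itself is degenerate (zero-gradient image).
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    if pyr.degenerate[0][0]:
        return float("nan")
    h0 = pyr.levels[0][0]
    inter = np.minimum(pyr.levels[3], h0[None, :]).sum(axis=1)
    inter[pyr.degenerate[3]] = 0.0
    return float(np.median(inter) if aggregate == "median" else np.mean(inter))


def complexity(field: GradientField) -> float:
    """Mean gradient magnitude over all pixels.

    The mean is a size-invariant surrogate for the total oriented-gradient
    strength: with all images resampled to a fixed pixel budget the two
    differ by a constant factor.
    """
    return float(field.magnitude.mean())


def anisotropy(pyr: HOGPyramid, pooling: str = "pooled") -> float:
    """Dispersion of gradient strength across orientations at level 3.

    ``pooled``: one SD over the 16 x 64 normalized bin values of all
    non-degenerate level-3 histograms (population SD). ``per-block``: SD per
    histogram, then averaged. 0 indicates an orientation-uniform image;
    identical one-hot histograms reach the pooled maximum sqrt(15)/16.
    Returns NaN if every level-3 histogram is degenerate.
    """
    if pooling not in ("pooled", "per-block"):
        raise ValueError("pooling must be 'pooled' or 'per-block'")
    keep = ~pyr.degenerate[3]
    if not keep.any():
        return float("nan")
    hists = pyr.levels[3][keep]
    if pooling == "pooled":
        return float(np.std(hists.ravel()))
    return float(np.mean(np.std(hists, axis=1)))


def birkhoff_measure(ss: float, comp: float) -> float:
    """Self-similarity over complexity; NaN if either is undefined or comp == 0."""
    if comp is None or ss is None or np.isnan(comp) or np.isnan(ss) or comp == 0:
        return float("nan")
    return float(ss) / float(comp)
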