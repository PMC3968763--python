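"""Synthetic images and rater populations with known ground truth.

Stands in for scanned artworks and undeposited rating data: every pipeline
stage can be exercised end to end against known generating parameters.

Image kinds
-----------
constant        flat color; zero gradients (degenerate self-similarity).
grating         oriented linear luminance ramp; concentrates all gradient
                mass in one orientation bin when axis-aligned.
block_mosaic    8x8 grid of oriented ramp patches assembled as a globally
                continuous separable field I(x,y) = A(x) + B(y), with
                half-integer per-block slopes. Continuity avoids seam
                gradients and half-integer slopes make centered differences
                exact on the 8-bit grid, so each level-3 pyramid block has a
                one-hot orientation histogram: low self-similarity, maximal
                anisotropy.
periodic_tiling toroidally periodic noise tile repeated 8x8; every level-3
                block sees identical content, so self-similarity is ~1.
spectral_noise  random-phase noise with amplitude spectrum 1/f^alpha; the
                slope alpha monotonically controls measured complexity
                (steeper slope = less fine structure).
color_field     smooth interpolation between two colors; exercises the
                color statistics.

Rating model
------------
Participant p in latent cluster g rates image i as

    rating = round(clip(a_g + w_g . z_i + eps, 1, 4)),   eps ~ N(0, sigma^2)

with z_i the standardized image features and 1 = most beautiful. The
adaptation phases add a condition shift +delta_i/2 (after beautiful
adaptors) or -delta_i/2 (after least-beautiful adaptors), with
delta_i = delta0 + delta1 * z_ss(i); clusters listed in
``inverted_clusters`` have the sign of delta flipped, emulating the
anomalous cluster whose contrast opposed the majority. The shift is applied
symmetrically so the baseline expectation is condition-free; the model is
agnostic about its mechanism (adaptation vs criterion shift vs comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import AdaptorSets
from .phog import RasterImage
from .ratings import RatingMatrix

# ---------------------------------------------------------------------------
# image generation


@dataclass
class ImageGenSpec:
    kind: str
    size: tuple[int, int] = (256, 256)  # (H, W)
    params: dict = field(default_factory=dict)
    seed: int = 0
    id: str = ""


def _to_uint8(gray: np.ndarray, lo: int = 0, hi: int = 255) -> np.ndarray:
    g = np.asarray(gray, dtype=float)
    rng_ = g.max() - g.min()
    if rng_ == 0:
        out = np.full_like(g, (lo + hi) / 2)
    else:
        out = lo + (g - g.min()) / rng_ * (hi - lo)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _gray_to_rgb(gray: np.ndarray) -> np.ndarray:
    return np.repeat(gray[:, :, None], 3, axis=2)


def _tint(gray: np.ndarray, c0: np.ndarray, c1: np.ndarray) -> np.ndarray:
    """Map gray levels onto the line between two RGB colors."""
    t = gray.astype(float)[:, :, None] / 255.0
    rgb = c0[None, None, :] * (1 - t) + c1[None, None, :] * t
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


# default half-integer block slopes for the 8x8 mosaic; all 16 (|a|,|b|)
# combinations give orientations at least ~4 deg away from a 22.5-deg bin
# boundary, so quantization and Lab conversion cannot move mass across bins
MOSAIC_COL_SLOPES = (1.5, -1.5, 0.5, -0.5, -0.5, 0.5, -1.5, 1.5)
MOSAIC_ROW_SLOPES = (2.0, -2.0, 1.0, -1.0, -1.0, 1.0, -2.0, 2.0)


def _piecewise_ramp(n_pixels: int, slopes: tuple[float, ...]) -> np.ndarray:
    """Continuous piecewise-linear profile with one slope per equal block."""
    n_blocks = len(slopes)
    block = n_pixels // n_blocks
    if block * n_blocks != n_pixels:
        raise ValueError(f"{n_pixels} pixels not divisible into {n_blocks} blocks")
    inc = np.repeat(np.asarray(slopes, dtype=float), block)
    prof = np.concatenate([[0.0], np.cumsum(inc)[:-1]])
    return prof


def generate_image(spec: ImageGenSpec) -> RasterImage:
    """Deterministically render one synthetic image from its spec."""
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.kind == "constant":
        color = np.asarray(p.get("color", (128, 128, 128)), dtype=np.uint8)
        pixels = np.tile(color, (h, w, 1))
    elif spec.kind == "grating":
        theta = np.radians(p.get("orientation_deg", 0.0))
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        proj = xx * np.cos(theta) + yy * np.sin(theta)
        if p.get("waveform", "ramp") == "sine":
            gray = _to_uint8(np.sin(2 * np.pi * p.get("cycles", 8) * proj / max(h, w)))
        else:
            gray = _to_uint8(proj)
        pixels = _gray_to_rgb(gray)
    elif spec.kind == "block_mosaic":
        col_slopes = tuple(p.get("col_slopes", MOSAIC_COL_SLOPES))
        row_slopes = tuple(p.get("row_slopes", MOSAIC_ROW_SLOPES))
        # ties-up rounding keeps centered differences of half-integer slopes
        # exact (ties-to-even would break translation invariance)
        A = np.floor(_piecewise_ramp(w, col_slopes) + 0.5)
        B = np.floor(_piecewise_ramp(h, row_slopes) + 0.5)
        I = B[:, None] + A[None, :]
        # center into the 8-bit range without rescaling (slopes stay exact)
        offset = round(127 - (I.max() + I.min()) / 2)
        gray = np.clip(I + offset, 0, 255).astype(np.uint8)
        pixels = _gray_to_rgb(gray)
    elif spec.kind == "periodic_tiling":
        reps = int(p.get("reps", 8))
        tile_px = h // reps
        if tile_px * reps != h or w != h:
            raise ValueError("periodic_tiling requires a square image divisible by reps")
        noise = rng.standard_normal((tile_px, tile_px))
        fy = np.fft.fftfreq(tile_px)[:, None]
        fx = np.fft.fftfreq(tile_px)[None, :]
        sigma_f = p.get("smoothness", 0.15)
        filt = np.exp(-(fx**2 + fy**2) / (2 * sigma_f**2))
        tile = np.real(np.fft.ifft2(np.fft.fft2(noise) * filt))
        gray = np.tile(_to_uint8(tile, 30, 225), (reps, reps))
        pixels = _gray_to_rgb(gray)
    elif spec.kind == "spectral_noise":
        alpha = float(p.get("slope", 1.0))
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        f = np.sqrt(fx**2 + fy**2)
        f[0, 0] = 1.0
        amp = f**-alpha
        amp[0, 0] = 0.0
        phase = np.exp(2j * np.pi * rng.random((h, w)))
        gray = np.real(np.fft.ifft2(amp * phase))
        pixels = _gray_to_rgb(_to_uint8(gray, 10, 245))
    elif spec.kind == "color_field":
        c0 = np.asarray(p.get("color_a", (200, 60, 40)), dtype=float)
        c1 = np.asarray(p.get("color_b", (40, 80, 200)), dtype=float)
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        sigma_f = p.get("smoothness", 0.03)
        filt = np.exp(-(fx**2 + fy**2) / (2 * sigma_f**2))
        gray = np.real(np.fft.ifft2(np.fft.fft2(rng.standard_normal((h, w))) * filt))
        pixels = _tint(_to_uint8(gray), c0, c1)
    else:
        raise ValueError(f"unknown image kind {spec.kind!r}")
    if p.get("tint") is not None:
        c0, c1 = (np.asarray(c, dtype=float) for c in p["tint"])
        pixels = _tint(pixels[:, :, 0], c0, c1)
    return RasterImage(pixels, id=spec.id or f"{spec.kind}_{spec.seed}")


# palette used to spread the collection over hue/saturation/value space
_PALETTE = [
    ((230, 40, 30), (255, 235, 220)),   # reds
    ((250, 210, 40), (60, 40, 20)),     # yellows vs dark
    ((30, 160, 60), (220, 255, 230)),   # greens
    ((30, 200, 210), (10, 40, 60)),     # cyans
    ((40, 60, 220), (200, 210, 255)),   # blues
    ((200, 40, 200), (30, 10, 40)),     # magentas
    ((20, 20, 20), (240, 240, 240)),    # near-grayscale
]


def generate_image_collection(
    n: int = 150,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
) -> tuple[list[RasterImage], pd.DataFrame]:
    """A mixed collection spanning a wide range of each statistic.

    Cycles through spectral noise (graded spectral slopes -> graded
    complexity), periodic tilings (high self-similarity), block mosaics
    (low self-similarity, high anisotropy) and color fields, each tinted
    with varied palette colors. Returns the images and a ground-truth table
    (kind and generating parameters) for recovery tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    images: list[RasterImage] = []
    truth = []
    kinds = ["spectral_noise", "periodic_tiling", "block_mosaic", "color_field"]
    # non-square variants (multiples of 8) so aspect ratio varies across the
    # collection; periodic tilings must stay square
    h0, w0 = size
    rect_sizes = [(h0, w0), (h0, w0 + w0 // 4), (h0 + h0 // 4, w0), (h0 - h0 // 8, w0 + w0 // 8)]
    for i in range(n):
        kind = kinds[i % len(kinds)]
        img_size = (h0, w0) if kind == "periodic_tiling" else rect_sizes[(i // len(kinds)) % len(rect_sizes)]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params: dict = {}
        slope = np.nan
        if kind == "spectral_noise":
            slope = 0.5 + 2.0 * ((i // len(kinds)) % 8) / 7.0
            params = {"slope": slope, "tint": _PALETTE[i % len(_PALETTE)]}
        elif kind == "periodic_tiling":
            params = {
                "smoothness": 0.08 + 0.12 * rng.random(),
                "tint": _PALETTE[(i // 2) % len(_PALETTE)],
            }
        elif kind == "block_mosaic":
            perm = rng.permutation(8)
            params = {
                "col_slopes": tuple(np.asarray(MOSAIC_COL_SLOPES)[perm]),
                "row_slopes": tuple(np.asarray(MOSAIC_ROW_SLOPES)[rng.permutation(8)]),
                "tint": _PALETTE[(i // 3) % len(_PALETTE)],
            }
        elif kind == "color_field":
            c0, c1 = _PALETTE[i % len(_PALETTE)]
            params = {"color_a": c0, "color_b": c1, "smoothness": 0.02 + 0.08 * rng.random()}
        image_id = f"img_{i:03d}"
        spec = ImageGenSpec(kind=kind, size=img_size, params=params, seed=sub_seed, id=image_id)
        images.append(generate_image(spec))
        truth.append({"image_id": image_id, "kind": kind, "spectral_slope": slope})
    return images, pd.DataFrame(truth).set_index("image_id")


# ---------------------------------------------------------------------------
# rater population


@dataclass
class PopulationSpec:
    """Latent preference-cluster structure of a simulated rater population.

    ``weights[g]`` maps standardized feature names to the cluster's taste
    weights (positive = more of the feature rated less beautiful);
    ``intercepts[g]`` is the cluster's baseline rating level. ``delta0`` is
    the mean condition shift between the two adaptation conditions and
    ``delta1`` its per-unit link to standardized self-similarity;
    ``inverted_clusters`` have the shift sign flipped. The default
    population mirrors the study scale: 50 raters in 7 clusters of sizes
    10/9/7/7/7/6/4, intercepts calibrated so the rounded, clipped grand
    mean is ~2.88 on the 1-4 scale.
    """

    cluster_sizes: tuple[int, ...] = (10, 9, 7, 7, 7, 6, 4)
    intercepts: tuple[float, ...] = (3.0, 2.85, 3.1, 2.95, 2.45, 3.05, 3.25)
    weights: tuple[dict, ...] = (
        {"self_similarity": 0.35, "hsv_value": -0.40},
        {"self_similarity": -0.30, "hsv_saturation": -0.35},
        {"hsv_hue": 0.25, "lab_b": -0.35},
        {"self_similarity": 0.30, "lab_l": -0.35},
        {"self_similarity": -0.25, "hsv_saturation": -0.30},
        {"hsv_value": -0.35, "lab_b": -0.30},
        {"complexity": 0.20, "lab_l": -0.30},
    )
    sigma: float = 0.8
    delta0: float = 0.16
    delta1: float = 0.04
    inverted_clusters: tuple[int, ...] = (4,)
    counterbalance: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("rating noise sigma must be >= 0")
        if len(self.intercepts) != self.n_clusters or len(self.weights) != self.n_clusters:
            raise ValueError("intercepts/weights must match the number of clusters")
        if any(s < 4 for s in self.cluster_sizes):
            raise ValueError("cluster sizes below 4 are infeasible for the adaptation design")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_participants(self) -> int:
        return int(sum(self.cluster_sizes))

    def participant_clusters(self) -> pd.Series:
        ids = [f"p{idx:03d}" for idx in range(self.n_participants)]
        labels = np.repeat(np.arange(self.n_clusters), self.cluster_sizes)
        return pd.Series(labels, index=ids, name="cluster")


def standardize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Z-score each numeric feature over the collection; NaNs become 0 (the mean)."""
    num = features.select_dtypes(include=[np.number])
    sd = num.std(ddof=1).replace(0, 1.0)
    z = (num - num.mean()) / sd
    return z.fillna(0.0)


def _cluster_utilities(z: pd.DataFrame, pop: PopulationSpec) -> np.ndarray:
    """(n_clusters, n_images) deterministic rating expectations a_g + w_g . z_i."""
    util = np.zeros((pop.n_clusters, len(z)))
    for g in range(pop.n_clusters):
        mu = np.full(len(z), pop.intercepts[g])
        for name, wgt in pop.weights[g].items():
            if name not in z.columns:
                raise KeyError(f"weight on unknown feature {name!r}")
            mu = mu + wgt * z[name].to_numpy()
        util[g] = mu
    return util


def _round_clip(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.clip(x, 1.0, 4.0)), 1, 4).astype(int)


def simulate_baseline_ratings(
    features: pd.DataFrame,
    pop: PopulationSpec,
    seed: int = 0,
) -> tuple[RatingMatrix, pd.Series]:
    """Complete baseline rating matrix plus the true cluster assignment."""
    z = standardize_features(features)
    util = _cluster_utilities(z, pop)
    clusters = pop.participant_clusters()
    rng = np.random.default_rng(seed)
    eps = rng.normal(0, pop.sigma, size=(pop.n_participants, len(z)))
    raw = util[clusters.to_numpy()] + eps
    ratings = pd.DataFrame(_round_clip(raw), index=clusters.index, columns=z.index)
    return RatingMatrix(ratings, phase="baseline"), clusters


def simulate_adaptation_ratings(
    features: pd.DataFrame,
    pop: PopulationSpec,
    adaptor_sets: dict[int, AdaptorSets],
    assignment: pd.Series,
    seed: int = 0,
    true_clusters: pd.Series | None = None,
) -> tuple[RatingMatrix, RatingMatrix, pd.Series]:
    """Post-adaptation rating matrices (after_beautiful, after_least).

    ``assignment`` is the experiment's participant -> cluster map (e.g. the
    k-means solution) and determines which evaluation set each participant
    rates; the participant's taste (utilities, inverted shift) always comes
    from their latent generating cluster (``true_clusters``, defaulting to
    the population's construction order). Each evaluation image is rated
    once per condition with the condition shift +-delta_i/2 around the
    baseline expectation. Also returns the counterbalanced condition order
    per participant ('beautiful_first' / 'least_first').
    """
    z = standardize_features(features)
    util = _cluster_utilities(z, pop)
    col_of = {img: j for j, img in enumerate(z.index)}
    delta_i = pop.delta0 + pop.delta1 * z["self_similarity"].to_numpy()
    rng = np.random.default_rng(seed)
    if true_clusters is None:
        true_clusters = pop.participant_clusters()
    all_images = sorted({img for s in adaptor_sets.values() for img in s.evaluation})
    out_col = {img: j for j, img in enumerate(all_images)}
    arr_b = np.full((len(assignment), len(all_images)), np.nan)
    arr_l = np.full((len(assignment), len(all_images)), np.nan)
    # vectorized over participants sharing (experiment cluster, true cluster)
    groups = pd.DataFrame(
        {"g": assignment.astype(int), "g_true": true_clusters.reindex(assignment.index).astype(int)}
    )
    row_of = {pid: r for r, pid in enumerate(assignment.index)}
    for (g, g_true), members in groups.groupby(["g", "g_true"]).groups.items():
        eval_imgs = adaptor_sets[int(g)].evaluation
        cols = [col_of[i] for i in eval_imgs]
        base = util[int(g_true), cols]
        shift = delta_i[cols] / 2.0
        if int(g_true) in pop.inverted_clusters:
            shift = -shift
        m = len(members)
        noise_b = rng.normal(0, pop.sigma, (m, len(cols)))
        noise_l = rng.normal(0, pop.sigma, (m, len(cols)))
        rows = [row_of[pid] for pid in members]
        ocols = [out_col[i] for i in eval_imgs]
        arr_b[np.ix_(rows, ocols)] = _round_clip(base[None, :] + shift[None, :] + noise_b)
        arr_l[np.ix_(rows, ocols)] = _round_clip(base[None, :] - shift[None, :] + noise_l)
    after_b = pd.DataFrame(arr_b, index=assignment.index, columns=all_images)
    after_l = pd.DataFrame(arr_l, index=assignment.index, columns=all_images)
    orders = pd.Series(
        ["beautiful_first" if (i % 2 == 0 or not pop.counterbalance) else "least_first"
         for i in range(len(assignment))],
        index=assignment.index,
        name="condition_order",
    )
    return (
        RatingMatrix(after_b, phase="after_beautiful"),
        RatingMatrix(after_l, phase="after_least"),
        orders,
    )


def separated_population(
    n_clusters: int = 7,
    cluster_sizes: tuple[int, ...] | None = None,
    separation_sigma: float = 3.0,
    sigma: float = 0.8,
    feature_names: tuple[str, ...] | None = None,
    **kwargs,
) -> PopulationSpec:
    """Population whose clusters differ by a stated separation.

    Cluster g loads weight s on its own feature, with
    s = separation_sigma * sigma / sqrt(2), so that for independent
    standardized features the per-image SD of the expected-rating difference
    between any two clusters is ``separation_sigma`` noise SDs.
    """
    if cluster_sizes is None:
        cluster_sizes = tuple([max(4, 50 // n_clusters)] * n_clusters)
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(n_clusters))
    if len(feature_names) < n_clusters:
        raise ValueError("need at least one feature per cluster")
    s = separation_sigma * sigma / np.sqrt(2)
    weights = tuple({feature_names[g]: s * (1 if g % 2 == 0 else -1)} for g in range(n_clusters))
    intercepts = tuple([2.9] * n_clusters)
    return PopulationSpec(
        cluster_sizes=cluster_sizes,
        intercepts=intercepts,
        weights=weights,
        sigma=sigma,
        **kwargs,
    )
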