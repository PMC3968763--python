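"""Feature-table assembly: one row of image statistics per image.

Each image yields 15 statistics (four PHOG-derived measures, the aspect
ratio, ten color-channel means) plus six hue-sector pixel fractions and an
achromatic tally. Degenerate cases (flat images with no gradients) surface
as NaN plus a flag string rather than failing the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import color, phog
from .phog import RasterImage

logger = logging.getLogger(__name__)

#: Stable column order of the features table.
FEATURE_COLUMNS = [
    "self_similarity",
    "complexity",
    "anisotropy",
    "birkhoff",
    "aspect_ratio",
    "hsv_hue",
    "hsv_saturation",
    "hsv_value",
    "rgb_r",
    "rgb_g",
    "rgb_b",
    "lab_l",
    "lab_a",
    "lab_b",
]
HUE_COLUMNS = [f"hue_{name}" for name in color.HUE_SECTOR_NAMES]
ALL_COLUMNS = FEATURE_COLUMNS + HUE_COLUMNS + ["achromatic_fraction", "flags"]

#: The properties entered into the regression / mixed-model layers.
PHOG_PROPERTIES = ["self_similarity", "complexity", "anisotropy", "birkhoff"]


@dataclass
class ImageFeatureRecord:
    image_id: str
    values: dict[str, float]
    degenerate_flags: set[str] = dc_field(default_factory=set)

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {"image_id": self.image_id}
        row.update({c: self.values.get(c, np.nan) for c in ALL_COLUMNS if c != "flags"})
        row["flags"] = ";".join(sorted(self.degenerate_flags))
        return row


def extract_features(
    img: RasterImage,
    pixel_budget: int | None = 100_000,
    ss_aggregate: str = "median",
    anisotropy_pooling: str = "pooled",
    circular_hue: bool = False,
) -> ImageFeatureRecord:
    """Compute the full statistic set for one image.

    The aspect ratio uses the original (pre-downsampling) dimensions; all
    other statistics are computed on the image resampled to ``pixel_budget``
    pixels (``None`` disables resampling).
    """
    flags: set[str] = set()
    aspect = img.aspect_ratio
    work = phog.preprocess_image(img, pixel_budget)
    field = phog.compute_gradient_field(work)
    comp = phog.complexity(field)
    pyr = phog.build_hog_pyramid(field)
    ss = phog.self_similarity(pyr, aggregate=ss_aggregate)
    aniso = phog.anisotropy(pyr, pooling=anisotropy_pooling)
    birk = phog.birkhoff_measure(ss, comp)
    if np.isnan(ss):
        flags.add("self_similarity_undefined")
    if np.isnan(aniso):
        flags.add("anisotropy_undefined")
    if np.isnan(birk):
        flags.add("birkhoff_undefined")
    values = {
        "self_similarity": ss,
        "complexity": comp,
        "anisotropy": aniso,
        "birkhoff": birk,
        "aspect_ratio": aspect,
    }
    values.update(color.color_channel_means(work, circular_hue=circular_hue))
    fractions, achromatic = color.hue_sector_fractions(work)
    values.update(dict(zip(HUE_COLUMNS, fractions)))
    values["achromatic_fraction"] = achromatic
    if achromatic >= 1.0:
        flags.add("achromatic_image")
    return ImageFeatureRecord(image_id=img.id, values=values, degenerate_flags=flags)


def load_image(path: str | Path, image_id: str | None = None) -> RasterImage:
    """Read a PNG/JPEG/TIFF file as an 8-bit RGB raster image."""
    from PIL import Image

    p = Path(path)
    with Image.open(p) as im:
        rgb = im.convert("RGB")
        pixels = np.asarray(rgb, dtype=np.uint8)
    return RasterImage(pixels, id=image_id or p.stem)


def compute_all_features(
    images: list[RasterImage],
    **kwargs,
) -> pd.DataFrame:
    """Feature table for a collection of images, one row per image.

    Deterministic given the inputs; images whose extraction fails are kept
    as all-NaN rows flagged ``extraction_failed``.
    """
    if not images:
        raise ValueError("no images supplied")
    rows = []
    for img in images:
        try:
            rec = extract_features(img, **kwargs)
        except Exception as exc:  # noqa: BLE001 - degraded row, not a crash
            logger.warning("feature extraction failed for %r: %s", img.id, exc)
            rec = ImageFeatureRecord(img.id, {}, {"extraction_failed"})
        rows.append(rec.to_row())
    df = pd.DataFrame(rows, columns=["image_id"] + ALL_COLUMNS)
    return df.set_index("image_id")


def compute_features_from_manifest(manifest: str | Path, **kwargs) -> pd.DataFrame:
    """Feature table from a manifest CSV with columns ``image_id, path``.

    Unreadable files are skipped with a logged warning and an all-NaN row
    flagged ``unreadable_file``.
    """
    man = pd.read_csv(manifest)
    if not {"image_id", "path"} <= set(man.columns):
        raise ValueError("manifest must have columns image_id, path")
    images: list[RasterImage] = []
    failed_rows = []
    for _, r in man.iterrows():
        try:
            images.append(load_image(r["path"], image_id=str(r["image_id"])))
        except Exception as exc:  # noqa: BLE001
            logger.warning("skipping unreadable image %r (%s): %s", r["image_id"], r["path"], exc)
            failed_rows.append(str(r["image_id"]))
    if images:
        df = compute_all_features(images, **kwargs)
    else:
        df = pd.DataFrame(columns=ALL_COLUMNS, index=pd.Index([], name="image_id"))
    for image_id in failed_rows:
        df.loc[image_id] = {c: (np.nan if c != "flags" else "unreadable_file") for c in ALL_COLUMNS}
    return df.loc[[str(i) for i in man["image_id"]]]
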