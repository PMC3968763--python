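"""Per-channel color statistics in HSV, RGB and CIE Lab space.

Channel means follow the conventions used throughout the aesthetics
literature: HSV channels in [0, 1], RGB in [0, 255], Lab with L in [0, 100]
and signed a/b (sRGB, D65 white point). Hue is averaged as a plain
arithmetic mean by default — hue is circular, so a circular mean is
available as an opt-in variant.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv, rgb2lab

from .phog import RasterImage

# 60-degree sectors centered on 0, 60, ..., 300 degrees
HUE_SECTOR_NAMES = ("red", "yellow", "green", "cyan", "blue", "magenta")
ACHROMATIC_SATURATION = 0.05


def color_channel_means(img: RasterImage, circular_hue: bool = False) -> dict[str, float]:
    """Arithmetic mean of each channel in HSV, RGB and Lab space.

    With ``circular_hue=True`` the HSV hue mean is the circular mean
    (still reported on the [0, 1] scale).
    """
    rgb = img.pixels.astype(float)
    hsv = rgb2hsv(img.pixels)
    lab = rgb2lab(img.pixels)
    if circular_hue:
        ang = hsv[:, :, 0] * 2 * np.pi
        hue = (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi)) % 1.0
    else:
        hue = hsv[:, :, 0].mean()
    return {
        "hsv_hue": float(hue),
        "hsv_saturation": float(hsv[:, :, 1].mean()),
        "hsv_value": float(hsv[:, :, 2].mean()),
        "rgb_r": float(rgb[:, :, 0].mean()),
        "rgb_g": float(rgb[:, :, 1].mean()),
        "rgb_b": float(rgb[:, :, 2].mean()),
        "lab_l": float(lab[:, :, 0].mean()),
        "lab_a": float(lab[:, :, 1].mean()),
        "lab_b": float(lab[:, :, 2].mean()),
    }


def hue_sector_fractions(img: RasterImage) -> tuple[np.ndarray, float]:
    """Fraction of pixels in each of six 60-degree hue sectors.

    Sectors are centered on the six primary/secondary hues (red =
    [330, 30) degrees, and so on). Every pixel is assigned by its raw hue;
    near-achromatic pixels (saturation < 0.05), whose hue is numerically
    unstable, are additionally counted in a separate achromatic tally.

    Returns ``(fractions, achromatic_fraction)`` with ``fractions`` summing
    to 1.
    """
    hsv = rgb2hsv(img.pixels)
    hue_deg = hsv[:, :, 0].ravel() * 360.0
    sector = (np.floor(((hue_deg + 30.0) % 360.0) / 60.0)).astype(np.intp)
    counts = np.bincount(sector, minlength=6)[:6]
    fractions = counts / counts.sum()
    achromatic = float((hsv[:, :, 1] < ACHROMATIC_SATURATION).mean())
    return fractions, achromatic
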