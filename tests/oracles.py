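"""Independent brute-force oracles for small images.

Everything here is written as explicit double loops over pixels, bins and
rectangles, sharing nothing with the vectorized implementation except the
Lab color conversion (a standard-library concern, not part of the method).
"""

from __future__ import annotations

import math

import numpy as np
from skimage.color import rgb2lab


def gradient_field_bruteforce(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Lab max-channel gradient by explicit loops."""
    lab = rgb2lab(pixels)
    h, w, _ = lab.shape
    mag = np.zeros((h, w))
    ori = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            best_m, best_o = -1.0, 0.0
            for c in range(3):
                xm, xp = max(x - 1, 0), min(x + 1, w - 1)
                ym, yp = max(y - 1, 0), min(y + 1, h - 1)
                gx = (lab[y, xp, c] - lab[y, xm, c]) / 2.0
                gy = (lab[yp, x, c] - lab[ym, x, c]) / 2.0
                m = math.hypot(gx, gy)
                if m > best_m:
                    best_m = m
                    best_o = math.degrees(math.atan2(gy, gx)) % 360.0
            mag[y, x] = best_m
            ori[y, x] = 0.0 if best_m == 0 else best_o
    return mag, ori


def _edges(n: int, blocks: int) -> list[tuple[int, int]]:
    step = n // blocks
    out = []
    for i in range(blocks):
        lo = i * step
        hi = (i + 1) * step if i < blocks - 1 else n
        out.append((lo, hi))
    return out


def hog_bruteforce(mag, ori, r0, r1, c0, c1) -> tuple[np.ndarray, bool]:
    hist = np.zeros(16)
    for y in range(r0, r1):
        for x in range(c0, c1):
            b = int(ori[y, x] // 22.5)
            if b == 16:
                b = 15
            hist[b] += mag[y, x]
    s = hist.sum()
    if s <= 0:
        return hist, True
    return hist / s, False


def pyramid_bruteforce(mag, ori) -> list[list[tuple[np.ndarray, bool]]]:
    h, w = mag.shape
    levels = []
    for level in range(4):
        n = 2**level
        hists = []
        for (r0, r1) in _edges(h, n):
            for (c0, c1) in _edges(w, n):
                hists.append(hog_bruteforce(mag, ori, r0, r1, c0, c1))
        levels.append(hists)
    return levels


def self_similarity_bruteforce(levels) -> float:
    h0, degen0 = levels[0][0]
    if degen0:
        return float("nan")
    inters = []
    for hist, degen in levels[3]:
        if degen:
            inters.append(0.0)
        else:
            inters.append(sum(min(a, b) for a, b in zip(hist, h0)))
    return float(np.median(inters))


def anisotropy_bruteforce(levels) -> float:
    vals = []
    for hist, degen in levels[3]:
        if not degen:
            vals.extend(hist.tolist())
    if not vals:
        return float("nan")
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / len(vals)
    return math.sqrt(var)


def complexity_bruteforce(mag) -> float:
    total = 0.0
    h, w = mag.shape
    for y in range(h):
        for x in range(w):
            total += mag[y, x]
    return total / (h * w)


def spearman_bruteforce(x, y) -> float:
    """Rank both variables (mean ranks for ties), then Pearson on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def paired_t_bruteforce(b, l) -> tuple[float, int]:
    d = [bi - li for bi, li in zip(b, l)]
    n = len(d)
    m = sum(d) / n
    s2 = sum((x - m) ** 2 for x in d) / (n - 1)
    return m / math.sqrt(s2 / n), n - 1
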