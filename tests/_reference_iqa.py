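"""Independent straight-line oracles for the quality metrics.

Every function here evaluates the defining formula of one metric component by
direct summation / explicit loops, sharing no code with ``uweval.iqa``. They
are deliberately slow and simple; tests compare them against the package on
small fixed patterns and small synthetic corpora.
"""

import math

import numpy as np


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def ref_entropy(image) -> float:
    counts = {}
    h, w, _ = image.shape
    n = h * w
    for i in range(h):
        for j in range(w):
            r, g, b = (float(image[i, j, c]) for c in range(3))
            level = int(round(0.299 * r + 0.587 * g + 0.114 * b))
            level = min(max(level, 0), 255)
            counts[level] = counts.get(level, 0) + 1
    total = 0.0
    for c in counts.values():
        p = c / n
        total -= p * math.log2(p)
    return total


# ---------------------------------------------------------------------------
# UIQM components
# ---------------------------------------------------------------------------

def _ref_trimmed_mean(values, alpha=0.1):
    xs = sorted(values)
    t = int(alpha * len(xs))
    kept = xs[t: len(xs) - t] if len(xs) - 2 * t > 0 else xs
    return sum(kept) / len(kept)


def ref_uicm(image) -> float:
    h, w, _ = image.shape
    rg, yb = [], []
    for i in range(h):
        for j in range(w):
            r, g, b = (float(image[i, j, c]) for c in range(3))
            rg.append(r - g)
            yb.append(0.5 * (r + g) - b)
    mu_rg = _ref_trimmed_mean(rg)
    mu_yb = _ref_trimmed_mean(yb)
    var_rg = sum((v - mu_rg) ** 2 for v in rg) / len(rg)
    var_yb = sum((v - mu_yb) ** 2 for v in yb) / len(yb)
    return -0.0268 * math.sqrt(mu_rg**2 + mu_yb**2) + 0.1586 * math.sqrt(var_rg + var_yb)


def _ref_sobel_magnitude(channel):
    h, w = channel.shape
    # reflect padding duplicating the edge row/column (scipy 'reflect')
    padded = np.pad(channel.astype(float), 1, mode="symmetric")
    kx = [[1, 0, -1], [2, 0, -2], [1, 0, -1]]
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            gx = gy = 0.0
            for di in range(3):
                for dj in range(3):
                    gx += kx[di][dj] * padded[i + di, j + dj]
                    gy += kx[dj][di] * padded[i + di, j + dj]
            out[i, j] = math.hypot(gx, gy)
    return out


def _ref_blocks(arr, block=10):
    h, w = arr.shape
    out = []
    for bi in range(h // block):
        for bj in range(w // block):
            out.append(arr[bi * block:(bi + 1) * block, bj * block:(bj + 1) * block])
    return out


def _ref_eme(channel, block=10):
    blocks = _ref_blocks(channel, block)
    total = 0.0
    for blk in blocks:
        mx, mn = float(blk.max()), float(blk.min())
        if mn > 0 and mx > 0:
            total += math.log(mx / mn)
    return 2.0 / len(blocks) * total


def ref_uism(image) -> float:
    weights = (0.299, 0.587, 0.114)
    total = 0.0
    for c, lam in enumerate(weights):
        channel = image[..., c].astype(float)
        edge = _ref_sobel_magnitude(channel) * channel
        total += lam * _ref_eme(edge)
    return total


def ref_uiconm(image) -> float:
    h, w, _ = image.shape
    gray = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            r, g, b = (float(image[i, j, c]) for c in range(3))
            gray[i, j] = 0.299 * r + 0.587 * g + 0.114 * b
    blocks = _ref_blocks(gray)
    total = 0.0
    for blk in blocks:
        mx, mn = float(blk.max()), float(blk.min())
        if mx + mn > 0 and mx > mn:
            t = (mx - mn) / (mx + mn)
            total -= t * math.log(t)
    return total / len(blocks)


def ref_uiqm(image) -> float:
    return 0.0282 * ref_uicm(image) + 0.2953 * ref_uism(image) + 3.5753 * ref_uiconm(image)


# ---------------------------------------------------------------------------
# UCIQE components (manual sRGB -> CIELAB, D65, 2 degree observer)
# ---------------------------------------------------------------------------

def _srgb_to_lab(r, g, b):
    def inv_gamma(u):
        u = u / 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    rl, gl, bl = inv_gamma(r), inv_gamma(g), inv_gamma(b)
    # sRGB -> XYZ matrix and D65 2-degree white point of the CIE standard
    x = 0.412453 * rl + 0.357580 * gl + 0.180423 * bl
    y = 0.212671 * rl + 0.715160 * gl + 0.072169 * bl
    z = 0.019334 * rl + 0.119193 * gl + 0.950227 * bl
    xn, yn, zn = 0.95047, 1.0, 1.08883

    def f(t):
        return t ** (1 / 3) if t > 0.008856 else 7.787 * t + 16.0 / 116.0

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    return 116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)


def ref_uciqe_components(image):
    h, w, _ = image.shape
    lum, chroma, sat = [], [], []
    for i in range(h):
        for j in range(w):
            L, a, b = _srgb_to_lab(*(float(image[i, j, c]) for c in range(3)))
            l01 = L / 100.0
            c01 = math.hypot(a, b) / 100.0
            lum.append(l01)
            chroma.append(c01)
            norm = math.hypot(c01, l01)
            sat.append(c01 / norm if norm > 0 else 0.0)
    mean_c = sum(chroma) / len(chroma)
    sigma_chroma = math.sqrt(sum((c - mean_c) ** 2 for c in chroma) / len(chroma))
    con_luminance = float(np.percentile(lum, 99) - np.percentile(lum, 1))
    mu_saturation = sum(sat) / len(sat)
    return sigma_chroma, con_luminance, mu_saturation


def ref_uciqe(image) -> float:
    sc, cl, ms = ref_uciqe_components(image)
    return 0.4680 * sc + 0.2745 * cl + 0.2576 * ms


# ---------------------------------------------------------------------------
# CCF components
# ---------------------------------------------------------------------------

def ref_ccf_components(image):
    h, w, _ = image.shape
    rg, yb, gray = [], [], []
    for i in range(h):
        for j in range(w):
            r, g, b = (float(image[i, j, c]) for c in range(3))
            rg.append(r - g)
            yb.append(0.5 * (r + g) - b)
            gray.append(0.299 * r + 0.587 * g + 0.114 * b)

    def mean(xs):
        return sum(xs) / len(xs)

    def std(xs):
        m = mean(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))

    colorfulness = math.hypot(std(rg), std(yb)) + 0.3 * math.hypot(mean(rg), mean(yb))
    contrast = std(gray)

    # dark channel: local min over a 10x10 window (rows i-5..i+4), clamped
    per_pixel_min = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            per_pixel_min[i, j] = min(float(image[i, j, c]) for c in range(3))
    total = 0.0
    for i in range(h):
        for j in range(w):
            lo_i, hi_i = max(0, i - 5), min(h, i + 5)
            lo_j, hi_j = max(0, j - 5), min(w, j + 5)
            total += per_pixel_min[lo_i:hi_i, lo_j:hi_j].min()
    clearness = 100.0 * (1.0 - (total / (h * w)) / 255.0)
    return colorfulness, contrast, clearness


def ref_ccf(image) -> float:
    cf, ct, cl = ref_ccf_components(image)
    return 0.17593 * cf + 0.61759 * ct + 0.33988 * cl
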