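"""No-reference underwater image-quality metrics.

Four established metrics are computed on 8-bit RGB images:

* **UIQM** — weighted sum of a colorfulness term (UICM), a sharpness term
  (UISM) and a contrast term (UIConM);
* **UCIQE** — linear combination of chroma standard deviation, luminance
  contrast and mean saturation in CIELAB;
* **CCF** — weighted combination of colorfulness, contrast and a
  clearness (anti-fog) term;
* **Entropy** — Shannon entropy of the 8-bit grayscale histogram, in bits.

Each composite metric exposes its components alongside the total so that the
weighted-sum structure can be audited; the coefficient values actually used
are stored in :data:`UIQM_COEFFS`, :data:`UCIQE_COEFFS` and
:data:`CCF_WEIGHTS`.

All metrics are deterministic and operate on the stored resolution; no
internal resizing is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color

__all__ = [
    "UIQM_COEFFS",
    "UICM_COEFFS",
    "UISM_LUMA_WEIGHTS",
    "UCIQE_COEFFS",
    "CCF_WEIGHTS",
    "BLOCK_SIZE",
    "LUMA_WEIGHTS",
    "MetricResult",
    "QualityRecord",
    "compute_entropy",
    "compute_uiqm",
    "compute_uciqe",
    "compute_ccf",
    "score_collection",
    "summarize_records",
]

#: UIQM combination coefficients (c1 UICM + c2 UISM + c3 UIConM).
UIQM_COEFFS = {"uicm": 0.0282, "uism": 0.2953, "uiconm": 3.5753}
#: Inner UICM coefficients applied to the chromatic mean / spread magnitudes.
UICM_COEFFS = {"mu": -0.0268, "sigma": 0.1586}
#: Per-channel weights for the UISM sharpness term (standard luma weights).
UISM_LUMA_WEIGHTS = {"r": 0.299, "g": 0.587, "b": 0.114}
#: UCIQE combination coefficients (c1 sigma_chroma + c2 con_lum + c3 mu_sat).
UCIQE_COEFFS = {"sigma_chroma": 0.4680, "con_luminance": 0.2745, "mu_saturation": 0.2576}
#: CCF combination weights (colorfulness, contrast, clearness).
CCF_WEIGHTS = {"colorfulness": 0.17593, "contrast": 0.61759, "clearness": 0.33988}
#: Side length of the square analysis blocks used by block-based terms.
BLOCK_SIZE = 10
#: Grayscale conversion weights (ITU-R BT.601 luma).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)
#: Trim fraction on each tail for the UICM asymmetric trimmed mean.
UICM_TRIM_FRACTION = 0.1


@dataclass(frozen=True)
class MetricResult:
    """A composite metric value with its exposed components and weights.

    ``total`` equals ``sum(weights[k] * components[k])`` to within 1e-9.
    """

    total: float
    components: dict[str, float]
    weights: dict[str, float]

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.total


@dataclass(frozen=True)
class QualityRecord:
    """Raw four-metric vector for one (image, variant) pair.

    ``variant_id`` 0 denotes the original image; 1..V the enhancer variants.
    """

    image_id: str
    variant_id: int
    uiqm: float
    uciqe: float
    ccf: float
    entropy: float
    variant_name: str = ""

    def __post_init__(self) -> None:
        if self.variant_id < 0:
            raise ValueError(f"variant_id must be >= 0, got {self.variant_id}")
        for name in ("uiqm", "uciqe", "ccf", "entropy"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite for image {self.image_id!r}")
        if not 0.0 <= self.entropy <= 8.0:
            raise ValueError(f"entropy must lie in [0, 8], got {self.entropy}")


def _validate_image(image: np.ndarray) -> np.ndarray:
    """Check the RGB image contract and return a float64 copy."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"image must be at least 8x8 pixels, got {arr.shape[:2]}")
    arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr


def _grayscale(arr: np.ndarray) -> np.ndarray:
    wr, wg, wb = LUMA_WEIGHTS
    return wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]


def _block_view(arr: np.ndarray, block: int = BLOCK_SIZE) -> np.ndarray:
    """Tile ``arr`` into full ``block`` x ``block`` blocks, truncating borders.

    Returns an array of shape (n_blocks, block*block). Raises if the image is
    smaller than a single block in either dimension.
    """
    h, w = arr.shape
    nbh, nbw = h // block, w // block
    if nbh == 0 or nbw == 0:
        raise ValueError(
            f"image of shape {arr.shape} is smaller than one {block}x{block} analysis block"
        )
    trimmed = arr[: nbh * block, : nbw * block]
    blocks = trimmed.reshape(nbh, block, nbw, block).swapaxes(1, 2)
    return blocks.reshape(nbh * nbw, block * block)


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

def compute_entropy(image: np.ndarray) -> float:
    """Shannon entropy (bits) of the 8-bit grayscale histogram.

    Gray levels are obtained with the standard luma weights and rounded to the
    nearest integer level; the histogram has 256 bins and empty bins
    contribute zero (``0 * log 0 := 0``). The result lies in [0, 8].
    """
    arr = _validate_image(image)
    gray = np.clip(np.rint(_grayscale(arr)), 0, 255).astype(np.intp)
    counts = np.bincount(gray.ravel(), minlength=256)
    p = counts[counts > 0] / gray.size
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# UIQM
# ---------------------------------------------------------------------------

def _trimmed_mean(values: np.ndarray, alpha: float = UICM_TRIM_FRACTION) -> float:
    """Asymmetric alpha-trimmed mean: drop floor(alpha*N) values on each tail."""
    x = np.sort(values.ravel())
    n = x.size
    t = int(alpha * n)
    kept = x[t : n - t] if n - 2 * t > 0 else x
    return float(kept.mean())


def _eme(channel: np.ndarray, block: int = BLOCK_SIZE) -> float:
    """Enhancement-measure estimate: mean block log-ratio of max to min.

    Blocks whose minimum (or maximum) is zero carry no ratio information and
    contribute zero.
    """
    blocks = _block_view(channel, block)
    bmax = blocks.max(axis=1)
    bmin = blocks.min(axis=1)
    valid = (bmin > 0) & (bmax > 0)
    out = np.zeros(blocks.shape[0])
    out[valid] = np.log(bmax[valid] / bmin[valid])
    return float(2.0 / blocks.shape[0] * out.sum())


def _log_amee(channel: np.ndarray, block: int = BLOCK_SIZE) -> float:
    """Plain log-AMEE contrast over blocks of the given channel.

    Uses the Michelson block contrast t = (max-min)/(max+min) and the
    entropy-style kernel -t*log(t); degenerate blocks (t = 0 or max+min = 0)
    contribute zero. Nonnegative; zero for a constant image.
    """
    blocks = _block_view(channel, block)
    bmax = blocks.max(axis=1)
    bmin = blocks.min(axis=1)
    denom = bmax + bmin
    valid = denom > 0
    t = np.zeros(blocks.shape[0])
    t[valid] = (bmax[valid] - bmin[valid]) / denom[valid]
    pos = t > 0
    return float(-(t[pos] * np.log(t[pos])).sum() / blocks.shape[0])


def compute_uicm(image: np.ndarray) -> float:
    """Colorfulness component of UIQM from the RG / YB opponent channels."""
    arr = _validate_image(image)
    rg = arr[..., 0] - arr[..., 1]
    yb = 0.5 * (arr[..., 0] + arr[..., 1]) - arr[..., 2]
    mu_rg = _trimmed_mean(rg)
    mu_yb = _trimmed_mean(yb)
    # second moments taken about the trimmed mean, over all pixels
    var_rg = float(np.mean((rg - mu_rg) ** 2))
    var_yb = float(np.mean((yb - mu_yb) ** 2))
    return UICM_COEFFS["mu"] * math.hypot(mu_rg, mu_yb) + UICM_COEFFS["sigma"] * math.sqrt(
        var_rg + var_yb
    )


_SOBEL_X = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


def _sobel_magnitude(channel: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(channel, _SOBEL_X, mode="reflect")
    gy = ndimage.convolve(channel, _SOBEL_Y, mode="reflect")
    return np.hypot(gx, gy)


def compute_uism(image: np.ndarray) -> float:
    """Sharpness component of UIQM: luma-weighted EME of edge-enhanced channels."""
    arr = _validate_image(image)
    total = 0.0
    for idx, key in enumerate(("r", "g", "b")):
        channel = arr[..., idx]
        edge = _sobel_magnitude(channel) * channel
        total += UISM_LUMA_WEIGHTS[key] * _eme(edge)
    return total


def compute_uiconm(image: np.ndarray) -> float:
    """Contrast component of UIQM: log-AMEE of the luma channel."""
    arr = _validate_image(image)
    return _log_amee(_grayscale(arr))


def compute_uiqm(image: np.ndarray) -> MetricResult:
    """Underwater Image Quality Measure.

    ``total = c1*UICM + c2*UISM + c3*UIConM`` with the canonical coefficients
    in :data:`UIQM_COEFFS`; the three components are exposed in
    ``result.components``.
    """
    components = {
        "uicm": compute_uicm(image),
        "uism": compute_uism(image),
        "uiconm": compute_uiconm(image),
    }
    total = sum(UIQM_COEFFS[k] * v for k, v in components.items())
    return MetricResult(total=total, components=components, weights=dict(UIQM_COEFFS))


# ---------------------------------------------------------------------------
# UCIQE
# ---------------------------------------------------------------------------

def compute_uciqe(image: np.ndarray) -> MetricResult:
    """Underwater Color Image Quality Evaluation.

    Computed in CIELAB (D65): chroma standard deviation, luminance contrast
    (99th minus 1st percentile of L) and mean saturation
    ``C / sqrt(C^2 + L^2)``, combined with :data:`UCIQE_COEFFS`. Chroma and
    luminance are expressed on the [0, 1] scale (LAB values / 100) so the
    total is a small bounded score; saturation is scale-free.
    """
    arr = _validate_image(image)
    lab = color.rgb2lab(arr / 255.0)
    lum = lab[..., 0] / 100.0
    chroma = np.hypot(lab[..., 1], lab[..., 2]) / 100.0
    sigma_chroma = float(chroma.std())
    con_luminance = float(np.percentile(lum, 99) - np.percentile(lum, 1))
    norm = np.hypot(chroma, lum)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(norm > 0, chroma / np.where(norm > 0, norm, 1.0), 0.0)
    mu_saturation = float(sat.mean())
    components = {
        "sigma_chroma": sigma_chroma,
        "con_luminance": con_luminance,
        "mu_saturation": mu_saturation,
    }
    total = sum(UCIQE_COEFFS[k] * v for k, v in components.items())
    return MetricResult(total=total, components=components, weights=dict(UCIQE_COEFFS))


# ---------------------------------------------------------------------------
# CCF
# ---------------------------------------------------------------------------

def _hasler_colorfulness(arr: np.ndarray) -> float:
    rg = arr[..., 0] - arr[..., 1]
    yb = 0.5 * (arr[..., 0] + arr[..., 1]) - arr[..., 2]
    sigma = math.hypot(float(rg.std()), float(yb.std()))
    mu = math.hypot(float(rg.mean()), float(yb.mean()))
    return sigma + 0.3 * mu


def _clearness(arr: np.ndarray, block: int = BLOCK_SIZE) -> float:
    """Anti-fog term on a 0-100 scale from the local dark channel.

    A veiled (hazy) image has a bright dark channel everywhere; a clear image
    has dark-channel values near zero. Clearness = 100 * (1 - mean dark
    channel / 255), with the dark channel taken as the local minimum over a
    square window across the three color channels.
    """
    per_pixel_min = arr.min(axis=2)
    dark = ndimage.minimum_filter(per_pixel_min, size=block, mode="nearest")
    return 100.0 * (1.0 - float(dark.mean()) / 255.0)


def compute_ccf(image: np.ndarray) -> MetricResult:
    """Colorfulness-contrast-fog composite.

    ``total = w1*colorfulness + w2*contrast + w3*clearness`` with the
    regression weights in :data:`CCF_WEIGHTS`. Colorfulness is the
    Hasler-Suesstrunk opponent statistic on 0-255 channels, contrast the RMS
    (standard-deviation) contrast of the luma channel, and clearness a
    dark-channel anti-fog score on a 0-100 scale.
    """
    arr = _validate_image(image)
    components = {
        "colorfulness": _hasler_colorfulness(arr),
        "contrast": float(_grayscale(arr).std()),
        "clearness": _clearness(arr),
    }
    total = sum(CCF_WEIGHTS[k] * v for k, v in components.items())
    return MetricResult(total=total, components=components, weights=dict(CCF_WEIGHTS))


# ---------------------------------------------------------------------------
# Batch scoring
# ---------------------------------------------------------------------------

def score_image(image_id: str, variant_id: int, image: np.ndarray, variant_name: str = "") -> QualityRecord:
    """Compute all four metrics for one image and package them as a record."""
    return QualityRecord(
        image_id=str(image_id),
        variant_id=int(variant_id),
        uiqm=compute_uiqm(image).total,
        uciqe=compute_uciqe(image).total,
        ccf=compute_ccf(image).total,
        entropy=compute_entropy(image),
        variant_name=variant_name,
    )


def score_collection(images, on_error: str = "collect"):
    """Score a collection of ``(image_id, variant_id, image)`` items.

    Parameters
    ----------
    images
        Iterable of ``(image_id, variant_id, image)`` or
        ``(image_id, variant_id, image, variant_name)`` tuples.
    on_error
        ``"collect"`` records per-item failures and continues; ``"raise"``
        propagates the first failure.

    Returns
    -------
    records : list of QualityRecord
    summary : pandas.DataFrame
        Per-variant mean and standard deviation of each metric
        (index ``variant_id``, columns like ``uiqm_mean``/``uiqm_std``).
    errors : list of (image_id, variant_id, message)
    """
    import pandas as pd

    records: list[QualityRecord] = []
    errors: list[tuple[str, int, str]] = []
    count = 0
    for item in images:
        count += 1
        image_id, variant_id, image = item[0], item[1], item[2]
        variant_name = item[3] if len(item) > 3 else ""
        try:
            records.append(score_image(image_id, variant_id, image, variant_name))
        except Exception as exc:  # noqa: BLE001 - record-level error collection
            if on_error == "raise":
                raise
            errors.append((str(image_id), int(variant_id), str(exc)))
    if count == 0:
        raise ValueError("score_collection requires at least one image")
    summary = summarize_records(records)
    return records, summary, errors


def summarize_records(records: list[QualityRecord]):
    """Per-variant mean/std of each metric (the summary-table shape)."""
    import pandas as pd

    if not records:
        return pd.DataFrame(
            columns=[f"{m}_{s}" for m in ("uiqm", "uciqe", "ccf", "entropy") for s in ("mean", "std")]
        )
    df = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "uiqm": [r.uiqm for r in records],
            "uciqe": [r.uciqe for r in records],
            "ccf": [r.ccf for r in records],
            "entropy": [r.entropy for r in records],
        }
    )
    agg = df.groupby("variant_id").agg(["mean", "std"])
    agg.columns = [f"{metric}_{stat}" for metric, stat in agg.columns]
    # a single record per variant has undefined sample std; report 0 spread
    return agg.fillna(0.0)
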