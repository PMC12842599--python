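"""Seeded synthetic scenarios emulating enhancement-detection interactions.

Real underwater benchmarks couple three things the analysis modules care
about: (1) originals whose quality distribution is roughly bimodal (a
degraded mode and a clearer mode), (2) enhancement that tends to improve
low-quality images and degrade already-good ones, and (3) detection behavior
(recall, localization, false positives) that worsens as image quality drops.
This module encodes each as a small, fully parameterized law so that every
pipeline stage can be tested offline with analytically pinned expectations:

* :class:`QualityLaw` — a two-component Gaussian mixture for the latent
  original quality q0 in [0, 1];
* :class:`ResponseLaw` — a piecewise-linear map from (q0, variant) to the
  variant's latent quality q_v: variants pull quality toward the crossover
  point from below (improvement) and push it down from above (degradation),
  with per-variant gain and i.i.d. response noise;
* :class:`DetectionLaw` — miss probability, localization jitter (pixels) and
  Poisson false-positive rate, each linear in (1 - q); confidences decrease
  with realized jitter.

Everything is driven by ``numpy.random.default_rng`` seeded from the config,
so the same seed reproduces a scenario bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from uweval.det_io import (
    Box,
    DetectionSet,
    GroundTruthSet,
    write_detections,
    write_ground_truth,
)

__all__ = [
    "QualityLaw",
    "ResponseLaw",
    "DetectionLaw",
    "ScenarioConfig",
    "Scenario",
    "generate_degraded_image",
    "generate_scenario",
    "scenario_image",
    "scenario_to_files",
]


@dataclass(frozen=True)
class QualityLaw:
    """Bimodal latent-quality mixture for original images.

    Defaults place a heavier degraded mode near 0.37 and a clearer mode near
    0.58, echoing the two-peaked original-quality distributions underwater
    benchmarks exhibit.
    """

    means: tuple[float, float] = (0.37, 0.58)
    sigmas: tuple[float, float] = (0.06, 0.06)
    weights: tuple[float, float] = (0.55, 0.45)

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("mixture sigmas must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.choice(2, size=n, p=self.weights)
        q = rng.normal(np.take(self.means, comp), np.take(self.sigmas, comp))
        return np.clip(q, 0.02, 0.98)


@dataclass(frozen=True)
class ResponseLaw:
    """Piecewise-linear enhancement response around a crossover quality.

    For variant v with gain g_v::

        q_v = q0 + g_v * improve_slope * (crossover - q0)   if q0 <  crossover
        q_v = q0 - g_v * degrade_slope * (q0 - crossover)   if q0 >= crossover

    plus N(0, noise_sd) response noise, clipped to [0, 1]. ``variant_gains``
    defaults to values evenly spaced in [0.6, 1.0] over the V variants.
    """

    crossover: float = 0.5
    improve_slope: float = 0.6
    degrade_slope: float = 0.6
    noise_sd: float = 0.06
    variant_gains: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.crossover < 1.0:
            raise ValueError("crossover must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def gains(self, n_variants: int) -> np.ndarray:
        if self.variant_gains is not None:
            if len(self.variant_gains) != n_variants:
                raise ValueError(
                    f"variant_gains has {len(self.variant_gains)} entries for {n_variants} variants"
                )
            return np.asarray(self.variant_gains, dtype=float)
        if n_variants == 1:
            return np.array([1.0])
        return np.linspace(0.6, 1.0, n_variants)

    def apply(self, q0: np.ndarray, gain: float, rng: np.random.Generator) -> np.ndarray:
        shift = np.where(
            q0 < self.crossover,
            gain * self.improve_slope * (self.crossover - q0),
            -gain * self.degrade_slope * (q0 - self.crossover),
        )
        noise = rng.normal(0.0, self.noise_sd, size=q0.shape) if self.noise_sd > 0 else 0.0
        return np.clip(q0 + shift + noise, 0.0, 1.0)


@dataclass(frozen=True)
class DetectionLaw:
    """Quality-dependent detection behavior.

    All three laws interpolate linearly between their value at q = 1 (clear)
    and q = 0 (fully degraded):

    * miss probability: ``p_miss(q) = miss_clear + (miss_degraded - miss_clear) * (1 - q)``
    * localization jitter sd (pixels): same shape between ``jitter_clear``
      and ``jitter_degraded``;
    * false positives per image: Poisson with rate between ``fp_rate_clear``
      and ``fp_rate_degraded``.

    Detection confidence is ``conf_base - conf_jitter_cost * |jitter| +
    N(0, conf_noise_sd)``, clipped to [0.05, 0.99], so poorly localized boxes
    rank lower.
    """

    miss_clear: float = 0.05
    miss_degraded: float = 0.60
    jitter_clear: float = 0.5
    jitter_degraded: float = 7.0
    fp_rate_clear: float = 0.15
    fp_rate_degraded: float = 1.5
    conf_base: float = 0.92
    conf_jitter_cost: float = 0.04
    conf_noise_sd: float = 0.03
    #: Correlation of per-box detectability / jitter latents across variants.
    #: 1 means fully shared scene difficulty; 0 means independent detectors.
    variant_corr: float = 0.99

    def __post_init__(self) -> None:
        for name in ("miss_clear", "miss_degraded"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.variant_corr <= 1.0:
            raise ValueError(f"variant_corr must lie in [0, 1], got {self.variant_corr}")
        for name in ("jitter_clear", "jitter_degraded", "fp_rate_clear", "fp_rate_degraded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def p_miss(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return np.clip(self.miss_clear + (self.miss_degraded - self.miss_clear) * (1.0 - q), 0.0, 1.0)

    def jitter_sd(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return self.jitter_clear + (self.jitter_degraded - self.jitter_clear) * (1.0 - q)

    def fp_rate(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return self.fp_rate_clear + (self.fp_rate_degraded - self.fp_rate_clear) * (1.0 - q)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic study.

    Defaults describe a mid-sized study: 200 annotated images, nine enhancer
    variants, three object categories, 800x600 nominal image frames with one
    to six ground-truth boxes per image.
    """

    n_images: int = 200
    n_variants: int = 9
    seed: int = 0
    image_width: int = 800
    image_height: int = 600
    n_categories: int = 3
    boxes_per_image: tuple[int, int] = (1, 6)
    quality_law: QualityLaw = field(default_factory=QualityLaw)
    response_law: ResponseLaw = field(default_factory=ResponseLaw)
    detection_law: DetectionLaw = field(default_factory=DetectionLaw)

    def __post_init__(self) -> None:
        if self.n_images < 1 or self.n_variants < 0:
            raise ValueError("need n_images >= 1 and n_variants >= 0")
        lo, hi = self.boxes_per_image
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid boxes_per_image range {self.boxes_per_image}")
        if self.n_categories < 1:
            raise ValueError("need at least one category")


@dataclass
class Scenario:
    """A generated study: ground truth, per-variant detections, latent state.

    ``qualities`` is an (n_images, V+1) array of latent qualities q_{n,v}
    (column 0 = original). ``oracle_best`` records, per image, the variant
    with the highest latent quality (ties to the original) — the
    detection-optimal variant in expectation under the detection law.
    """

    config: ScenarioConfig
    ground_truth: GroundTruthSet
    detections: list[DetectionSet]
    qualities: np.ndarray
    oracle_best: dict[int, int]

    @property
    def variant_names(self) -> list[str]:
        return ["original"] + [f"enh{v}" for v in range(1, self.config.n_variants + 1)]


# ---------------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------------

def _base_image(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    """Smooth random texture with broad dynamic range, float in [0, 255]."""
    from scipy import ndimage

    coarse = rng.uniform(0.0, 1.0, size=(max(height // 8, 2), max(width // 8, 2), 3))
    field = np.stack(
        [
            ndimage.zoom(coarse[..., c], (height / coarse.shape[0], width / coarse.shape[1]), order=1)
            for c in range(3)
        ],
        axis=-1,
    )[:height, :width]
    fine = rng.uniform(-0.08, 0.08, size=field.shape)
    return np.clip((field * 0.9 + 0.05 + fine) * 255.0, 0.0, 255.0)


#: Per-channel attenuation at full cast strength (red absorbed most).
_CAST_ATTENUATION = (0.75, 0.25, 0.05)
#: Veil (background light) level toward which haze compresses contrast.
_VEIL_LEVEL = (110.0, 160.0, 175.0)


def generate_degraded_image(seed: int, width: int = 96, height: int = 72,
                            cast_strength: float = 0.0, haze_strength: float = 0.0,
                            noise_sigma: float = 0.0) -> np.ndarray:
    """Textured test image with underwater-style degradations, uint8 RGB.

    Degradations, applied in order to a seed-deterministic base texture:

    * color cast: per-channel attenuation scaled by ``cast_strength``
      (red suppressed most, mimicking wavelength-dependent absorption);
    * haze: affine contrast compression toward a bluish-green veil level,
      full strength yielding a constant veil image;
    * sensor noise: additive Gaussian with sd ``noise_sigma``, clipped.

    With all strengths zero the base image is returned unchanged, so the same
    seed always reproduces the same scene across degradation settings.
    """
    if not (0.0 <= cast_strength <= 1.0 and 0.0 <= haze_strength <= 1.0):
        raise ValueError("cast_strength and haze_strength must lie in [0, 1]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    img = _base_image(rng, width, height)
    atten = 1.0 - cast_strength * np.asarray(_CAST_ATTENUATION)
    img = img * atten
    veil = np.asarray(_VEIL_LEVEL)
    img = (1.0 - haze_strength) * img + haze_strength * veil
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def scenario_image(scenario: Scenario, image_id: int, variant_id: int,
                   width: int = 96, height: int = 72) -> np.ndarray:
    """Render the (image, variant) pair of a scenario as a degraded image.

    The base scene depends only on the image id (shared across variants);
    degradation strengths decrease with the latent quality q_{n,v}, so
    measured quality metrics track the latent state.
    """
    q = float(scenario.qualities[image_id, variant_id])
    return generate_degraded_image(
        seed=(scenario.config.seed * 100003 + image_id) % (2**31),
        width=width,
        height=height,
        cast_strength=0.85 * (1.0 - q),
        haze_strength=0.65 * (1.0 - q),
        noise_sigma=8.0 * (1.0 - q),
    )


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

def _random_gt_boxes(rng: np.random.Generator, config: ScenarioConfig):
    lo, hi = config.boxes_per_image
    n = int(rng.integers(lo, hi + 1))
    boxes = []
    for _ in range(n):
        w = float(rng.uniform(20, min(180, config.image_width / 2)))
        h = float(rng.uniform(20, min(180, config.image_height / 2)))
        x = float(rng.uniform(0, config.image_width - w))
        y = float(rng.uniform(0, config.image_height - h))
        cat = int(rng.integers(1, config.n_categories + 1))
        boxes.append((Box(x, y, w, h), cat))
    return boxes


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Draw a full scenario from the configured laws.

    Per image: q0 from the quality law; q_v from the response law; one to six
    ground-truth boxes; per variant, each ground-truth box is detected with
    probability 1 - p_miss(q_v), jittered with sd sigma(q_v), and
    Poisson(lambda(q_v)) false positives are added with low-to-moderate
    confidences. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, V = config.n_images, config.n_variants
    law = config.detection_law

    q = np.zeros((n, V + 1))
    q[:, 0] = config.quality_law.sample(rng, n)
    gains = config.response_law.gains(V) if V else np.zeros(0)
    for v in range(1, V + 1):
        q[:, v] = config.response_law.apply(q[:, 0], float(gains[v - 1]), rng)

    gt_boxes = {image_id: _random_gt_boxes(rng, config) for image_id in range(n)}
    categories = {c: f"category_{c}" for c in range(1, config.n_categories + 1)}
    ground_truth = GroundTruthSet(boxes=gt_boxes, categories=categories)

    # Per-box latents couple the variants: each box carries a shared
    # difficulty draw mixed with an independent per-variant component at
    # correlation `variant_corr`. Marginals stay as specified (detected with
    # prob 1 - p_miss(q_v), jitter sd sigma(q_v)); jointly, per-image
    # difficulty is strongly correlated across variants, as for real scenes
    # seen through different enhancers, while each variant keeps detector
    # idiosyncrasies of its own.
    rho = law.variant_corr
    mix = math.sqrt(max(1.0 - rho * rho, 0.0))
    from scipy.stats import norm as _norm

    box_latents = {
        image_id: [
            {
                "z_miss": float(rng.normal()),
                "z_miss_var": rng.normal(size=V + 1),
                "jitter": rng.normal(0.0, 1.0, size=4),
                "jitter_var": rng.normal(0.0, 1.0, size=(V + 1, 4)),
                "conf_noise": float(rng.normal(0.0, 1.0)),
            }
            for _ in gt_boxes[image_id]
        ]
        for image_id in range(n)
    }

    detections: list[DetectionSet] = []
    for v in range(V + 1):
        per_image: dict[int, list[tuple[Box, int, float]]] = {}
        for image_id in range(n):
            qv = float(q[image_id, v])
            p_miss = float(law.p_miss(qv))
            sigma = float(law.jitter_sd(qv))
            dets: list[tuple[Box, int, float]] = []
            for (box, cat), latent in zip(gt_boxes[image_id], box_latents[image_id]):
                u_miss = _norm.cdf(rho * latent["z_miss"] + mix * latent["z_miss_var"][v])
                if u_miss < p_miss:
                    continue
                gx, gy, gw, gh = rho * latent["jitter"] + mix * latent["jitter_var"][v]
                dx, dy = gx * sigma, gy * sigma
                jittered = Box(
                    x=box.x + dx,
                    y=box.y + dy,
                    w=max(box.w + gw * sigma / 2.0, 4.0),
                    h=max(box.h + gh * sigma / 2.0, 4.0),
                )
                jitter_mag = math.hypot(dx, dy)
                conf = law.conf_base - law.conf_jitter_cost * jitter_mag
                conf += law.conf_noise_sd * latent["conf_noise"]
                dets.append((jittered, cat, float(np.clip(conf, 0.05, 0.99))))
            n_fp = int(rng.poisson(law.fp_rate(qv)))
            for _ in range(n_fp):
                fp_box, fp_cat = _random_gt_boxes(rng, replace(config, boxes_per_image=(1, 1)))[0]
                dets.append((fp_box, fp_cat, float(rng.uniform(0.05, 0.45))))
            if dets:
                per_image[image_id] = dets
        detections.append(
            DetectionSet(variant_id=v, detections=per_image,
                         variant_name="original" if v == 0 else f"enh{v}")
        )

    oracle_best: dict[int, int] = {}
    for image_id in range(n):
        row = q[image_id]
        best = row.max()
        oracle_best[image_id] = 0 if row[0] == best else int(np.argmax(row))

    return Scenario(config=config, ground_truth=ground_truth, detections=detections,
                    qualities=q, oracle_best=oracle_best)


def scenario_to_files(scenario: Scenario, out_dir, write_images: bool = False,
                      image_size: tuple[int, int] = (96, 72)) -> dict:
    """Serialize a scenario to COCO JSON files plus a YAML manifest.

    Writes ``ground_truth.json``, one ``detections_<variant>.json`` per
    variant and ``manifest.yaml``; with ``write_images=True`` also renders a
    PNG per (image, variant) under ``<variant_name>/<image_id>.png``.
    Round-trips through :mod:`uweval.det_io` reproduce boxes and scores
    exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt_path = out_dir / "ground_truth.json"
    write_ground_truth(scenario.ground_truth, gt_path)
    variants = []
    for ds, name in zip(scenario.detections, scenario.variant_names):
        det_path = out_dir / f"detections_{name}.json"
        write_detections(ds, det_path)
        entry = {"name": name, "variant_id": ds.variant_id, "detections": det_path.name}
        if write_images:
            img_dir = out_dir / name
            img_dir.mkdir(exist_ok=True)
            from PIL import Image

            width, height = image_size
            for image_id in scenario.ground_truth.image_ids:
                arr = scenario_image(scenario, image_id, ds.variant_id, width, height)
                Image.fromarray(arr).save(img_dir / f"{image_id}.png")
            entry["images"] = name
        variants.append(entry)
    manifest = {
        "ground_truth": gt_path.name,
        "seed": scenario.config.seed,
        "variants": variants,
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return {"ground_truth": gt_path, "manifest": manifest_path, "out_dir": out_dir}
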