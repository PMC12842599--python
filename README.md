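# uweval

Quality–detection evaluation for underwater imagery: does image enhancement
actually help object detection, and for which images?

Underwater images suffer wavelength-dependent color casts, haze and low
visibility, so enhancement is routinely applied before running detectors —
yet dataset-level mAP usually drops after enhancement. `uweval` implements
the analysis framework that resolves this apparent contradiction by working
at the level where the effect varies: the individual image. It is a library
for researchers studying enhancement–detection interactions (plus a thin
`uweval` CLI), built around three components:

1. **Composite quality index (Q-index).** Four no-reference metrics — UIQM,
   UCIQE, CCF and grayscale entropy — are combined per (image, variant) pair
   by outlier removal (3 scaled MADs), global min–max rescaling over all
   variants jointly, and equal-weight averaging into a bounded score

   Q = Σₘ wₘ·m̃,  m̃ = (m − min m)/(max m − min m),  wₘ = ¼,

   with ΔQ = Q(enhanced) − Q(original) describing how enhancement shifts the
   quality distribution.

2. **Per-image mAP₅₀:₉₅.** The COCO protocol applied to a single image:
   greedy confidence-ordered matching at IoU thresholds 0.50:0.05:0.95,
   101-point interpolated AP, averaged over the categories present in that
   image's ground truth and over thresholds. This attributes detection
   changes image by image instead of hiding them in a dataset average.

3. **Mixed-set upper bound.** With scores mAPₙ,ᵥ for image n under variant v
   (v = 0 the original), the oracle keeps the best version of every image:

   v*ₙ = argmaxᵥ mAPₙ,ᵥ,  S_mix = {(n, v*ₙ)},  m̄AP_mix = (1/N) Σₙ mAPₙ,v*ₙ.

   The gap between m̄AP_mix and the original column is the detection
   performance a perfect per-image enhancement selector could recover; the
   composition of S_mix shows which enhancers contribute it.

A seeded synthetic generator (`uweval.synthetic`) produces images, COCO
ground truth and detections whose behavior depends on a latent per-image
quality — low-quality images improve under enhancement, high-quality images
degrade — so the whole pipeline runs and is validated without external
datasets. See `docs/methods.md` for the model details and design choices.

## Worked example

`examples/mixed_set_upper_bound.py` generates a default synthetic study
(200 images, 9 enhancer variants), scores the per-image mAP matrix and
builds the mixed set:

```
mean per-image mAP_50:95 per set:
  original   0.481
  variant_1  0.480
  ...
  variant_9  0.491
  mixed      0.585   (+0.104 abs, +21.6% rel)

mixed-set composition (fraction of images drawn from each variant):
  original   0.260
  enh1       0.130
  ...
  enh9       0.070
original is plurality source: True
```

No single variant beats the original on average (0.47–0.49 everywhere), yet
the mixed set reaches 0.585 — a 21.6% relative improvement that only a
per-image selector could realize. The original is the largest single source
of the mixed set (enhancement is often unnecessary), while every enhancer
still contributes 6–13% of images (enhancement genuinely helps a subset,
concentrated at low quality). The other examples walk through the Q-index
pipeline (`quality_index_walkthrough.py`), the per-image protocol on
hand-built boxes (`per_image_map_demo.py`) and scenario file round trips
(`synthetic_scenario.py`).

File-based runs use COCO annotation/results JSON plus a small YAML manifest;
the CLI mirrors the library:

```bash
uweval simulate --out run/ --seed 3
uweval mixedset --root run/ --out run/results/
uweval permap --gt gt.json --dets original=dets0.json --dets enhA=detsA.json --out scores.csv
```

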