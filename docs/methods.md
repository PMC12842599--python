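# Methods

`uweval` studies the interaction between underwater image enhancement and
object detection at the granularity where it actually varies: the single
image. It implements three connected analyses — a composite no-reference
quality index, a per-image COCO-style detection score, and a mixed-set oracle
upper bound for selective enhancement — plus a fully parameterized synthetic
generator so that every stage can be exercised and validated offline.

## Quality metrics

Four established no-reference metrics are computed on 8-bit RGB images. The
exact coefficients used are exposed as module constants in `uweval.iqa`
(`UIQM_COEFFS`, `UICM_COEFFS`, `UCIQE_COEFFS`, `CCF_WEIGHTS`) and travel with
every `MetricResult`, so they are auditable both in code and in output.

**UIQM** = 0.0282·UICM + 0.2953·UISM + 3.5753·UIConM.

* UICM uses the RG/YB opponent channels with an asymmetric trimmed mean
  (trim fraction 0.1 per tail) and second moments taken about the trimmed
  mean: −0.0268·√(μ²_RG+μ²_YB) + 0.1586·√(σ²_RG+σ²_YB).
* UISM is the luma-weighted (0.299, 0.587, 0.114) EME of Sobel-edge-enhanced
  channels: blocks of 10×10 pixels, partial border blocks truncated, natural
  log of the block max/min ratio, blocks containing a zero skipped.
* UIConM is a plain log-AMEE of the luma channel: for each 10×10 block the
  Michelson contrast t = (max−min)/(max+min) contributes −t·ln t. The PLIP
  algebra some formulations wrap around this kernel is deliberately omitted:
  it is not identifiable from published result tables, and the plain form is
  the one most open implementations use. Consequence: UIConM is nonnegative,
  zero for constant images, and maximal for mid-contrast blocks.

**UCIQE** = 0.4680·σ_chroma + 0.2745·con_luminance + 0.2576·μ_saturation in
CIELAB (D65, 2° observer, via scikit-image). Chroma and luminance are placed
on a [0,1] scale (LAB/100); luminance contrast is the 99th minus the 1st
percentile of L; saturation is the scale-free C/√(C²+L²). A pure gray image
scores zero to ≈1e-4 (the LAB transform leaves a residual chroma of ~1e-3
LAB units on grays).

**CCF** = 0.17593·colorfulness + 0.61759·contrast + 0.33988·clearness.
Colorfulness is the Hasler–Süsstrunk opponent statistic on 0–255 channels;
contrast is the RMS (standard deviation) contrast of the luma channel;
clearness is an anti-fog term, 100·(1 − mean dark channel/255), with the
dark channel as the local min over a 10×10 window across channels. The
fog-density estimator behind the published metric is not specified precisely
in the literature we could rely on, so clearness is this package's own
documented estimator with the same monotonic intent (hazier → lower).

**Entropy** is the Shannon entropy (bits, base-2) of the 256-bin grayscale
histogram; grayscale via the 0.299/0.587/0.114 luma weights, rounded to the
nearest level; empty bins contribute 0. Range [0, 8].

Numeric identity with any particular published benchmark table is *not*
claimed for UIQM/UCIQE/CCF — white point, gamma and fog-estimator details
vary across implementations. What the test suite pins instead is internal
correctness: every component matches an independent straight-line
implementation of its defining formula (explicit loops, no shared code) to
1e-6 relative on fixed patterns and a 20-image synthetic corpus.

Images are processed at their stored resolution; any resizing is the
caller's concern (it belongs to detector input pipelines, not quality
scoring).

## Q-index

The Q-index is an analytical tool for distribution-level reasoning, not a
new perceptual metric. Pipeline, in this exact order:

1. **Outlier removal.** Per metric, pooled over all variants of a
   collection, values with |x − median| > 3·1.4826·MAD are dropped
   (1.4826 is the consistency constant that makes the MAD estimate a normal
   σ; the median itself can never be flagged). Pooling matches the global
   pooling of step 2 so both steps see the same population. A record that
   loses any metric is dropped from aggregation entirely and listed in
   `excluded` — imputation would invent values the analysis never defines.
2. **Global rescaling.** Min–max normalization per metric with bounds over
   all variants jointly (original included), outliers excluded from the
   bounds. A constant metric raises a `DegenerateScaleError` naming the
   metric rather than silently emitting a constant: a flat metric carries no
   ranking information and a silent default would distort the composite.
   The bounds are retained on the table so held-out values can be rescaled
   (clipped) later.
3. **Equal-weight aggregation.** qindex = Σ w_m·metric_m with default
   weights 0.25 each; weights are user-configurable, validated nonnegative,
   and renormalized to sum to 1.

ΔQ-index = qindex(variant) − qindex(original) per image. When outlier
removal dropped an original, its enhanced records have no baseline;
`delta_qindex` raises by default and can skip those records on request.

Weight sensitivity perturbs one weight at a time by ±25% (renormalizing) and
reports per-variant median qindex/Δ and the maximum absolute change against
the equal-weight baseline. Quality bins partition [0,1] into `n_bins`
(default 10) equal-width intervals, left-closed right-open with the last bin
closed so qindex 1.0 lands in the top bin; empty bins are reported.

## Per-image mAP

For one (image, variant) pair, and each category present in that image's
ground truth, detections are sorted by descending confidence (stable: equal
confidences keep file order, making results reproducible bit for bit) and
matched greedily — each detection takes the unmatched ground-truth box of
its category with the highest IoU at or above the threshold, else it is a
false positive; each ground-truth box matches at most once. APs are computed
at the ten IoU thresholds 0.50:0.05:0.95 with COCO's 101-point interpolated
precision (monotone precision envelope evaluated on the standard recall
grid; an all-point trapezoidal integrator is available via
`interpolation="trapezoid"` for sensitivity checks). Per threshold, APs are
averaged over the categories present in the image's ground truth; the ten
values average into mAP_50:95.

Conventions worth stating because the image-level protocol does not follow
automatically from the dataset-level one:

* categories with ground truth but no detections contribute AP 0; detections
  of categories absent from the image's ground truth are ignored for that
  image (mirrors COCO's per-category design; a documented limitation — such
  detections are never penalized at image level);
* images with zero ground-truth boxes have no recall axis; their score is
  undefined (`defined=False`, NaN) and they are excluded from set means and
  from the mixed-set N;
* no confidence floor and no max-detections cap are applied during scoring
  (both are configuration concerns of detector output, not of the protocol).

`dataset_map` implements the conventional pooled evaluation for comparison:
matching is still per image, but each category's PR curve pools the
confidence-ordered detections of all images. On single-image datasets it
coincides exactly with the per-image score. Both paths are validated to
1e-6 against an independent straight-line reference implementation of the
protocol that lives in the test suite.

## Mixed set

Given the N×(V+1) score matrix, the mixed set keeps, per image, the variant
with the highest per-image mAP; its mean is the oracle upper bound for
selective enhancement. Ties prefer the original and then the lowest variant
index: enhancement is an intervention, applied only when it strictly helps.
Ties are common here — per-image APs on few boxes take few distinct values —
so the tie rule is a real modeling choice, documented rather than attributed.
`compare_sets` reports per-set means plus the absolute and relative
improvement of mixed over original (full precision and integer-rounded;
undefined when the original mean is 0). `composition_stats` reports the
fraction of images drawn from each variant and whether the original is the
plurality source.

## Synthetic generator

The generator emulates the statistical structure the analyses are designed
to detect, with three small laws (all parameters explicit, everything driven
by one seed):

* **QualityLaw** — latent original quality q0 from a two-component Gaussian
  mixture, default means 0.37/0.58, σ 0.06, weights 0.55/0.45, clipped to
  [0.02, 0.98]: a heavier degraded mode and a clearer mode, the roughly
  bimodal shape underwater benchmarks show.
* **ResponseLaw** — enhancement pulls quality toward a crossover point
  (default 0.5) from below and pushes it down from above, linearly with
  per-variant gain (defaults evenly spaced in [0.6, 1.0] over 9 variants)
  plus N(0, 0.06) response noise: low-quality images improve, high-quality
  images over-enhance and degrade.
* **DetectionLaw** — miss probability, localization jitter (pixels) and
  Poisson false-positive rate each interpolate linearly between their values
  at q=1 (0.05, 0.5 px, 0.15/image) and q=0 (0.60, 7 px, 1.5/image);
  confidences decrease with realized jitter.

One structural choice matters: detection outcomes are **coupled across
variants** through shared per-box latents (one detectability draw, one
jitter direction per box) mixed with an independent per-variant component at
correlation `variant_corr` = 0.99. Marginally each variant still detects a
box with probability 1−p_miss(q_v) and jitters with sd σ(q_v); jointly,
per-image difficulty is nearly comonotone across variants — as it is for
real scenes viewed through different enhancers, where the same occluded or
tiny object is hard for every detector. With fully independent draws the
maximum of nine noisy rivals essentially always beats the original and the
mixed set degenerates to "always enhance"; the coupling restores the
empirically observed structure (the original as the plurality source of the
mixed set, individual enhancer shares of roughly 4–15%) while the small
independent component keeps per-variant idiosyncrasies and breaks ties.

`generate_degraded_image` renders seed-deterministic textured scenes with
three degradations applied in order: per-channel attenuation (red suppressed
most, as wavelength-dependent absorption does), affine contrast compression
toward a bluish-green veil (full strength yields a constant image), and
clipped additive Gaussian noise. `scenario_image` ties rendering to the
latent state: degradation strengths scale with 1−q_{n,v}, so the measured
Q-index of rendered originals correlates ≈0.9 with the latent quality.

What the generator does **not** emulate: real object appearance and texture
(boxes are placed on synthetic textures with no visual object inside),
classification confusions (detections keep their box's category), crowd or
overlapping-instance annotation pathologies, and any specific enhancement
algorithm's visual signature. Passing tests therefore demonstrate that the
*analysis machinery* recovers planted distributional structure — not that
any particular enhancer behaves this way on real reefs.

## Numerical choices and degenerate inputs

* Stable sorts everywhere an order matters (confidence ties keep input
  order); results are bit-reproducible for fixed inputs and seed.
* IoU is clamped to [0,1] against (x+w)−x roundoff; matching uses IoU ≥
  threshold, with equal-IoU candidates resolved to the lowest ground-truth
  index.
* The 101-point recall grid is built exactly as the standard tooling builds
  it (linspace), because grid values like 0.70 differ from 70/100 in the
  last bit and a recall landing exactly on a grid point must resolve the
  same way.
* Entropy of an empty histogram bin is defined as 0 (0·log 0 := 0); blocks
  with zero contrast or zero minimum contribute 0 to UIConM/UISM.
* Empty inputs (no records, no images, all-NaN score rows, zero weights)
  raise immediately with named errors rather than propagating NaN.

## Problem sizes

The test suite and the acceptance run use a 200-image, 9-variant scenario
with 1–6 boxes per image and three categories for distribution-level checks
(≈700 boxes, ≈2 s to score), a 700-image single-variant scenario for the
recall-recovery check (≈2400 boxes), 20-image random fixtures for protocol
equivalence against the reference implementation, and 16×16 fixed patterns
for the metric oracles. Rendered images for quality scoring are 64×48 —
the metrics are resolution-dependent in value but not in ordering, and the
analyses only consume orderings and distributions.

## Known limitations

* The metric implementations pin internal consistency, not numeric identity
  with any specific published table (see above).
* Per-image AP ignores detections of categories absent from that image's
  ground truth; a variant that hallucinates off-category boxes is not
  penalized at image level (it is at dataset level).
* The mixed set is an oracle bound, not a deployable selector; the package
  deliberately contains no predictive selection model.
* Crowd annotations (`iscrowd=1`) are rejected, not supported.
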