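"""Quality metrics and Q-index on a small set of degraded images.

Builds six synthetic underwater-style images at increasing degradation (color
cast, haze, noise), scores the four no-reference metrics on each, then runs
the three-step Q-index pipeline (outlier removal, global min-max rescaling,
equal-weight aggregation) treating the clean render of each scene as an
"enhanced" variant of its degraded original.
"""

from uweval import iqa, qindex
from uweval.synthetic import generate_degraded_image

records = []
for k in range(6):
    severity = k / 5.0
    degraded = generate_degraded_image(
        seed=50 + k, width=96, height=72,
        cast_strength=0.8 * severity, haze_strength=0.6 * severity, noise_sigma=6 * severity,
    )
    cleaner = generate_degraded_image(
        seed=50 + k, width=96, height=72,
        cast_strength=0.2 * severity, haze_strength=0.1 * severity, noise_sigma=severity,
    )
    records.append(iqa.score_image(f"scene{k}", 0, degraded))
    records.append(iqa.score_image(f"scene{k}", 1, cleaner, variant_name="enhanced"))

print("raw metrics (variant 0 = degraded original, 1 = enhanced):")
for r in records:
    print(f"  {r.image_id} v{r.variant_id}: UIQM={r.uiqm:6.2f}  UCIQE={r.uciqe:5.3f}  "
          f"CCF={r.ccf:6.2f}  Entropy={r.entropy:5.2f}")

table = qindex.build_qindex_table(records)
if table.excluded:
    print(f"\noutliers removed by the 3-scaled-MAD rule: {table.excluded}")
deltas = qindex.delta_qindex(table, on_missing="skip")
print("\nQ-index per record (bounded composite in [0, 1]):")
for _, row in table.records.iterrows():
    print(f"  {row['image_id']} v{row['variant_id']}: qindex={row['qindex']:.3f}")

print("\ndelta Q-index (enhanced minus original; positive = quality gained):")
for _, row in deltas.iterrows():
    print(f"  {row['image_id']}: {row['delta']:+.3f}")
print("\nMore severe originals gain more from enhancement - the heavier the")
print("degradation, the larger the delta; a near-clean scene barely moves.")
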