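"""Score inter-rater agreement with IoU on simulated annotations.

Two simulated pathologists outline the same phantom's tumors with sloppy
(jittered) boundaries; their pixel-level agreement is intersection over
union.  The published per-image agreement table is aggregated the same way.
"""

from virtualstain import agreement as agr
from virtualstain import generate_phantom, simulate_rater

ph = generate_phantom(seed=3, shape=(256, 256), grade="G3",
                      n_glands_range=(4, 6))
truth = ph.truth_mask()

rater_a = simulate_rater(truth, seed=10, boundary_jitter_px=2.0)
rater_b = simulate_rater(truth, seed=11, boundary_jitter_px=2.0)
mask_a = agr.rasterize(rater_a, ph.shape)
mask_b = agr.rasterize(rater_b, ph.shape)
print(f"inter-rater any-tumor IoU at 2 px jitter: "
      f"{agr.iou(mask_a, mask_b, 'any_tumor'):.3f}")
print(f"rater A vs ground truth:                  "
      f"{agr.iou(mask_a, truth, 'any_tumor'):.3f}")

table = agr.aggregate(agr.INTER_RATER_IOU)
print("\npublished per-class agreement, mean (SD) [n]:")
for cls in table.index:
    row = table.loc[cls]
    print(f"  {cls:10s} {row['mean']:.2f} ({row['sd']:.2f}) [{int(row['n'])}]")
# IoU of 1.0 is pixel-perfect agreement; boundary jitter alone pulls it
# below 1 even when both raters mark every tumor.
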