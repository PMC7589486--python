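"""Quantify one synthetic eye end-to-end: generate, segment, report densities.

Renders a paired FA/ICGA raster with known per-zone choroidal densities,
runs the segmentation + stereographic quantification pipeline, and compares
the recovered densities against the generator's ground truth.
"""

from uwfchoroid import SegmentationConfig, SyntheticImageSpec, generate_image_pair
from uwfchoroid.geometry import area_map
from uwfchoroid.pipeline import quantify_pair

pair = generate_image_pair(SyntheticImageSpec(seed=7))
metrics = quantify_pair(pair.fa, pair.icga, pair.trim, pair.model, SegmentationConfig())

print("Per-region vascular metrics (areas in mm^2, CVD in %):")
print(metrics.frame.round(2).to_string())
print()
print("zone   true CVD   recovered CVD   error (pp)")
for zone, truth in pair.achieved_cvd.items():
    got = metrics.cvd(zone)
    print(f"{zone:4s}   {truth:8.2f}   {got:13.2f}   {got - truth:+.2f}")
print()
print("CVD is the choroidal vascular area (ICGA total minus FA retinal area,")
print("each pixel weighted by its true retinal area on the 12 mm eye sphere)")
print("divided by the gradable area of the zone. Errors within ~2 percentage")
print("points show the pipeline recovers the known ground truth.")
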