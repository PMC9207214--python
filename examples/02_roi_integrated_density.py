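"""Measure ROI integrated density on a synthetic image stack.

Renders a bright Gaussian blob over a flat background, measures the
integrated density inside a polygon ROI with background subtraction,
and compares against the analytic (noise-free) truth.
"""

import numpy as np

from olcquant import RoiSpec, generate_image_stack, measure_integrated_density

roi = RoiSpec(
    "cell0", "polygon",
    vertices=[[1.5, 1.5], [1.5, 8.5], [8.5, 8.5], [8.5, 1.5]],
    background=[[9.5, 9.5], [9.5, 11.5], [11.5, 11.5], [11.5, 9.5]],
)
stack, truth = generate_image_stack(
    n_frames=5, height=13, width=13, blob_path=[(5, 5)],
    blob_amplitude=50.0, background_level=10.0, noise_sd=0.5,
    roi=roi, seed=2,
)

trace = measure_integrated_density(stack, roi)  # background-subtracted
raw_truth_minus_bg = truth - 10.0 * 49          # 49 pixels inside the ROI

print("frame  measured  analytic(minus background)")
for t, m, a in zip(trace.times, trace.values, raw_truth_minus_bg):
    print(f"{t:5.0f}  {m:8.1f}  {a:8.1f}")
print("\nThe measured per-frame integrated density tracks the analytic "
      "blob mass inside the ROI; background subtraction removes the "
      "flat 10-counts/pixel offset.")
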