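"""Extract an orientation field from a filament-textured image.

Builds a synthetic actin-like texture aligned at 30 degrees, runs the
structure-tensor analysis, and reports the dominant orientation and the
orientation histogram.
"""

import numpy as np

from nemaflow import orientfield as of
from nemaflow import synthgen as sg

field_true = sg.gen_uniform_field((300, 300), 20.0)
image = sg.gen_filament_image(field_true, filament_length=15,
                              filament_density=0.03, seed=1)

pmap = of.structure_tensor(image, sigma_gradient=1.5, sigma_window=10)
hist = of.orientation_histogram(pmap, bin_width=20.0, min_coherency=0.25)
grid = of.sample_grid(pmap, grid_size=50, min_coherency=0.25)

print(f"dominant orientation: {hist.mode_angle():.1f} deg (true: 20.0 deg)")
print(f"grid field: {grid.shape[0]}x{grid.shape[1]} vectors, "
      f"{grid.n_valid} above the 25% coherency gate")
print("histogram (20 deg bins, frequencies):")
for lo, hi, f in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.frequency):
    bar = "#" * int(round(40 * f))
    print(f"  ({lo:+6.0f}, {hi:+6.0f}]  {f:.3f} {bar}")
# The mode sits in the bin containing the texture direction; off-axis bins
# carry only the 3-degree filament jitter and estimator noise.
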