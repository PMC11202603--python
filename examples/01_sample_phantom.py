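"""Sample one abdominal phantom and inspect its anatomy and ground truth.

The phantom carries per-cell speed of sound, attenuation (AC) and density
maps, a speckle scatterer cloud and the liver AC used as the regression
target.
"""

import numpy as np

from sonoac import PhantomSpec, sample_phantom, warp_axial_grid
from sonoac.phantom import TISSUE_LABELS

spec = PhantomSpec(seed=42)
tm = sample_phantom(spec)
tm = warp_axial_grid(tm, spec.probe_curvature_radius)

depth, width = tm.extent_mm
print(f"grid: {tm.label_map.shape} cells = {depth:.0f} x {width:.0f} mm")
print(f"liver AC ground truth: {tm.liver_ac_truth:.3f} dB/cm/MHz")
print(f"liver semi-axes: {tm.meta['liver_semi_axes_mm'][0]:.1f} x "
      f"{tm.meta['liver_semi_axes_mm'][1]:.1f} mm")
print(f"{tm.meta['n_layers']} superficial layers, {tm.meta['n_vessels']} vessel objects, "
      f"{len(tm.scatterers)} scatterers "
      f"({tm.meta['scatterers_per_unit_area']} per wavelength^2)")
for name, code in TISSUE_LABELS.items():
    frac = (tm.label_map == code).mean()
    if frac > 0:
        print(f"  {name:7s} {100 * frac:5.1f}% of cells")

# The warped top boundary follows the convex probe face.
first_skin = np.argmax(tm.label_map == TISSUE_LABELS["skin"], axis=0) * tm.cell_size
print(f"probe-face sagitta across the aperture: 0 .. {first_skin.max():.1f} mm")
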