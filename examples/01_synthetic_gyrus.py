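"""Build the default synthetic gyral blade and split its white matter.

The phantom is a single human-scale cortical fold: a sinusoidal
white/grey boundary (16 mm wavelength, 8 mm amplitude) extruded to a
12 mm blade, with the pial surface offset 2.5 mm along the exact surface
normals.  Gyral thickness — the shortest two-sided chord through each
white-matter voxel — is thresholded at 10 mm to separate the gyral blade
from deep white matter.

Run:  python examples/01_synthetic_gyrus.py
"""

import numpy as np

import gyralfield as gf

ribbon, grid, wm = gf.make_gyrus()  # default GyrusSpec
print(f"white surface: {ribbon.white.n_vertices} vertices, {ribbon.white.n_faces} faces")
print(f"voxel grid:    {grid.shape} at {grid.voxel_size[0]:.0f} mm")
print(f"white matter:  {wm.n_voxels} voxels")
print(f"cortical volume: {ribbon.total_volume:.2f} mm^3")

thickness = gf.compute_gyral_thickness(ribbon.white, grid, wm, n_directions=64, max_length=50.0)
inside = wm.values
print(f"gyral thickness: min {np.nanmin(thickness.values[inside]):.2f} mm, "
      f"max {np.nanmax(thickness.values[inside]):.2f} mm")

gyral = gf.threshold_gyral_mask(thickness, wm, threshold_mm := 10.0)
deep = gf.deep_mask_from_gyral(wm, gyral)
print(f"threshold {threshold_mm} mm -> {gyral.n_voxels} gyral voxels, "
      f"{deep.n_voxels} deep voxels")

anchor = gf.deep_anchor_point(deep)
print(f"deep-white-matter anchor: ({anchor[0]:.2f}, {anchor[1]:.2f}, {anchor[2]:.2f}) mm")
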