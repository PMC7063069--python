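"""From a 3-D deformation field to a per-beam 2-D field on the plane.

A spherical ROI inside a small grid carries a uniform 8 mm displacement;
each fluence-plane pixel's ray is traced through the grid and the
projected displacements of the crossed ROI voxels are averaged.  The
printed field shows the uniform translation re-appearing on the plane
(rotated into the beam frame), with coverage counting the voxels each ray
crossed.
"""

import numpy as np

import ifp

grid = ifp.Grid3D((16, 16, 16), (5.0,) * 3, (-37.5,) * 3)
centers = grid.voxel_centers()
roi = ifp.ROIMask(grid=grid,
                  mask=np.linalg.norm(centers, axis=-1) <= 20.0, name="target")
dvf = ifp.make_dvf("translation", {"translation": (8.0, 0.0, 0.0)}, grid)

beam = ifp.BeamGeometry(gantry_angle=0.0, sad=1000.0, isocenter=(0, 0, 0))
plane = ifp.PlaneGrid((12, 12), (5.0, 5.0), (-27.5, -27.5))
field = ifp.project_dvf_to_bev(dvf, roi, beam, plane)

covered = field.coverage > 0
print(f"covered pixels: {covered.sum()} of {field.coverage.size}")
print(f"mean plane vector over covered pixels: "
      f"{np.round(field.vectors[covered].mean(axis=0), 3)} mm")
print("  (gantry 0: beam-frame x = -world x, so +8 mm world maps to -8 mm)")
print(f"coverage row through the center: {field.coverage[:, 6]}")

filled = ifp.fill_uncovered(field, mode="nearest")
print(f"after nearest-fill, every pixel carries a vector; corner pixel: "
      f"{np.round(filled.vectors[0, 0], 3)} mm")
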