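"""Divergent-beam projection onto the isocenter plane.

Builds one beam, expresses points in its gantry frame, and projects points
and displacement vectors onto the isocenter plane.  The printed
magnification shows the core geometric fact the whole pipeline rests on: a
displacement at depth z (toward the source) appears on the plane scaled by
SAD / (SAD - z).
"""

import numpy as np

import ifp

beam = ifp.BeamGeometry(gantry_angle=72.0, sad=1000.0, isocenter=(0, 0, 0),
                        beam_id="demo")
print(f"beam {beam.beam_id}: gantry {beam.gantry_angle} deg, source at "
      f"{np.round(beam.source_position, 1)} (world mm)")

p_world = np.array([20.0, -30.0, 10.0])
p_beam = ifp.world_to_beam(p_world, beam)
print(f"world point {p_world} -> beam frame {np.round(p_beam, 3)}")

for z in (-100.0, 0.0, 100.0, 250.0):
    start = np.array([10.0, 0.0, z])
    end = start + np.array([5.0, 0.0, 0.0])   # 5 mm in-plane displacement
    v = ifp.project_vector(start, end, beam.sad)
    print(f"  5 mm displacement at depth z={z:+6.1f} mm projects to "
          f"{v[0]:.3f} mm  (magnification {1000 / (1000 - z):.3f})")

# a pixel's ray passes through the source and its plane position
ray = ifp.pixel_ray(np.array([25.0, 0.0]), beam.sad, beam)
print(f"ray through pixel (25, 0): direction {np.round(ray.direction, 4)}")
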