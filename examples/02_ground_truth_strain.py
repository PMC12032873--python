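"""Generate a contractile deformation and its ground-truth Green strain.

Uses the area-preserving (incompressible) radial map with 18% endocardial
circumferential shortening. At the endocardium the closed forms give
Ecc = ((r'/r)^2 - 1)/2 = -0.18 and Err = ((r/r')^2 - 1)/2 = 0.28125; the
printed pixel values come from the central-difference strain operator and
should sit close to these at the inner wall, decreasing toward the
epicardium (the transmural gradient of the incompressible annulus).
"""

import numpy as np

from densesim.anatomy import generate_annulus, polar_geometry
from densesim.motion import (DeformationModel, MotionParams,
                             generate_displacement_field, green_strain)

labelmap = generate_annulus(240, 0.8, 75, 120)
geometry = polar_geometry(labelmap)
params = MotionParams(rr_interval=1000.0, peak_rotation=0.3,
                      peak_ecc_scale=0.18, transmural_err_gradient=1.0)
model = DeformationModel(labelmap, geometry, params)

times = [0.0, 0.5 * params.t_es, params.t_es]
field = generate_displacement_field(labelmap, geometry, params, times, model=model)
strain = green_strain(field, geometry=geometry)

print(f"wall radii: {model.r_endo:.1f} -> {model.r_epi:.1f} mm; "
      f"end-systole at {params.t_es:.0f} ms")
print(f"peak displacement magnitude: "
      f"{np.linalg.norm(field.displacements[-1], axis=1).max():.2f} mm")

es = len(times) - 1
t = geometry.transmural
for name, sel in [("endocardial third", t < 1 / 3), ("epicardial third", t > 2 / 3)]:
    m = strain.valid & sel
    print(f"{name}: Err = {np.nanmean(strain.err[es][m]):+.3f}, "
          f"Ecc = {np.nanmean(strain.ecc[es][m]):+.3f}")
print("closed forms at the endocardial boundary: Err = +0.281, Ecc = -0.180")
print(f"strain at end-diastole (should be 0): "
      f"max |E| = {np.nanmax(np.abs(strain.E_tensor[0][strain.valid])):.1e}")
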