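"""Recover strain from simulated DENSE images and quantify its accuracy.

The analysis mirrors the standard DENSE workflow: phase -> wrapped Eulerian
displacement -> spatiotemporal unwrapping -> per-frame Laplacian-regularized
grid fit (smoothness k) -> Lagrangian tracking -> order-10 temporal
polynomial -> Green strain. The printed average signed error (ASE, true -
estimated, at end-systole) shows the regularization trade-off: higher k
suppresses noise (smaller std) but underestimates radial strain near the
endocardium (larger positive ASE).
"""

import numpy as np

from densesim.acquisition import AcqParams, simulate_case
from densesim.anatomy import generate_annulus, polar_geometry
from densesim.cohort import pixel_signed_errors
from densesim.motion import DeformationModel, MotionParams
from densesim.strain_eval import (RegularizedFitConfig, evaluate_series,
                                  ground_truth_on_grid, prepare_eulerian)

labelmap = generate_annulus(120, 1.6, 37.5, 60)
geometry = polar_geometry(labelmap)
params = MotionParams(rr_interval=900.0, peak_rotation=0.3, peak_ecc_scale=0.18)
model = DeformationModel(labelmap, geometry, params)
series = simulate_case(labelmap, geometry, model,
                       AcqParams(N1=120, N2=60, Nf=64, target_snr=10.0),
                       rng=np.random.default_rng(7))

fov = labelmap.fov
prepared = prepare_eulerian(series, model, fov)  # unwrap once, reuse per k
truth = ground_truth_on_grid(model, geometry, prepared[1], series.frame_times)
es = series.es_index
print(f"measured ES SNR: {series.snr[es]:.1f}\n")
print("   k    Err ASE+/-std      Ecc ASE+/-std   (true - estimated, ES)")
for k in (0.1, 0.3, 0.6, 0.9):
    est = evaluate_series(series, model, geometry, fov,
                          RegularizedFitConfig(k=k), prepared=prepared)
    table = pixel_signed_errors(truth, est, es).set_index(["component", "segment"])
    e = table.loc[("Err", "global")]
    c = table.loc[("Ecc", "global")]
    print(f"  {k:.1f}   {e.ase:+.3f} +/- {e['std']:.3f}   "
          f"{c.ase:+.3f} +/- {c['std']:.3f}")
print("\nhigher k: smaller std (noise suppressed) but growing positive Err ASE")
print("(radial strain underestimated, mostly subendocardially)")
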