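"""Shared fixtures: small annular anatomies and pre-simulated cases.

Everything is generated programmatically; session-scoped fixtures keep the
expensive Bloch simulations to a handful per test run.
"""

import numpy as np
import pytest

from densesim.acquisition import AcqParams, DenseSimulator
from densesim.anatomy import generate_annulus, polar_geometry
from densesim.motion import DeformationModel, MotionParams


@pytest.fixture(scope="session")
def annulus():
    """240 x 240 / 0.8 mm annulus, endo 75 px / epi 120 px (r = 30/48 mm)."""
    lm = generate_annulus(240, 0.8, 75, 120)
    return lm, polar_geometry(lm)


@pytest.fixture(scope="session")
def small_annulus():
    """Desk-scale 120 x 120 / 1.6 mm annulus (same physical geometry)."""
    lm = generate_annulus(120, 1.6, 37.5, 60)
    return lm, polar_geometry(lm)


@pytest.fixture(scope="session")
def incompressible_model(small_annulus):
    lm, geo = small_annulus
    params = MotionParams(rr_interval=900.0, peak_rotation=0.3,
                          peak_ecc_scale=0.18, transmural_err_gradient=1.0)
    return DeformationModel(lm, geo, params)


@pytest.fixture(scope="session")
def spiral_simulator(small_annulus, incompressible_model):
    """Noiseless spiral simulator on the desk-scale annulus (samples cached)."""
    lm, geo = small_annulus
    acq = AcqParams(N1=120, N2=60, Nf=64)
    sim = DenseSimulator(lm, geo, incompressible_model, acq,
                         rng=np.random.default_rng(1234))
    sim.prepare_spiral()
    return sim


@pytest.fixture(scope="session")
def spiral_series(spiral_simulator):
    return spiral_simulator.run()


@pytest.fixture(scope="session")
def cartesian_case(small_annulus):
    """Noise-free Cartesian-sampled case with modest motion (no phase wrap)."""
    lm, geo = small_annulus
    # amplitudes chosen so peak |u| stays below the 5 mm wrap half-period
    params = MotionParams(rr_interval=900.0, peak_rotation=0.08,
                          peak_ecc_scale=0.11, transmural_err_gradient=1.0)
    model = DeformationModel(lm, geo, params)
    acq = AcqParams(N1=120, N2=60, Nf=64, sampling="cartesian", n_frames=14)
    series = DenseSimulator(lm, geo, model, acq, rng=np.random.default_rng(7)).run()
    return {"labelmap": lm, "geometry": geo, "model": model, "series": series}
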