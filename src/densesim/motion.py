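"""Synthetic contractile myocardial motion and ground-truth Green strain.

The deformation model is a smooth, closed-form polar map applied to
end-diastolic (ED) myocardial pixels:

    r'(r, t)     = r - a(t) * f(r)
    theta'(r, t) = theta + a(t) * peak_rotation * g(r)

with ``a(t)`` a systole-weighted temporal activation (0 at ED, 1 at
end-systole), ``f`` a smooth radial-displacement profile and ``g`` a
transmural twist profile (constant by default). The peak radial map
``r - f(r)`` is the closed-form blend of

* a *constant-radial-strain* map (linear in r), and
* an exactly *area-preserving* map ``r'^2 = r^2 - c`` (the incompressible
  annulus, whose radial strain is higher at the endocardium and close to
  linear across the wall),

with blend weight ``transmural_err_gradient`` in [0, 1] — a low-order
smooth deformation field whose transmural radial-strain gradient, twist and
timing are all controllable, and whose Jacobian is exactly 1 in the
incompressible limit.

Ground-truth strain is the Green-Lagrange tensor E = (F^T F - I)/2 with the
deformation gradient F obtained by central differences of the deformed pixel
positions on the regular ED raster (one-sided at wall edges), projected onto
the radial/circumferential unit vectors of the ED geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import LabelMap, PolarGeometry

__all__ = [
    "MotionParams",
    "MotionField",
    "StrainMap",
    "DeformationModel",
    "FoldingError",
    "sample_motion_parameters",
    "temporal_activation",
    "generate_displacement_field",
    "green_strain",
    "strain_from_positions",
]


class FoldingError(ValueError):
    """Deformation map is not injective (non-positive Jacobian)."""


@dataclass
class MotionParams:
    """Parameters of one simulated cardiac deformation.

    rr_interval : ms, cardiac cycle length.
    peak_rotation : rad, peak-systolic rigid 2D twist about the LV center.
    transmural_err_gradient : [0, 1]; 0 gives a transmurally constant radial
        strain, 1 the (approximately linear, endocardium-weighted) gradient
        of an incompressible annulus.
    peak_err_scale : peak radial (wall-thickening) Green strain of the
        constant-strain component.
    peak_ecc_scale : magnitude of the peak endocardial circumferential
        shortening; the endocardial radius contracts by the matching factor
        sqrt(1 - 2*peak_ecc_scale).
    es_fraction : end-systole as a fraction of the R-R interval.
    coverage_start : ms, prospective-trigger offset (frames before this time
        are simply not sampled; the model itself covers the full cycle).
    twist_falloff : [0, 1], linear endo->epi reduction of the twist profile
        g(r) (0 keeps g constant).
    """

    rr_interval: float = 1000.0
    peak_rotation: float = 0.0
    transmural_err_gradient: float = 1.0
    peak_err_scale: float = 0.25
    peak_ecc_scale: float = 0.18
    es_fraction: float = 0.35
    coverage_start: float = 0.0
    twist_falloff: float = 0.0

    def __post_init__(self):
        if not 0 < self.es_fraction < 1:
            raise ValueError("es_fraction must be in (0, 1)")
        if self.peak_ecc_scale >= 0.5:
            raise ValueError("peak_ecc_scale must be < 0.5")

    @property
    def t_es(self) -> float:
        return self.es_fraction * self.rr_interval


def sample_motion_parameters(cohort_config, rng: np.random.Generator) -> MotionParams:
    """Draw independent motion parameters from a cohort configuration.

    ``cohort_config`` needs attributes ``rr_range``, ``rotation_range``,
    ``err_gradient_range``, ``err_scale_range``, ``ecc_scale_range`` (each a
    (low, high) pair). Collapsed ranges yield exactly that value.
    """

    def draw(lo_hi):
        lo, hi = float(lo_hi[0]), float(lo_hi[1])
        if hi < lo:
            raise ValueError(f"inverted range {lo_hi}")
        return lo if hi == lo else rng.uniform(lo, hi)

    return MotionParams(
        rr_interval=draw(cohort_config.rr_range),
        peak_rotation=draw(cohort_config.rotation_range),
        transmural_err_gradient=draw(cohort_config.err_gradient_range),
        peak_err_scale=draw(cohort_config.err_scale_range),
        peak_ecc_scale=draw(cohort_config.ecc_scale_range),
    )


def temporal_activation(t, params: MotionParams):
    """Systole-weighted activation a(t): 0 at ED, 1 at end-systole.

    Rising limb sin(pi t / (2 t_ES)) — faster early than late, matching the
    in-vivo pattern of more motion at the beginning of the cycle; falling
    limb a raised cosine back to 0 at the end of the cycle.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > params.rr_interval):
        raise ValueError("time outside the cardiac cycle")
    tes = params.t_es
    rising = np.sin(0.5 * np.pi * np.minimum(t, tes) / tes)
    falling = np.cos(0.5 * np.pi * (np.maximum(t, tes) - tes) / (params.rr_interval - tes))
    out = np.where(t <= tes, rising, falling)
    return out if out.ndim else float(out)


class DeformationModel:
    """Closed-form polar deformation of an annular myocardium.

    Evaluates displacements, inverse maps and Jacobians analytically at any
    physical position and time, so ground truth never needs temporal or
    spatial interpolation.
    """

    def __init__(self, labelmap: LabelMap, geometry: PolarGeometry, params: MotionParams):
        self.params = params
        self.geometry = geometry
        x, y = labelmap.coordinates()
        myo = labelmap.myocardium
        r_myo = np.hypot(x[myo] - geometry.center[0], y[myo] - geometry.center[1])
        self.r_endo = float(r_myo.min())
        self.r_epi = float(r_myo.max())
        self._fit_radial_profile()
        self._check_folding()

    # -- radial profile ----------------------------------------------------
    def _fit_radial_profile(self):
        p = self.params
        r0 = self.r_endo
        shrink = np.sqrt(1.0 - 2.0 * p.peak_ecc_scale)  # endocardial radius factor
        self._u_endo = r0 * (1.0 - shrink)
        self._m_lin = np.sqrt(1.0 + 2.0 * p.peak_err_scale)
        self._c_inc = r0**2 - (r0 - self._u_endo) ** 2

    def _target_map(self, r):
        """Peak-activation radial map r'(r): blend of the constant-strain
        (linear) and exactly area-preserving (sqrt) maps."""
        p = self.params
        r0 = self.r_endo
        t_lin = (r0 - self._u_endo) + self._m_lin * (r - r0)
        t_inc = np.sqrt(np.clip(r**2 - self._c_inc, 0.0, None))
        g = p.transmural_err_gradient
        return (1.0 - g) * t_lin + g * t_inc

    def _f(self, r):
        """Peak radial displacement profile f(r) = r - r'(r)."""
        return r - self._target_map(r)

    def _fprime(self, r):
        p = self.params
        t_inc = np.sqrt(np.clip(r**2 - self._c_inc, 1e-12, None))
        d_target = (1.0 - p.transmural_err_gradient) * self._m_lin + \
            p.transmural_err_gradient * r / t_inc
        return 1.0 - d_target

    def _check_folding(self):
        r = np.linspace(self.r_endo, self.r_epi, 201)
        rp = r - self._f(r)  # peak activation
        drp = 1.0 - self._fprime(r)
        if np.any(rp <= 0) or np.any(drp <= 0):
            raise FoldingError("deformation folds (non-positive Jacobian) at peak activation")

    # -- kinematics --------------------------------------------------------
    def activation(self, t):
        return temporal_activation(t, self.params)

    def _polar(self, points):
        d = np.asarray(points, dtype=float) - self.geometry.center
        r = np.hypot(d[..., 0], d[..., 1])
        th = np.arctan2(d[..., 1], d[..., 0])
        return r, th

    def _twist_profile(self, r):
        w = self.params.twist_falloff
        if w == 0.0:
            return np.ones_like(r)
        s = np.clip((r - self.r_endo) / (self.r_epi - self.r_endo), 0.0, 1.0)
        return 1.0 - w * s

    def map_points(self, points, t):
        """Deformed physical positions of material points ``points`` at time t."""
        a = self.activation(t)
        if a == 0.0:  # exact identity at end-diastole
            return np.array(points, dtype=float)
        r, th = self._polar(points)
        rp = r - a * self._f(r)
        thp = th + a * self.params.peak_rotation * self._twist_profile(r)
        out = np.stack([rp * np.cos(thp), rp * np.sin(thp)], axis=-1)
        return out + self.geometry.center

    def displacement(self, points, t):
        return self.map_points(points, t) - np.asarray(points, dtype=float)

    def inverse_map(self, points, t, n_iter: int = 30):
        """Reference (ED) positions of the material points now at ``points``.

        Newton iteration on the monotone radial map, then removal of the
        twist. Radii are clipped to the wall for out-of-wall queries.
        """
        a = self.activation(t)
        rp, thp = self._polar(points)
        r = np.clip(rp, 1e-6, None).astype(float)
        for _ in range(n_iter):
            res = r - a * self._f(r) - rp
            dres = 1.0 - a * self._fprime(r)
            step = res / dres
            r = r - step
            if np.max(np.abs(step)) < 1e-12:
                break
        th = thp - a * self.params.peak_rotation * self._twist_profile(r)
        out = np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)
        return out + self.geometry.center

    def jacobian_determinant(self, points, t):
        """det F of the polar map: (dr'/dr) * (r'/r) (twist is area-neutral
        when g is constant; with falloff the shear term still has det 1)."""
        a = self.activation(t)
        r, _ = self._polar(points)
        rp = r - a * self._f(r)
        return (1.0 - a * self._fprime(r)) * rp / r

    def eulerian_displacement(self, points, t):
        """Displacement since ED of the tissue currently at ``points``."""
        ref = self.inverse_map(points, t)
        return np.asarray(points, dtype=float) - ref

    def deformed_mask(self, t, n: int, pixel_size: float, origin=(0.0, 0.0)) -> np.ndarray:
        """Rasterize the deformed myocardium on an ``n x n`` grid at time t."""
        from .anatomy import pixel_coordinates

        x, y = pixel_coordinates(n, pixel_size, origin)
        pts = np.stack([x, y], axis=-1)
        ref = self.inverse_map(pts.reshape(-1, 2), t).reshape(n, n, 2)
        r = np.hypot(ref[..., 0] - self.geometry.center[0], ref[..., 1] - self.geometry.center[1])
        return (r > self.r_endo) & (r <= self.r_epi)


@dataclass
class MotionField:
    """Sampled Lagrangian pixel trajectories on the ED raster.

    ``ref_positions``/``displacements`` are flat arrays over myocardial
    pixels; ``pixel_index`` holds their (row, col) raster indices and
    ``shape`` the raster shape, so fields can be re-rasterized.
    """

    ref_positions: np.ndarray  # (P, 2) mm
    frame_times: np.ndarray  # (T,) ms, strictly increasing
    displacements: np.ndarray  # (T, P, 2) mm
    pixel_index: tuple  # (rows, cols)
    shape: tuple
    spacing: float  # mm

    def deformed_positions(self, frame: int) -> np.ndarray:
        return self.ref_positions + self.displacements[frame]


def generate_displacement_field(
    labelmap: LabelMap,
    geometry: PolarGeometry,
    params: MotionParams,
    frame_times,
    model: DeformationModel | None = None,
) -> MotionField:
    """Sample the analytic deformation at myocardial pixels and frame times."""
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    model = model or DeformationModel(labelmap, geometry, params)
    myo = labelmap.myocardium
    rows, cols = np.nonzero(myo)
    x, y = labelmap.coordinates()
    ref = np.stack([x[myo], y[myo]], axis=-1)
    disp = np.empty((len(frame_times), len(ref), 2))
    for i, t in enumerate(frame_times):
        disp[i] = model.displacement(ref, t)
    return MotionField(ref, frame_times, disp, (rows, cols), myo.shape, labelmap.pixel_size)


@dataclass
class StrainMap:
    """Per-pixel Green-Lagrange strain through time on the ED raster."""

    frame_times: np.ndarray
    E_tensor: np.ndarray  # (T, H, W, 2, 2), NaN outside valid pixels
    err: np.ndarray  # (T, H, W)
    ecc: np.ndarray  # (T, H, W)
    valid: np.ndarray  # (H, W) bool
    transmural: np.ndarray | None = None  # (H, W), NaN outside


def _deformation_gradient(def_x, def_y, valid, spacing):
    """Per-pixel F from finite differences of deformed positions.

    Central differences where both neighbors are valid, one-sided at wall
    edges; pixels with no valid neighbor in either direction are flagged
    invalid.
    """
    H, W = valid.shape
    F = np.full((H, W, 2, 2), np.nan)
    ok = np.zeros((H, W), dtype=bool)

    def diff(arr, axis):
        # returns derivative raster and a validity raster
        d = np.full((H, W), np.nan)
        good = np.zeros((H, W), dtype=bool)
        fwd = np.roll(arr, -1, axis=axis)
        bwd = np.roll(arr, 1, axis=axis)
        vf = np.roll(valid, -1, axis=axis).copy()
        vb = np.roll(valid, 1, axis=axis).copy()
        if axis == 0:
            vf[-1, :] = False
            vb[0, :] = False
        else:
            vf[:, -1] = False
            vb[:, 0] = False
        both = valid & vf & vb
        d[both] = (fwd[both] - bwd[both]) / (2 * spacing)
        fonly = valid & vf & ~vb
        d[fonly] = (fwd[fonly] - arr[fonly]) / spacing
        bonly = valid & ~vf & vb
        d[bonly] = (arr[bonly] - bwd[bonly]) / spacing
        good = both | fonly | bonly
        return d, good

    dxdX, g1 = diff(def_x, axis=1)  # d(x')/dX  (X along columns)
    dxdY, g2 = diff(def_x, axis=0)
    dydX, g3 = diff(def_y, axis=1)
    dydY, g4 = diff(def_y, axis=0)
    ok = g1 & g2 & g3 & g4
    F[..., 0, 0] = dxdX
    F[..., 0, 1] = dxdY
    F[..., 1, 0] = dydX
    F[..., 1, 1] = dydY
    return F, ok


def strain_from_positions(ref_raster, def_raster, valid, spacing, radial_unit, circ_unit):
    """Green strain from reference/deformed position rasters.

    ``ref_raster``/``def_raster`` are (H, W, 2); units are (H, W, 2) rasters
    of projection directions at the reference positions.
    """
    F, ok = _deformation_gradient(def_raster[..., 0], def_raster[..., 1], valid, spacing)
    E = 0.5 * (np.einsum("...ki,...kj->...ij", F, F) - np.eye(2))
    err = np.einsum("...i,...ij,...j->...", radial_unit, E, radial_unit)
    ecc = np.einsum("...i,...ij,...j->...", circ_unit, E, circ_unit)
    err[~ok] = np.nan
    ecc[~ok] = np.nan
    return E, err, ecc, ok


def green_strain(field: MotionField, spacing: float | None = None,
                 geometry: PolarGeometry | None = None) -> StrainMap:
    """Ground-truth Green-Lagrange strain of a sampled motion field."""
    spacing = spacing or field.spacing
    H, W = field.shape
    rows, cols = field.pixel_index
    valid_px = np.zeros((H, W), dtype=bool)
    valid_px[rows, cols] = True

    ref = np.full((H, W, 2), np.nan)
    ref[rows, cols] = field.ref_positions
    if geometry is None:
        raise ValueError("geometry is required for Err/Ecc projection")
    rad = geometry.radial_unit
    circ = geometry.circ_unit
    trans = geometry.transmural

    T = len(field.frame_times)
    E_all = np.full((T, H, W, 2, 2), np.nan)
    err_all = np.full((T, H, W), np.nan)
    ecc_all = np.full((T, H, W), np.nan)
    ok_all = np.ones((H, W), dtype=bool)
    for f in range(T):
        defo = np.full((H, W, 2), np.nan)
        defo[rows, cols] = field.deformed_positions(f)
        E, errm, eccm, ok = strain_from_positions(ref, defo, valid_px, spacing, rad, circ)
        E_all[f], err_all[f], ecc_all[f] = E, errm, eccm
        ok_all &= ok
    return StrainMap(field.frame_times, E_all, err_all, ecc_all, ok_all & valid_px, trans)
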